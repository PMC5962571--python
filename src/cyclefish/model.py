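"""Cell-cycle-scheduled birth-death model of transcription.

Each gene is transcribed at a piecewise-constant rate: ``k_high`` inside one
or two deterministic high-expression windows of the cycle and ``k_low``
(basal, non-zero) outside them, with first-order degradation at rate ``p``.
For this linear (monomolecular) system the chemical master equation with a
Poisson initial condition has a closed-form solution: the copy number at any
time is Poisson distributed with mean ``m(t)`` obeying

    dm/dt = k(t) - p * m(t),

solved piecewise-exponentially on constant-rate segments.  A cell observed
at an unknown position within a phase therefore carries a count drawn from a
uniform-in-time mixture of Poissons over that phase — the analytic
per-phase count distribution used for maximum-likelihood fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .phases import PhaseMap, default_phase_map

__all__ = [
    "GeneParams",
    "ModelSpec",
    "transcription_rate",
    "mean_trajectory",
    "periodic_mean_start",
    "segment_schedule",
    "phase_count_distribution",
    "phase_mixture_means",
    "promoter_activity",
    "table1_model",
]


@dataclass(frozen=True)
class GeneParams:
    """Kinetic parameterization of one gene.

    Parameters
    ----------
    name
        Gene label (e.g. ``"SIC1"``).
    k_high, k_low
        Transcription rate constants (molecules/min) inside and outside the
        high-expression windows; ``0 <= k_low <= k_high``.
    p
        First-order degradation rate constant (1/min), ``p > 0``.
    windows
        One or two half-open high-expression intervals ``(t_start, t_end)``
        in cycle minutes, sorted and non-overlapping, each within
        ``[0, cycle_length)``.  A window crossing the cycle boundary must be
        supplied pre-split into two windows.
    """

    name: str
    k_high: float
    k_low: float
    p: float
    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError(f"{self.name}: degradation rate p must be > 0")
        if not (0 <= self.k_low <= self.k_high):
            raise ValueError(
                f"{self.name}: need 0 <= k_low <= k_high, got "
                f"k_low={self.k_low}, k_high={self.k_high}"
            )
        wins = tuple(tuple(map(float, w)) for w in self.windows)
        if len(wins) > 2:
            raise ValueError(f"{self.name}: at most 2 high-expression windows")
        for a, b in wins:
            if not (a < b):
                raise ValueError(f"{self.name}: empty window ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            if b1 > a2:
                raise ValueError(f"{self.name}: windows overlap or unsorted")
        object.__setattr__(self, "windows", wins)

    @property
    def basal_mean(self) -> float:
        """Steady-state mean in the low-expression regime, k_low / p."""
        return self.k_low / self.p


@dataclass(frozen=True)
class ModelSpec:
    """A set of genes sharing one cell-cycle phase map."""

    genes: tuple[GeneParams, ...]
    phase_map: PhaseMap = field(default_factory=default_phase_map)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate gene names in model: {names}")
        T = self.phase_map.cycle_length
        for g in self.genes:
            for a, b in g.windows:
                if not (0 <= a < T and 0 < b <= T):
                    raise ValueError(
                        f"{g.name}: window ({a}, {b}) outside [0, {T})"
                    )
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def gene(self, name: str) -> GeneParams:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not in model ({self.gene_names})")

    @property
    def cycle_length(self) -> float:
        return self.phase_map.cycle_length


# ---------------------------------------------------------------------------
# rate schedule and mean dynamics
# ---------------------------------------------------------------------------

def transcription_rate(
    gene: GeneParams, t: float | np.ndarray, cycle_length: float = 129.0
) -> float | np.ndarray:
    """Transcription rate at cycle time ``t`` (reduced modulo the cycle).

    ``k_high`` iff the reduced time lies in a high-expression window
    (half-open: the start minute is high, the end minute is low), else
    ``k_low``.
    """
    tt = np.asarray(t, dtype=float) % cycle_length
    high = np.zeros(tt.shape, dtype=bool)
    for a, b in gene.windows:
        high |= (tt >= a) & (tt < b)
    out = np.where(high, gene.k_high, gene.k_low)
    if np.ndim(t) == 0:
        return float(out)
    return out


def segment_schedule(
    gene: GeneParams, cycle_length: float = 129.0
) -> tuple[np.ndarray, np.ndarray]:
    """One cycle as constant-rate segments.

    Returns ``(bounds, rates)`` with ``bounds`` of length ``n+1`` spanning
    ``[0, cycle_length]`` and ``rates`` of length ``n``; segment ``i`` has
    transcription rate ``rates[i]`` on ``[bounds[i], bounds[i+1])``.
    """
    edges = {0.0, float(cycle_length)}
    for a, b in gene.windows:
        edges.add(float(a))
        edges.add(float(b))
    bounds = np.array(sorted(edges))
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    rates = np.asarray(transcription_rate(gene, mids, cycle_length), dtype=float)
    return bounds, rates


def _propagate_mean(m0: float, k: float, p: float, dt: float) -> float:
    """Closed-form mean after time ``dt`` at constant rates: relax to k/p."""
    kp = k / p
    return kp + (m0 - kp) * math.exp(-p * dt)


def mean_trajectory(
    gene: GeneParams,
    t_grid: np.ndarray,
    m0: float,
    cycle_length: float = 129.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Mean copy number on ``t_grid`` (cycle minutes, increasing) from
    ``m(t0) = m0``.

    The mean relaxes exponentially toward ``k/p`` on each constant-rate
    segment; the trajectory is continuous and piecewise smooth.  ``t_grid``
    may extend over several cycles (the schedule repeats periodically).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if m0 < 0:
        raise ValueError("initial mean m0 must be >= 0")
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be a non-decreasing 1-d array")
    if t_grid.size and t_grid[0] < t0:
        raise ValueError("t_grid must start at or after t0")

    bounds, rates = segment_schedule(gene, cycle_length)
    out = np.empty_like(t_grid)
    t_cur, m_cur = float(t0), float(m0)
    # track the current segment incrementally (recomputing it from
    # t_cur % cycle_length can stall at boundaries within one float ulp)
    c0 = t0 % cycle_length
    seg = min(int(np.searchsorted(bounds, c0, side="right")) - 1, len(rates) - 1)
    seg_end_abs = t_cur + (bounds[seg + 1] - c0)
    for i, t in enumerate(t_grid):
        while t > seg_end_abs + 1e-9:
            m_cur = _propagate_mean(
                m_cur, rates[seg], gene.p, max(seg_end_abs - t_cur, 0.0)
            )
            t_cur = seg_end_abs
            seg += 1
            if seg >= len(rates):
                seg = 0
            seg_end_abs += bounds[seg + 1] - bounds[seg]
        m_cur = _propagate_mean(m_cur, rates[seg], gene.p, max(t - t_cur, 0.0))
        t_cur = t
        out[i] = m_cur
    return out


def periodic_mean_start(gene: GeneParams, cycle_length: float = 129.0) -> float:
    """Mean at cycle time 0 of the unique cycle-periodic solution.

    Over one cycle the mean map is affine, ``m(T) = A + B m(0)`` with
    ``B = exp(-p T)``; the fixed point ``A / (1 - B)`` is the periodic
    steady state every initial condition converges to geometrically.
    """
    bounds, rates = segment_schedule(gene, cycle_length)
    a = 0.0
    for i, k in enumerate(rates):
        a = _propagate_mean(a, k, gene.p, bounds[i + 1] - bounds[i])
    b = math.exp(-gene.p * cycle_length)
    return a / (1.0 - b)


def _segment_start_means(
    gene: GeneParams, cycle_length: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Periodic-state mean at each segment start: (bounds, rates, m_at_start)."""
    bounds, rates = segment_schedule(gene, cycle_length)
    # fixed point of the affine one-cycle map m -> A + exp(-pT) m
    a = 0.0
    for i, k in enumerate(rates):
        a = _propagate_mean(a, k, gene.p, bounds[i + 1] - bounds[i])
    m = np.empty(len(rates))
    m[0] = a / (1.0 - math.exp(-gene.p * cycle_length))
    for i in range(len(rates) - 1):
        m[i + 1] = _propagate_mean(m[i], rates[i], gene.p, bounds[i + 1] - bounds[i])
    return bounds, rates, m


def periodic_mean_at(
    gene: GeneParams, t: np.ndarray, cycle_length: float = 129.0
) -> np.ndarray:
    """Vectorized periodic-state mean m(t) at arbitrary cycle times."""
    bounds, rates, m_start = _segment_start_means(gene, cycle_length)
    tt = np.asarray(t, dtype=float) % cycle_length
    seg = np.clip(np.searchsorted(bounds, tt, side="right") - 1, 0, len(rates) - 1)
    kp = rates[seg] / gene.p
    return kp + (m_start[seg] - kp) * np.exp(-gene.p * (tt - bounds[seg]))


# ---------------------------------------------------------------------------
# analytic per-phase count distributions
# ---------------------------------------------------------------------------

QUADRATURE_DT = 0.1  # midpoint-rule resolution (minutes) for phase mixtures


def phase_quadrature_times(pmap: PhaseMap, phase: str, dt: float = QUADRATURE_DT) -> np.ndarray:
    """Midpoint-rule abscissae covering one phase interval exactly."""
    a, b = pmap.phase_interval(phase)
    n = max(1, int(math.ceil((b - a) / dt)))
    h = (b - a) / n
    return a + (np.arange(n) + 0.5) * h


def phase_mixture_means(
    gene: GeneParams, pmap: PhaseMap, phase: str, dt: float = QUADRATURE_DT
) -> np.ndarray:
    """Periodic-state means m(t) at the phase's quadrature points."""
    return periodic_mean_at(gene, phase_quadrature_times(pmap, phase, dt),
                            pmap.cycle_length)


def mixture_pmf(means: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Uniform mixture of Poisson pmfs, evaluated at ``counts``.

    ``means`` are the mixture-component means (quadrature points of one
    phase); returns ``mean_t Poisson(counts; means[t])``.
    """
    m = np.asarray(means, dtype=float)[:, None]
    c = np.asarray(counts, dtype=float)[None, :]
    logpmf = c * np.log(m) - m - gammaln(c + 1.0)
    return np.exp(logpmf).mean(axis=0)


def phase_count_distribution(
    gene: GeneParams,
    pmap: PhaseMap,
    phase: str,
    n_max: int = 200,
    dt: float = QUADRATURE_DT,
) -> np.ndarray:
    """Analytic pmf of the mRNA count for a cell in ``phase``.

    The count of a cell at cycle time t is Poisson(m(t)) at the periodic
    steady state; a cell's position within its phase is uniform, so the
    phase distribution is the uniform Poisson mixture over the phase
    interval (midpoint quadrature at ``dt``-minute resolution).  The pmf is
    truncated at ``n_max`` with all remaining tail mass folded into the last
    bin, so it sums to 1 exactly.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    means = phase_mixture_means(gene, pmap, phase, dt)
    pmf = mixture_pmf(means, np.arange(n_max + 1))
    tail = 1.0 - pmf.sum()
    pmf[-1] += max(tail, 0.0)
    return pmf


def promoter_activity(gene: GeneParams) -> float:
    """Relative promoter activity, percent: 100 * k_low / k_high."""
    if gene.k_high == 0:
        raise ValueError(f"{gene.name}: k_high is zero; activity undefined")
    return 100.0 * gene.k_low / gene.k_high


# ---------------------------------------------------------------------------
# the published parameterization (shipped as package data)
# ---------------------------------------------------------------------------

def _model_from_mapping(d: Mapping, pmap: PhaseMap | None = None) -> ModelSpec:
    genes = tuple(
        GeneParams(
            name=g["name"],
            k_high=float(g["k_high"]),
            k_low=float(g["k_low"]),
            p=float(g["p"]),
            windows=tuple(tuple(map(float, w)) for w in g["windows"]),
        )
        for g in d["genes"]
    )
    if pmap is None:
        pmap = default_phase_map(float(d.get("cycle_length", 129.0)))
    return ModelSpec(genes=genes, phase_map=pmap)


def table1_model(phase_map: PhaseMap | None = None) -> ModelSpec:
    """The published three-gene parameterization (SIC1, CLN2, CLB5)."""
    import yaml

    path = Path(__file__).parent / "data" / "table1.yaml"
    return _model_from_mapping(yaml.safe_load(path.read_text()), phase_map)
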