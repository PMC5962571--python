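"""Exact stochastic simulation of the transcription birth-death model.

Each gene is a time-inhomogeneous birth-death process: births (transcription)
at a piecewise-constant rate ``k(t)``, deaths (degradation) with propensity
``p * n``.  Because the rates are constant between window boundaries, the
standard Gillespie algorithm applies within each segment; a tentative event
that would cross a segment boundary is discarded and re-drawn from the
boundary, which is exact by the memoryless property.

Populations are simulated from anaphase of the previous cycle (cycle time
114 = 129 - 15) for 15 + 129 minutes, with per-minute snapshots; cycle time
is simulation time + 114 modulo 129.  Initial copy numbers are drawn
Poisson(k_low / p) per gene — the basal steady state, which is also (to
numerical accuracy) the periodic state at anaphase for the shipped
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import GeneParams, ModelSpec, segment_schedule
from .phases import PhaseMap

__all__ = [
    "SnapshotMatrix",
    "simulate_cell",
    "simulate_population",
    "population_noise_timecourse",
    "per_cell_temporal_cv",
    "phase_binned_counts",
    "ANAPHASE_SHIFT",
]

#: Minutes between the simulation start (anaphase) and cycle time 0.
ANAPHASE_SHIFT = 15.0


@njit(cache=False)
def _ssa_counts_at(bounds, rates, p, n0, snap_times, seed):  # pragma: no cover
    """SSA for one gene on a piecewise-constant schedule.

    bounds : float64[m+1] increasing segment edges covering the simulation
    rates  : float64[m] birth rate on [bounds[i], bounds[i+1])
    p      : death rate constant
    n0     : initial copy number
    snap_times : float64[s] increasing times in [bounds[0], bounds[-1]]
    Returns int64[s] copy numbers at the snapshot times.
    """
    np.random.seed(seed)
    out = np.empty(snap_times.size, dtype=np.int64)
    t = bounds[0]
    n = n0
    seg = 0
    isnap = 0
    while isnap < snap_times.size:
        seg_end = bounds[seg + 1]
        k = rates[seg]
        a = k + p * n
        if a <= 0.0:
            # no event possible until rates change
            t_next = seg_end
        else:
            t_next = t + np.random.exponential(1.0 / a)
        if t_next >= seg_end:
            # record snapshots up to the boundary, then re-draw from there
            while isnap < snap_times.size and snap_times[isnap] <= seg_end:
                out[isnap] = n
                isnap += 1
            t = seg_end
            if seg + 1 >= rates.size:
                # past the schedule end; remaining snapshots (== t_end) done
                while isnap < snap_times.size:
                    out[isnap] = n
                    isnap += 1
                break
            seg += 1
            continue
        # record snapshots strictly before the event
        while isnap < snap_times.size and snap_times[isnap] < t_next:
            out[isnap] = n
            isnap += 1
        t = t_next
        if np.random.random() * a < k:
            n += 1
        else:
            n -= 1
    return out


def _run_gene_ssa(
    bounds: np.ndarray,
    rates: np.ndarray,
    p: float,
    n0: int,
    snap_times: np.ndarray,
    seed: int,
) -> np.ndarray:
    return _ssa_counts_at(
        np.ascontiguousarray(bounds, dtype=np.float64),
        np.ascontiguousarray(rates, dtype=np.float64),
        float(p),
        np.int64(n0),
        np.ascontiguousarray(snap_times, dtype=np.float64),
        np.int64(seed),
    )


def _tiled_schedule(
    gene: GeneParams, cycle_length: float, t_origin: float, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute-time schedule starting at cycle time ``t_origin``.

    Tiles the periodic one-cycle schedule so that absolute time 0 maps to
    cycle time ``t_origin`` and the schedule covers ``[0, duration]``.
    """
    bounds1, rates1 = segment_schedule(gene, cycle_length)
    edges = [0.0]
    rates = []
    c = t_origin % cycle_length
    seg = min(int(np.searchsorted(bounds1, c, side="right")) - 1, len(rates1) - 1)
    t = 0.0
    while t < duration:
        seg_len = (bounds1[seg + 1] - c) if seg >= 0 else 0.0
        t_next = min(t + seg_len, duration)
        rates.append(rates1[seg])
        edges.append(t_next)
        t = t + seg_len
        seg += 1
        if seg >= len(rates1):
            seg = 0
        c = bounds1[seg]
    return np.asarray(edges), np.asarray(rates)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Per-stream 31-bit seeds derived from a master seed (counter-based)."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass
class SnapshotMatrix:
    """Per-minute copy numbers for a simulated population.

    ``counts`` has shape (n_cells, n_times, n_genes); ``times`` are
    simulation minutes (unit spacing from 0); ``sim_origin`` is the cycle
    time at simulation start, so cycle time = (sim_origin + time) mod cycle.
    """

    times: np.ndarray
    counts: np.ndarray
    genes: list[str]
    sim_origin: float
    cycle_length: float
    seed: int

    def __post_init__(self) -> None:
        if self.counts.shape[1] != self.times.size:
            raise ValueError("counts/time shape mismatch")
        if self.counts.shape[2] != len(self.genes):
            raise ValueError("counts/genes shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def cycle_times(self) -> np.ndarray:
        return (self.sim_origin + self.times) % self.cycle_length

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def cycle_slice(self) -> tuple[np.ndarray, np.ndarray]:
        """(minute indices, cycle times 0..T-1) of one full cycle.

        Selects the run of integer minutes whose cycle times are
        0, 1, ..., cycle_length - 1 (requires the snapshot grid to cover a
        full cycle after the anaphase lead-in).
        """
        T = int(round(self.cycle_length))
        idx = np.nonzero(np.isclose(self.cycle_times, 0.0))[0]
        idx = idx[idx + T <= self.times.size]
        if idx.size == 0:
            raise ValueError("snapshot grid does not cover one full cycle")
        i0 = int(idx[0])
        return np.arange(i0, i0 + T), self.cycle_times[i0 : i0 + T]


def simulate_cell(
    model: ModelSpec,
    t_start: float,
    duration: float,
    seed: int,
    snap_times: np.ndarray | None = None,
) -> np.ndarray:
    """Exact SSA trajectory of one cell; per-minute counts per gene.

    The cell starts at cycle time ``t_start`` with independent
    Poisson(k_low/p) initial counts per gene and is simulated for
    ``duration`` minutes.  Returns an (n_times, n_genes) array at
    ``snap_times`` (default: integer minutes 0..duration).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if snap_times is None:
        snap_times = np.arange(0.0, np.floor(duration) + 1.0)
    seeds = _spawn_seeds(seed, 2 * len(model.genes))
    rng_init = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = np.empty((len(snap_times), len(model.genes)), dtype=np.int64)
    for j, gene in enumerate(model.genes):
        n0 = int(rng_init.poisson(gene.basal_mean))
        bounds, rates = _tiled_schedule(gene, model.cycle_length, t_start, duration)
        out[:, j] = _run_gene_ssa(bounds, rates, gene.p, n0, snap_times, int(seeds[j]))
    return out


def simulate_population(
    model: ModelSpec, n_cells: int = 2000, seed: int = 0
) -> SnapshotMatrix:
    """Simulate ``n_cells`` independent cells from anaphase through the next
    full cycle (15 + cycle_length minutes), per-minute snapshots.

    Reproducible: per-cell RNG streams are derived from ``seed`` by a
    counter-based scheme, so results do not depend on iteration order.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    T = model.cycle_length
    origin = T - ANAPHASE_SHIFT
    duration = ANAPHASE_SHIFT + T
    times = np.arange(0.0, duration + 0.5)
    cell_seeds = _spawn_seeds(seed, n_cells)
    counts = np.empty((n_cells, times.size, len(model.genes)), dtype=np.int64)
    for i in range(n_cells):
        counts[i] = simulate_cell(model, origin, duration, int(cell_seeds[i]), times)
    return SnapshotMatrix(
        times=times,
        counts=counts,
        genes=model.gene_names,
        sim_origin=origin,
        cycle_length=T,
        seed=seed,
    )


def population_noise_timecourse(snap: SnapshotMatrix) -> np.ndarray:
    """Population noise CV(t) = sd/mean across cells, per minute per gene.

    Minutes with zero mean yield NaN (undefined), not an exception.
    Sample standard deviation (n-1 denominator).
    """
    if snap.n_cells < 2:
        raise ValueError("need at least 2 cells for a population CV")
    mean = snap.counts.mean(axis=0)
    sd = snap.counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv


def per_cell_temporal_cv(
    snap: SnapshotMatrix | np.ndarray,
) -> np.ndarray:
    """Temporal CV of each cell over one full cycle, per gene.

    For a SnapshotMatrix the cycle_length consecutive per-minute values
    covering cycle times 0..T-1 are used; a raw (n_cells, n_times, n_genes)
    array is used as-is.  Cells with zero temporal mean yield NaN.
    """
    if isinstance(snap, SnapshotMatrix):
        idx, _ = snap.cycle_slice()
        x = snap.counts[:, idx, :].astype(float)
    else:
        x = np.asarray(snap, dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, sd / mean, np.nan)


def phase_binned_counts(
    snap: SnapshotMatrix, pmap: PhaseMap, seed: int = 0
) -> "pd.DataFrame":
    """One fixed-cell observation per simulated cell (in silico smFISH).

    Each cell is assigned a uniform random cycle time (so phases are hit
    with probability proportional to their duration) and contributes its
    simulated counts at that minute, labelled with the phase.  Returns a
    long-format CellTable (cell_id, phase, gene, count).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    T = pmap.cycle_length
    idx_cycle, _ = snap.cycle_slice()
    u = rng.uniform(0.0, T, size=snap.n_cells)
    minute = np.floor(u).astype(int)  # cycle minute 0..T-1
    phases = np.asarray(pmap.phase_at(u), dtype=object)
    rows = {
        "cell_id": np.repeat(np.arange(snap.n_cells), len(snap.genes)),
        "phase": np.repeat(phases, len(snap.genes)),
        "gene": np.tile(np.asarray(snap.genes, dtype=object), snap.n_cells),
        "count": snap.counts[np.arange(snap.n_cells), idx_cycle[minute], :].reshape(-1),
    }
    return pd.DataFrame(rows)
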