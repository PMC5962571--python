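"""Synthetic data generation for the full analysis pipeline.

Emulates the data-generating process the analysis assumes: an asynchronous
population of fixed cells, each at a uniform random position of the cycle,
with per-gene mRNA counts from the cycle-scheduled birth-death model;
spot tables with long-tailed (lognormal, unit-median) intensity noise for
the quantification round trip; and stress experiments sampled at fixed
times after osmotic shock.

Two statistically equivalent routes produce cell tables: the fast path
draws counts from the analytic Poisson-mixture phase distributions, the SSA
path snapshots full Gillespie trajectories.  Intensity noise is lognormal
with unit median so that median normalization is exactly self-consistent.
Transcription-site flags are a synthetic convention: a cell with at least
three transcripts carries one nuclear multi-molecule spot with probability
proportional to the instantaneous transcription rate at its cycle position,
which makes TS-positive fractions peak in each gene's high-expression
phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec, periodic_mean_at, table1_model, transcription_rate
from .phases import PhaseMap
from .spots import TS_MIN_MOLECULES
from .stress import StressConfig, simulate_stress_population

__all__ = ["SynthConfig", "generate_cell_table", "generate_spot_table",
           "generate_stress_experiment"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic data generator.

    ``intensity_sigma`` is the lognormal shape of spot intensity noise
    around a unit median; ``ts_prob_high`` is the probability that a cell
    transcribing at the full high rate carries a visible transcription site
    (scaled down proportionally at lower instantaneous rates).
    """

    model: ModelSpec = field(default_factory=table1_model)
    n_cells: int = 2000
    intensity_sigma: float = 0.25
    ts_prob_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.intensity_sigma < 0:
            raise ValueError("intensity_sigma must be >= 0")
        if not (0 <= self.ts_prob_high <= 1):
            raise ValueError("ts_prob_high must be in [0, 1]")


def generate_cell_table(
    cfg: SynthConfig,
    pmap: PhaseMap | None = None,
    method: str = "analytic",
) -> pd.DataFrame:
    """Phase-labelled per-cell mRNA counts from the model.

    Each cell receives a uniform random cycle time (phases therefore appear
    with probability proportional to their duration).  ``method='analytic'``
    draws each count as Poisson with the periodic-state mean at that time —
    exactly the phase-mixture distribution; ``method='ssa'`` reads one
    snapshot per cell from a fresh Gillespie population.  Both paths are
    statistically indistinguishable.  Returns a long CellTable
    (cell_id, phase, gene, count, ts).
    """
    pmap = pmap if pmap is not None else cfg.model.phase_map
    model = cfg.model
    T = pmap.cycle_length
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5D]))
    u = rng.uniform(0.0, T, size=cfg.n_cells)
    phases = np.asarray(pmap.phase_at(u), dtype=object)
    if method == "analytic":
        counts_by_gene = {
            gene.name: rng.poisson(periodic_mean_at(gene, u, T))
            for gene in model.genes
        }
    elif method == "ssa":
        # one exact Gillespie trajectory per cell, read at the cell's own
        # (continuous) sampled time — same law as the analytic path
        from .simulate import ANAPHASE_SHIFT, simulate_cell
        from .simulate import _spawn_seeds

        seeds = _spawn_seeds(cfg.seed, cfg.n_cells)
        origin = T - ANAPHASE_SHIFT
        counts_arr = np.empty((cfg.n_cells, len(model.genes)), dtype=np.int64)
        for i in range(cfg.n_cells):
            t_read = ANAPHASE_SHIFT + u[i]
            counts_arr[i] = simulate_cell(
                model, origin, t_read + 1e-9, int(seeds[i]),
                snap_times=np.array([t_read]),
            )[0]
        counts_by_gene = {
            g.name: counts_arr[:, j] for j, g in enumerate(model.genes)
        }
    else:
        raise ValueError("method must be 'analytic' or 'ssa'")
    frames = [
        pd.DataFrame(
            {
                "cell_id": np.arange(cfg.n_cells),
                "phase": phases,
                "gene": gene.name,
                "count": counts_by_gene[gene.name],
            }
        )
        for gene in model.genes
    ]
    table = pd.concat(frames, ignore_index=True)
    cycle_time = pd.Series(np.tile(u, len(model.genes)), index=table.index)

    # synthetic transcription-site convention
    ts = np.zeros(len(table), dtype=int)
    for gene in model.genes:
        sel = (table["gene"] == gene.name).to_numpy()
        rate = np.asarray(
            transcription_rate(gene, cycle_time[sel].to_numpy(), T), dtype=float
        )
        prob = cfg.ts_prob_high * rate / gene.k_high
        eligible = table.loc[sel, "count"].to_numpy() >= TS_MIN_MOLECULES
        ts[sel] = (rng.uniform(size=sel.sum()) < prob) & eligible
    table["ts"] = ts
    return table


def generate_spot_table(cells: pd.DataFrame, cfg: SynthConfig) -> pd.DataFrame:
    """Inverse of spot quantification, for round-trip testing.

    Every mRNA becomes a single-molecule cytoplasmic spot, except that each
    transcription site aggregates ``3 + Poisson(1)`` molecules (capped by
    the cell's count) into one nuclear spot.  Intensities are
    molecules x Lognormal(0, sigma), whose median is exactly the
    single-molecule intensity, so median normalization recovers the truth
    at sigma = 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x59]))
    rows_cell, rows_gene, rows_mol, rows_nuc = [], [], [], []
    ts_col = cells["ts"] if "ts" in cells.columns else np.zeros(len(cells), int)
    for cell_id, gene, c, n_ts in zip(
        cells["cell_id"], cells["gene"], cells["count"], ts_col
    ):
        remaining = int(c)
        if remaining == 0:
            continue
        for _ in range(int(n_ts)):
            if remaining < TS_MIN_MOLECULES:
                break
            mol = min(TS_MIN_MOLECULES + int(rng.poisson(1.0)), remaining)
            rows_cell.append(cell_id)
            rows_gene.append(gene)
            rows_mol.append(mol)
            rows_nuc.append(True)
            remaining -= mol
        rows_cell.extend([cell_id] * remaining)
        rows_gene.extend([gene] * remaining)
        rows_mol.extend([1] * remaining)
        rows_nuc.extend([False] * remaining)
    mol = np.asarray(rows_mol, dtype=float)
    noise = (
        rng.lognormal(mean=0.0, sigma=cfg.intensity_sigma, size=mol.size)
        if cfg.intensity_sigma > 0
        else np.ones(mol.size)
    )
    return pd.DataFrame(
        {
            "spot_id": np.arange(mol.size),
            "cell_id": rows_cell,
            "gene": rows_gene,
            "intensity": mol * noise,
            "nuclear": rows_nuc,
        }
    )


def generate_stress_experiment(
    cfg: SynthConfig, stress: StressConfig, n_cells: int | None = None
) -> dict[float, pd.DataFrame]:
    """Stress-experiment fixture: one CellTable per sampling time.

    Thin wrapper over the stress simulator, emitting the observed-data
    dialect (cell_id, phase, gene, count) at each of the configured
    sampling times.
    """
    return simulate_stress_population(
        cfg.model, stress, n_cells=n_cells or cfg.n_cells, seed=cfg.seed
    )
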