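"""smFISH spot-level quantification and per-phase descriptive statistics.

Detected fluorescent spots are converted to molecule counts by normalizing
each spot's intensity to the median intensity of that gene's spot
population (a single mRNA defines the unit intensity); nuclear spots
carrying at least three mRNA equivalents are called transcription sites
(TS).  Per-cell counts are the sum of molecule calls over a cell's spots.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .phases import PhaseMap

__all__ = [
    "molecules_per_spot",
    "quantify_cells",
    "call_transcription_sites",
    "phase_summary",
    "TS_MIN_MOLECULES",
]

#: A nuclear spot with at least this many mRNA equivalents is a
#: transcription site.
TS_MIN_MOLECULES = 3

SPOT_COLUMNS = ("spot_id", "cell_id", "gene", "intensity", "nuclear")


def _check_spots(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    if (spots["intensity"] <= 0).any():
        raise ValueError("spot intensities must be > 0")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def molecules_per_spot(spots: pd.DataFrame, gene: str) -> pd.Series:
    """Integer molecule count per spot for one gene.

    Each intensity is divided by the median intensity of the gene's spot
    population, rounded half-away-from-zero, and floored at one molecule
    (upstream detection already rejected sub-threshold noise).  Indexed like
    the gene's rows in ``spots``.
    """
    _check_spots(spots)
    sub = spots[spots["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no spots for gene {gene!r}")
    med = float(sub["intensity"].median())
    mol = _round_half_away(sub["intensity"].to_numpy(float) / med)
    return pd.Series(np.maximum(mol, 1).astype(int), index=sub.index, name="molecules")


def call_transcription_sites(spots: pd.DataFrame, gene: str) -> pd.Series:
    """Transcription-site count per cell for one gene.

    A TS is a nuclear spot containing at least three mRNA molecules;
    cytoplasmic spots are never TS.  Cells of the gene with no qualifying
    spot report 0.
    """
    mol = molecules_per_spot(spots, gene)
    sub = spots.loc[mol.index]
    is_ts = sub["nuclear"].astype(bool) & (mol >= TS_MIN_MOLECULES)
    per_cell = is_ts.groupby(sub["cell_id"]).sum()
    return per_cell.reindex(sub["cell_id"].unique(), fill_value=0).astype(int)


def quantify_cells(
    spots: pd.DataFrame, phases: Mapping | pd.Series | None = None
) -> pd.DataFrame:
    """Spot table -> CellTable (cell_id, phase, gene, count, ts).

    Per-cell mRNA count is the sum of molecule calls over the cell's spots;
    ``ts`` is the number of transcription sites.  ``phases`` maps cell_id to
    phase label (omitted -> phase column left as 'NA' placeholder for
    downstream joining).
    """
    _check_spots(spots)
    frames = []
    for gene in sorted(spots["gene"].unique()):
        mol = molecules_per_spot(spots, gene)
        sub = spots.loc[mol.index]
        counts = mol.groupby(sub["cell_id"]).sum()
        ts = call_transcription_sites(spots, gene)
        df = pd.DataFrame(
            {
                "cell_id": counts.index,
                "gene": gene,
                "count": counts.to_numpy(int),
                "ts": ts.reindex(counts.index, fill_value=0).to_numpy(int),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if phases is not None:
        pmap_series = pd.Series(phases)
        out.insert(1, "phase", out["cell_id"].map(pmap_series))
        if out["phase"].isna().any():
            bad = out.loc[out["phase"].isna(), "cell_id"].unique()[:5]
            raise ValueError(f"no phase label for cells {list(bad)}")
    else:
        out.insert(1, "phase", "NA")
    return out


def phase_summary(
    cells: pd.DataFrame,
    pmap: PhaseMap,
    min_count: int = 1,
) -> pd.DataFrame:
    """Descriptive per-phase, per-gene statistics of a CellTable.

    Returns one row per (gene, phase) with n, mean, median, SEM, CV
    (sample sd / mean; NaN where the mean is 0), the fraction of cells with
    at least ``min_count`` transcripts, and — when a ``ts`` column is
    present — the fraction of cells with at least one transcription site.
    """
    for col in ("phase", "gene", "count"):
        if col not in cells.columns:
            raise ValueError(f"cell table missing column {col!r}")
    unknown = set(cells["phase"].unique()) - set(pmap.phase_names)
    if unknown:
        raise ValueError(f"unknown phase labels: {sorted(unknown)}")
    has_ts = "ts" in cells.columns
    rows = []
    for (gene, phase), grp in cells.groupby(["gene", "phase"], sort=True):
        x = grp["count"].to_numpy(float)
        n = x.size
        mean = x.mean()
        sd = x.std(ddof=1) if n > 1 else math.nan
        rows.append(
            {
                "gene": gene,
                "phase": phase,
                "n": n,
                "mean": mean,
                "median": float(np.median(x)),
                "sem": sd / math.sqrt(n) if n > 1 else math.nan,
                "cv": sd / mean if (n > 1 and mean > 0) else math.nan,
                f"frac_ge_{min_count}": float((x >= min_count).mean()),
                "frac_ts": float((grp["ts"] >= 1).mean()) if has_ts else math.nan,
            }
        )
    out = pd.DataFrame(rows)
    order = {p: i for i, p in enumerate(pmap.phase_names)}
    return (
        out.assign(_o=out["phase"].map(order))
        .sort_values(["gene", "_o"])
        .drop(columns="_o")
        .reset_index(drop=True)
    )
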