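"""Seven-phase partition of the budding-yeast cell cycle.

An asynchronous fixed-cell population is "synchronized in silico" by
assigning each cell a cell-cycle phase from morphological markers and
converting the observed phase occupancy into time: the duration of a phase
is proportional to the fraction of cells found in it.  The canonical
partition used throughout this package is

    early G1 (eG1), late G1 (lG1), S, G2, prometa-/metaphase (P/M),
    anaphase (Ana), telophase/cytokinesis (T/C)

on a cycle of 129 minutes.  Phase intervals are half-open ``[start, end)``
and times wrap modulo the cycle length, with t = 0 at the start of early G1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

PHASE_NAMES: tuple[str, ...] = ("eG1", "lG1", "S", "G2", "P/M", "Ana", "T/C")

DEFAULT_CYCLE_LENGTH = 129.0

#: Default phase occupancy fractions.  eG1 (0.211), G2 (0.166) and T/C (0.03)
#: are measured values for unstressed cells; the remaining fractions are
#: package defaults chosen so that Ana + T/C spans ~15 min (the anaphase →
#: cycle-start offset used by the simulator).  Fully configurable.
DEFAULT_PHASE_FRACTIONS: Mapping[str, float] = {
    "eG1": 0.211,
    "lG1": 0.180,
    "S": 0.180,
    "G2": 0.166,
    "P/M": 0.147,
    "Ana": 0.086,
    "T/C": 0.030,
}


class PhaseMapError(ValueError):
    """Invalid phase-map input (zero counts, bad labels, bad durations)."""


@dataclass(frozen=True)
class PhaseMap:
    """Ordered 7-phase partition of the cell cycle.

    Parameters
    ----------
    durations
        Minutes spent in each phase, in canonical phase order.  Must be
        positive and sum to ``cycle_length``.
    cycle_length
        Total cycle length in minutes (default 129).
    """

    durations: tuple[float, ...]
    cycle_length: float = DEFAULT_CYCLE_LENGTH
    phase_names: tuple[str, ...] = PHASE_NAMES
    boundaries: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.phase_names) != 7 or tuple(self.phase_names) != PHASE_NAMES:
            raise PhaseMapError(
                f"phase_names must be {PHASE_NAMES} in order, got {self.phase_names}"
            )
        if len(self.durations) != 7:
            raise PhaseMapError("exactly 7 phase durations required")
        if any(d <= 0 for d in self.durations):
            bad = self.phase_names[[d <= 0 for d in self.durations].index(True)]
            raise PhaseMapError(f"phase {bad!r} has non-positive duration")
        if abs(sum(self.durations) - self.cycle_length) > 1e-9:
            raise PhaseMapError(
                f"durations sum to {sum(self.durations)}, expected {self.cycle_length}"
            )
        bounds = np.concatenate([[0.0], np.cumsum(self.durations)])
        bounds[-1] = self.cycle_length  # exact upper edge
        object.__setattr__(self, "boundaries", bounds)

    # -- queries ---------------------------------------------------------

    def phase_at(self, t: float | np.ndarray) -> str | np.ndarray:
        """Phase label containing cycle time ``t`` (reduced modulo the cycle).

        Total function: any real ``t`` is first wrapped into
        ``[0, cycle_length)``; the phase whose half-open interval contains
        the reduced time is returned.
        """
        tt = np.asarray(t, dtype=float) % self.cycle_length
        # tiny negative t can round the modulo up to exactly cycle_length
        tt = np.where(tt >= self.cycle_length, 0.0, tt)
        idx = np.clip(
            np.searchsorted(self.boundaries, tt, side="right") - 1, 0, 6
        )
        labels = np.asarray(self.phase_names, dtype=object)[idx]
        if np.ndim(t) == 0:
            return str(np.asarray(labels).item())
        return labels

    def phase_index_at(self, t: np.ndarray) -> np.ndarray:
        """Integer phase index (0..6) for an array of cycle times."""
        tt = np.asarray(t, dtype=float) % self.cycle_length
        tt = np.where(tt >= self.cycle_length, 0.0, tt)
        return np.clip(np.searchsorted(self.boundaries, tt, side="right") - 1, 0, 6)

    def phase_interval(self, phase: str) -> tuple[float, float]:
        """Half-open interval ``[start, end)`` of ``phase`` in cycle minutes."""
        i = self.index(phase)
        return float(self.boundaries[i]), float(self.boundaries[i + 1])

    def index(self, phase: str) -> int:
        try:
            return self.phase_names.index(phase)
        except ValueError:
            raise PhaseMapError(
                f"unknown phase label {phase!r}; expected one of {self.phase_names}"
            ) from None

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.durations) / self.cycle_length

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"name": n, "duration": float(d)}
                for n, d in zip(self.phase_names, self.durations)
            ],
            "cycle_length": float(self.cycle_length),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhaseMap":
        phases = d["phases"]
        names = tuple(p["name"] for p in phases)
        if names != PHASE_NAMES:
            raise PhaseMapError(f"phase names {names} not in canonical order")
        return cls(
            durations=tuple(float(p["duration"]) for p in phases),
            cycle_length=float(d.get("cycle_length", DEFAULT_CYCLE_LENGTH)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhaseMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_phase_map(
    phase_counts: Mapping[str, int] | Sequence[int],
    cycle_length: float = DEFAULT_CYCLE_LENGTH,
) -> PhaseMap:
    """Convert observed phase occupancy into phase durations.

    Each phase's duration is ``cycle_length * count / total`` — the in
    silico synchronization step: the fraction of an asynchronous population
    observed in a phase estimates the fraction of the cycle spent there.

    Parameters
    ----------
    phase_counts
        Cell counts per phase, either a mapping keyed by the canonical
        labels or a sequence of 7 counts in canonical order.  Every phase
        must have a strictly positive count.
    """
    if isinstance(phase_counts, Mapping):
        missing = [n for n in PHASE_NAMES if n not in phase_counts]
        if missing:
            raise PhaseMapError(f"missing counts for phases: {missing}")
        counts = [phase_counts[n] for n in PHASE_NAMES]
    else:
        counts = list(phase_counts)
        if len(counts) != 7:
            raise PhaseMapError("expected 7 phase counts")
    counts_arr = np.asarray(counts, dtype=float)
    if np.any(counts_arr < 0):
        bad = PHASE_NAMES[int(np.argmax(counts_arr < 0))]
        raise PhaseMapError(f"negative count for phase {bad!r}")
    total = counts_arr.sum()
    if total <= 0:
        raise PhaseMapError("total phase count is zero")
    zero = counts_arr == 0
    if np.any(zero):
        bad = PHASE_NAMES[int(np.argmax(zero))]
        raise PhaseMapError(f"phase {bad!r} has zero count; duration undefined")
    durations = cycle_length * counts_arr / total
    # enforce exact sum despite float rounding
    durations[-1] = cycle_length - durations[:-1].sum()
    return PhaseMap(durations=tuple(durations), cycle_length=cycle_length)


def default_phase_map(cycle_length: float = DEFAULT_CYCLE_LENGTH) -> PhaseMap:
    """PhaseMap from the package's default occupancy fractions."""
    durations = np.array(
        [DEFAULT_PHASE_FRACTIONS[n] for n in PHASE_NAMES], dtype=float
    ) * cycle_length
    durations[-1] = cycle_length - durations[:-1].sum()
    return PhaseMap(durations=tuple(durations), cycle_length=cycle_length)


def read_phase_counts_csv(path: str | Path) -> dict[str, int]:
    """Read a two-column ``phase,count`` CSV into a mapping."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if not {"phase", "count"}.issubset(df.columns):
        raise PhaseMapError(f"{path}: expected columns phase,count, got {list(df.columns)}")
    return {str(r.phase): int(r.count) for r in df.itertuples()}
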