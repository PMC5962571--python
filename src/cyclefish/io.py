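"""File I/O: cell tables, spot tables, model files, result objects.

Conventions: CSV with a header row, UTF-8, '.' decimal, counts strictly
integer; JSON for nested results; YAML (or JSON) for model and config
files.  Writers prepend provenance comment lines (version, seed, config
hash) starting with '#', which all readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .model import ModelSpec, _model_from_mapping
from .phases import PHASE_NAMES, PhaseMap

__all__ = [
    "SchemaError",
    "read_cell_table",
    "write_cell_table",
    "read_spot_table",
    "write_spot_table",
    "read_model",
    "write_model",
    "write_results",
    "read_results",
]

CELL_COLUMNS = ("cell_id", "phase", "gene", "count")
SPOT_COLUMNS = ("spot_id", "cell_id", "gene", "intensity", "nuclear")


class SchemaError(ValueError):
    """A data file violates the expected schema (offending rows named)."""


def _provenance_lines(seed: int | None, config: Any | None) -> list[str]:
    h = "-"
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        h = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return [
        f"# cyclefish {__version__}",
        f"# seed: {'-' if seed is None else seed}",
        f"# config_hash: {h}",
    ]


def _write_csv_with_header(
    df: pd.DataFrame, path: str | Path, seed: int | None, config: Any | None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\n".join(_provenance_lines(seed, config)) + "\n")
        df.to_csv(fh, index=False)


def write_cell_table(
    table: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: Any | None = None,
) -> None:
    """Write a CellTable CSV (cell_id, phase, gene, count [, ts])."""
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    cols = [c for c in (*CELL_COLUMNS, "ts") if c in table.columns]
    _write_csv_with_header(table[cols], path, seed, config)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a CellTable CSV.

    Counts must be non-negative integers and phase labels canonical;
    malformed rows are reported with their line position.
    """
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("count",) + (("ts",) if "ts" in df.columns else ()):
        as_num = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[as_num.isna() | (as_num != as_num.round()) | (as_num < 0)]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # 1-based + header
            raise SchemaError(
                f"{path}: column {col!r} must be a non-negative integer "
                f"(offending data rows: {rows})"
            )
        df[col] = as_num.astype(int)
    unknown = sorted(set(df["phase"].astype(str)) - set(PHASE_NAMES) - {"NA"})
    if unknown:
        raise SchemaError(f"{path}: unknown phase labels {unknown}")
    return df


def write_spot_table(
    spots: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: Any | None = None,
) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise SchemaError(f"spot table missing columns: {missing}")
    _write_csv_with_header(spots[list(SPOT_COLUMNS)], path, seed, config)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if (pd.to_numeric(df["intensity"], errors="coerce") <= 0).any() or df[
        "intensity"
    ].isna().any():
        raise SchemaError(f"{path}: intensities must be positive numbers")
    df["nuclear"] = df["nuclear"].astype(bool)
    return df


def read_model(path: str | Path, phase_map: PhaseMap | None = None) -> ModelSpec:
    """Read a model file (YAML or JSON) into a ModelSpec."""
    path = Path(path)
    d = yaml.safe_load(path.read_text())
    try:
        return _model_from_mapping(d, phase_map)
    except (KeyError, TypeError) as e:
        raise SchemaError(f"{path}: malformed model file ({e})") from e


def write_model(model: ModelSpec, path: str | Path) -> None:
    d = {
        "cycle_length": model.cycle_length,
        "genes": [
            {
                "name": g.name,
                "k_high": g.k_high,
                "k_low": g.k_low,
                "p": g.p,
                "windows": [list(w) for w in g.windows],
            }
            for g in model.genes
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_results(
    obj: Mapping | list, path: str | Path, seed: int | None = None,
    config: Any | None = None,
) -> None:
    """Write a result object as JSON with an embedded provenance block."""
    payload = {
        "provenance": {
            "package": "cyclefish",
            "version": __version__,
            "seed": seed,
            "config_hash": _provenance_lines(seed, config)[2].split(": ")[1],
        },
        "results": obj,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
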