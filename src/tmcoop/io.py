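"""Validated table readers/writers and run manifests shared by the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableError", "read_table", "write_table", "write_manifest", "write_pgm",
           "SCHEMAS"]

# column name -> (dtype, optional row validator)
SCHEMAS: dict[str, dict] = {
    "first_binding": {
        "t_bind_s": float,
        "position_nm": float,
        "age_s": float,
        "filament_length_nm": float,
        "censored": bool,
    },
    "second_binding": {
        "La": int,
        "L1": int,
        "x1": int,
        "L2": int,
        "overlapped": bool,
    },
    "residence": {"duration_s": float, "censored": bool},
    "occupancy_curve": {"concentration_uM": float, "occupancy": float},
}

_ROW_CHECKS = {
    "residence": lambda r: r["duration_s"] > 0 or "duration_s must be positive",
    "second_binding": lambda r: (
        r["L1"] / (2.0 * r["La"]) <= 0.5 or "initial occupancy exceeds 50%"
    ),
    "occupancy_curve": lambda r: (
        0.0 <= r["occupancy"] <= 1.0 or "occupancy outside [0, 1]"
    ),
}


class TableError(ValueError):
    """Malformed input table (missing columns, bad cells, broken invariants)."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Errors name the offending column or 1-based data row.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise TableError(f"{path}: cannot read CSV: {err}") from err
    missing = set(cols) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(cols)]
    for name, dtype in cols.items():
        if dtype is bool:
            vals = df[name]
            if vals.dtype != bool:
                lowered = vals.astype(str).str.strip().str.lower()
                bad = ~lowered.isin(["true", "false", "0", "1"])
                if bad.any():
                    row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
                    raise TableError(
                        f"{path}: row {row}: non-boolean value in '{name}'"
                    )
                df[name] = lowered.isin(["true", "1"])
        else:
            coerced = pd.to_numeric(df[name], errors="coerce")
            bad = coerced.isna() & df[name].notna()
            if bad.any() or coerced.isna().any():
                row = int(np.nonzero(coerced.isna().to_numpy())[0][0]) + 1
                raise TableError(f"{path}: row {row}: non-numeric value in '{name}'")
            df[name] = coerced.astype(dtype)
    check = _ROW_CHECKS.get(schema)
    if check is not None and len(df):
        for k, (_, r) in enumerate(df.iterrows(), start=1):
            res = check(r)
            if isinstance(res, str):
                raise TableError(f"{path}: row {k}: {res}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_manifest(out_dir: str | Path, **entries) -> Path:
    """Record inputs, parameters and seed of a run as JSON."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"tmcoop_version": __version__, **_jsonable(entries)}
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_pgm(path: str | Path, matrix: np.ndarray, max_val: int = 2) -> Path:
    """Export a small non-negative integer matrix as a plain-text (P2) PGM.

    Sentinel -1 entries are rendered as 0.
    """
    m = np.clip(np.asarray(matrix, dtype=int), 0, max_val)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"P2\n{m.shape[1]} {m.shape[0]}\n{max_val}\n"]
    for row in m:
        lines.append(" ".join(str(v) for v in row) + "\n")
    path.write_text("".join(lines))
    return path
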