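"""Synthetic input tables with known ground truth.

Every generator emulates one of the tabular inputs the analysis consumes
(first-binding events, second-binding geometries, residence times,
occupancy curves) using the statistical structure the corresponding model
assumes, writes CSV plus a metadata JSON carrying the ground-truth
parameters and seed, and is byte-reproducible under a fixed seed.
Downstream recovery tests read the truth only from the metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .firstbind import FirstBindingParams, simulate_first_binding_batch
from .secondbind import SecondBindingGeometry, overlap_probability

__all__ = [
    "gen_first_binding",
    "gen_second_binding",
    "gen_residence",
    "gen_occupancy_curve",
    "write_outputs",
]


def write_outputs(
    df: pd.DataFrame, metadata: dict, out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write table as CSV and ground-truth metadata as JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    meta_path = out / f"{stem}.meta.json"
    df.to_csv(csv_path, index=False, lineterminator="\n")
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return csv_path, meta_path


def gen_first_binding(
    kon_len: float = 4e-6,
    v_grow: float = 47.5,
    n: int = 500,
    seed: int = 0,
    max_time: float = 2000.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """First-binding events from the discrete-time growing-filament model."""
    params = FirstBindingParams(
        kon_len=kon_len, v_grow=v_grow, max_time=max_time, seed=seed
    )
    events = simulate_first_binding_batch(params, n)
    df = pd.DataFrame(
        {
            "t_bind_s": [e.t_bind for e in events],
            "position_nm": [e.position_nm for e in events],
            "age_s": [e.age_s for e in events],
            "filament_length_nm": [e.filament_length_nm for e in events],
            "censored": [e.censored for e in events],
        }
    )
    meta = {
        "table": "first_binding",
        "kon_len": kon_len,
        "v_grow": v_grow,
        "n": n,
        "seed": seed,
        "max_time": max_time,
        "dt": params.effective_dt,
    }
    if out_dir is not None:
        write_outputs(df, meta, out_dir, "first_binding")
    return df, meta


def gen_second_binding(
    c_true: float = 1.0,
    n: int = 37,
    seed: int = 0,
    la_range: tuple[int, int] = (5, 60),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Second-binding geometries with overlap flags drawn Bernoulli(p2).

    Geometry distributions are not constrained by the source data (only the
    measured events exist), so defaults are chosen to populate all three
    occupancy bins: filament length uniform on ``la_range`` grid units,
    first cable uniform up to the filament length (occupancy then spreads
    over 0-50%), second cable up to a third of the filament.
    """
    rng = np.random.default_rng(seed)
    rows = []
    while len(rows) < n:
        La = int(rng.integers(la_range[0], la_range[1] + 1))
        L1 = int(rng.integers(1, La + 1))
        x1 = int(rng.integers(0, La - L1 + 1))
        L2 = int(rng.integers(1, max(2, La // 3) + 1))
        geom = SecondBindingGeometry(La, L1, x1, L2)
        try:
            p2 = overlap_probability(geom, c_true)
        except ValueError:
            continue  # no admissible placement for this draw
        overlapped = bool(rng.random() < p2)
        rows.append((La, L1, x1, L2, overlapped))
    df = pd.DataFrame(rows, columns=["La", "L1", "x1", "L2", "overlapped"])
    meta = {
        "table": "second_binding",
        "c_true": c_true,
        "n": n,
        "seed": seed,
        "la_range": list(la_range),
    }
    if out_dir is not None:
        write_outputs(df, meta, out_dir, "second_binding")
    return df, meta


def gen_residence(
    T1: float = 65.0,
    censor_time: float = 200.0,
    n: int = 500,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Exponential residence times right-censored at the observation end."""
    rng = np.random.default_rng(seed)
    draws = rng.exponential(T1, size=n)
    censored = draws > censor_time
    durations = np.where(censored, censor_time, draws)
    df = pd.DataFrame({"duration_s": durations, "censored": censored})
    meta = {
        "table": "residence",
        "T1": T1,
        "censor_time": censor_time,
        "n": n,
        "seed": seed,
    }
    if out_dir is not None:
        write_outputs(df, meta, out_dir, "residence")
    return df, meta


def gen_occupancy_curve(
    n_hill: float = 14.6,
    ec50: float = 1.2,
    concentrations=None,
    sigma: float = 0.02,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Hill-shaped occupancy curve with truncated Gaussian noise on theta."""
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.geomspace(ec50 / 2.0, ec50 * 2.0, 8)
    L = np.asarray(concentrations, dtype=float)
    theta = L**n_hill / (ec50**n_hill + L**n_hill)
    noisy = np.clip(theta + rng.normal(0.0, sigma, size=L.size), 0.0, 1.0)
    df = pd.DataFrame({"concentration_uM": L, "occupancy": noisy})
    meta = {
        "table": "occupancy_curve",
        "n_hill": n_hill,
        "ec50": ec50,
        "sigma": sigma,
        "seed": seed,
        "concentrations": [float(x) for x in L],
    }
    if out_dir is not None:
        write_outputs(df, meta, out_dir, "occupancy_curve")
    return df, meta
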