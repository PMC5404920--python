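"""TIRFM-like observation model for simulated lattice trajectories.

Raw occupancy is converted to an image-like signal by the same three steps
used to compare simulations with microscopy: (1) only a fraction of
molecules carry a dye, so occupied sites are kept with probability
``labeled_fraction`` (default 0.2, i.e. 80% of occupied sites are blanked);
(2) optical resolution is ~100 nm, so each visible site is broadened by
dilation over +/- 4 sites within its row; (3) the two rows are summed to a
fluorescence level of 0, 1 or 2 per site.  Coverage statistics
(total/single/double occupancy) are always computed on the raw occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import math
import numpy as np
from scipy.ndimage import maximum_filter1d

from .constants import SITE_LENGTH_NM
from .lattice import LatticeParams, LatticeState, Trajectory, simulate

__all__ = [
    "ObservationSettings",
    "Kymograph",
    "CoverageSummary",
    "apply_labeling",
    "broaden",
    "sum_rows",
    "coverage_summary",
    "coverage_at_length",
    "CoverageAtLength",
    "render_kymograph",
    "estimate_boundary_velocity",
]


@dataclass(frozen=True)
class ObservationSettings:
    """Parameters of the imaging emulation.

    labeling_mode 'per-molecule' assigns a persistent dye flag to each
    molecule when it binds (temporally coherent kymographs); 'per-snapshot'
    resamples which occupied sites are visible independently in every frame.
    For a single snapshot the two are statistically identical.
    """

    labeled_fraction: float = 0.2
    broadening_radius_sites: int = 4  # ~100 nm at 21.6 nm per site
    frame_interval: float = 10.0
    labeling_mode: str = "per-molecule"

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.broadening_radius_sites < 0:
            raise ValueError("broadening radius must be >= 0")
        if self.labeling_mode not in ("per-molecule", "per-snapshot"):
            raise ValueError("labeling_mode must be 'per-molecule' or 'per-snapshot'")


@dataclass
class Kymograph:
    """frames x sites fluorescence matrix; -1 marks 'beyond the barbed end'."""

    values: np.ndarray
    frame_times: np.ndarray
    site_length_nm: float = SITE_LENGTH_NM

    @property
    def frame_interval(self) -> float:
        if len(self.frame_times) < 2:
            return float("nan")
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass(frozen=True)
class CoverageSummary:
    """Raw coverage fractions; total = (single + 2 * double) / 2."""

    total_occupancy: float
    single_fraction: float
    double_fraction: float


def apply_labeling(
    occupancy: np.ndarray,
    settings: ObservationSettings,
    rng: np.random.Generator,
    labeled_molecules: np.ndarray | None = None,
    molecule_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Blank unlabeled molecules: keep each occupied site w.p. labeled_fraction.

    In per-molecule mode pass ``molecule_ids`` (site -> molecule, -1 where
    empty) and the persistent ``labeled_molecules`` boolean lookup; in
    per-snapshot mode visibility is drawn Bernoulli per occupied site.
    """
    occ = np.asarray(occupancy)
    if settings.labeled_fraction == 1.0:
        return occ.astype(np.int8).copy()
    if molecule_ids is not None and labeled_molecules is not None:
        vis = np.zeros_like(occ, dtype=np.int8)
        bound = (occ == 1) & (molecule_ids >= 0)
        vis[bound] = labeled_molecules[molecule_ids[bound]]
        return vis
    keep = rng.random(occ.shape) < settings.labeled_fraction
    return (occ.astype(bool) & keep).astype(np.int8)


def broaden(row: np.ndarray, radius: int) -> np.ndarray:
    """Dilate a binary row by +/- radius sites, clipped at the filament ends."""
    row = np.asarray(row, dtype=np.int8)
    if radius == 0 or row.size == 0:
        return row.copy()
    return maximum_filter1d(row, size=2 * radius + 1, mode="constant", cval=0)


def sum_rows(row0: np.ndarray, row1: np.ndarray) -> np.ndarray:
    """Elementwise sum of the two broadened rows -> fluorescence in {0,1,2}."""
    return np.asarray(row0, dtype=np.int8) + np.asarray(row1, dtype=np.int8)


def process_snapshot(
    occupancy: np.ndarray,
    settings: ObservationSettings,
    rng: np.random.Generator,
    **labeling_kwargs,
) -> np.ndarray:
    """label -> broaden -> sum, in that fixed order."""
    vis = apply_labeling(occupancy, settings, rng, **labeling_kwargs)
    r = settings.broadening_radius_sites
    return sum_rows(broaden(vis[0], r), broaden(vis[1], r))


def coverage_summary(state: LatticeState) -> CoverageSummary:
    """Single/double/total coverage fractions of the raw occupancy."""
    if state.N == 0:
        raise ValueError("zero-length filament")
    col = state.occupancy.sum(axis=0)
    single = float((col == 1).mean())
    double = float((col == 2).mean())
    return CoverageSummary(
        total_occupancy=(single + 2 * double) / 2.0,
        single_fraction=single,
        double_fraction=double,
    )


@dataclass
class CoverageAtLength:
    """Replicate-averaged readout of growing filaments at a target length."""

    mean_fluorescence: float  # in [0, 2]
    fluorescence_per_rep: np.ndarray
    total_occupancy: float
    single_fraction: float
    double_fraction: float
    n_rep: int
    target_sites: int


def coverage_at_length(
    params: LatticeParams,
    settings: ObservationSettings,
    target_length_um: float = 6.0,
    n_rep: int = 24,
    rng: np.random.Generator | None = None,
) -> CoverageAtLength:
    """Processed fluorescence averaged over replicates at a target length.

    Each replicate filament is simulated until it first reaches the target
    length (6 um by default, matching the quantification frame used for
    experiments), its final snapshot is passed through the
    label/broaden/sum pipeline, and the fluorescence level is averaged over
    sites and replicates.  Raw coverage fractions are averaged alongside.
    """
    if params.v_grow <= 0:
        raise ValueError("coverage_at_length needs a growing filament (v_grow > 0)")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    target_sites = int(math.ceil(target_length_um * 1000.0 / params.site_length_nm))
    if target_sites / params.v_grow > params.max_time:
        raise ValueError(
            f"target length {target_length_um} um ({target_sites} sites) is not "
            f"reachable before max_time={params.max_time} s at v_grow={params.v_grow}"
        )
    fluor = np.empty(n_rep)
    tot = np.empty(n_rep)
    single = np.empty(n_rep)
    double = np.empty(n_rep)
    for r in range(n_rep):
        rep_params = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        traj = simulate(rep_params, stop_at_n=target_sites, log_events=False)
        if traj.final_state.N < target_sites:
            raise RuntimeError(
                f"replicate {r} ended at N={traj.final_state.N} < {target_sites} "
                f"before max_time={params.max_time} s"
            )
        state = traj.final_state
        fl = process_snapshot(state.occupancy, settings, rng)
        fluor[r] = fl.mean()
        cs = coverage_summary(state)
        tot[r] = cs.total_occupancy
        single[r] = cs.single_fraction
        double[r] = cs.double_fraction
    return CoverageAtLength(
        mean_fluorescence=float(fluor.mean()),
        fluorescence_per_rep=fluor,
        total_occupancy=float(tot.mean()),
        single_fraction=float(single.mean()),
        double_fraction=float(double.mean()),
        n_rep=n_rep,
        target_sites=target_sites,
    )


def _molecule_grids(traj: Trajectory, frame_times: np.ndarray) -> list[np.ndarray]:
    """molecule-id grid (-1 empty) at each frame time, by one replay pass."""
    occ0 = traj.initial_occupancy
    cap = occ0.shape[1]
    grid = np.full((2, cap), -1, dtype=np.int64)
    next_id = 0
    for j, i in zip(*np.nonzero(occ0)):
        grid[j, i] = next_id
        next_id += 1
    out = []
    k = 0
    from ._kernels import EV_BIND, EV_GROW

    for ft in frame_times:
        while k < traj.n_events and traj.times[k] <= ft:
            code = traj.codes[k]
            if code == EV_GROW:
                n_new = int(traj.sites[k])
                if n_new > grid.shape[1]:
                    pad = np.full((2, n_new - grid.shape[1]), -1, dtype=np.int64)
                    grid = np.concatenate([grid, pad], axis=1)
            elif code == EV_BIND:
                grid[traj.rows[k], traj.sites[k]] = next_id
                next_id += 1
            else:
                grid[traj.rows[k], traj.sites[k]] = -1
            k += 1
        out.append(grid.copy())
    return out


def render_kymograph(
    traj: Trajectory,
    settings: ObservationSettings,
    rng: np.random.Generator | None = None,
) -> Kymograph:
    """Process trajectory snapshots at frame_interval into a kymograph.

    Columns beyond the barbed end at a given frame carry the sentinel -1.
    """
    if rng is None:
        rng = np.random.default_rng(traj.seed)
    t_end = traj.final_state.t
    frame_times = np.arange(0.0, t_end + 1e-12, settings.frame_interval)
    snaps = traj.snapshots(frame_times)
    n_max = max(s.N for s in snaps)

    if settings.labeling_mode == "per-molecule":
        grids = _molecule_grids(traj, frame_times)
        n_mol = 1 + max((g.max() for g in grids), default=0)
        labeled = rng.random(max(n_mol, 1)) < settings.labeled_fraction
    values = np.full((len(frame_times), n_max), -1, dtype=np.int8)
    for f, s in enumerate(snaps):
        occ = s.occupancy
        if settings.labeling_mode == "per-molecule":
            g = grids[f][:, : occ.shape[1]]
            fl = process_snapshot(
                occ, settings, rng, labeled_molecules=labeled, molecule_ids=g
            )
        else:
            fl = process_snapshot(occ, settings, rng)
        values[f, : occ.shape[1]] = fl
    return Kymograph(values=values, frame_times=frame_times, site_length_nm=traj.params.site_length_nm)


def estimate_boundary_velocity(
    kymo: Kymograph,
    min_duration_s: float = 15.0,
    threshold: int = 1,
) -> dict[str, float]:
    """Cable-edge spreading velocities (sites/s) from a kymograph.

    The edge is the outermost lit site (fluorescence >= threshold) per
    frame.  Among all windows of at least ``min_duration_s`` with the edge
    defined in every frame, the one with the best linear fit (highest R^2,
    ties broken toward longer windows) is taken, separately for the
    barbed-direction (rightmost) and pointed-direction (leftmost) edges.
    Positive velocity means the cable is spreading.  Returns an empty dict
    when no qualifying window exists.
    """
    vals = kymo.values
    lit = (vals >= threshold) & (vals >= 0)
    n_frames = vals.shape[0]
    dt = kymo.frame_interval
    if not np.isfinite(dt) or dt <= 0:
        return {}
    win = max(3, int(math.ceil(min_duration_s / dt)) + 1)
    if n_frames < win:
        return {}

    right = np.full(n_frames, np.nan)
    left = np.full(n_frames, np.nan)
    for f in range(n_frames):
        idx = np.nonzero(lit[f])[0]
        if idx.size:
            right[f] = idx[-1]
            left[f] = idx[0]

    def best_slope(edge: np.ndarray, sign: float) -> float | None:
        best = None
        best_r2 = -np.inf
        for start in range(0, n_frames - win + 1):
            seg = edge[start : start + win]
            if np.isnan(seg).any():
                continue
            x = kymo.frame_times[start : start + win]
            slope, intercept = np.polyfit(x, seg, 1)
            pred = slope * x + intercept
            ss_res = float(((seg - pred) ** 2).sum())
            ss_tot = float(((seg - seg.mean()) ** 2).sum())
            r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            if r2 > best_r2:
                best_r2 = r2
                best = sign * slope
        return best

    out: dict[str, float] = {}
    vb = best_slope(right, +1.0)
    vp = best_slope(left, -1.0)
    if vb is not None:
        out["barbed"] = float(vb)
    if vp is not None:
        out["pointed"] = float(vp)
    return out
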