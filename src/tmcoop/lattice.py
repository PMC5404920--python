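"""Kinetic Monte Carlo model of tropomyosin loading on a growing actin filament.

The filament is a two-row lattice: each row is one helical groove, each
site one tropomyosin footprint (21.6 nm).  An unoccupied site binds at

    k_on * w^a * c^b

and an occupied one unbinds at ``k_off / (w^a * c^b)``, where ``a`` is the
number of occupied immediate same-row neighbours (end-to-end cooperativity)
and ``b`` the occupancy of the opposite-groove site (indirect cooperativity
through the filament).  Filament elongation is itself a stochastic event of
rate ``v_grow`` (sites/s); when it fires the site count is set to
``floor(t * v_grow)``, appending unoccupied columns at the barbed end
(site 0 is the pointed end).

``simulate`` runs a numba-compiled Gillespie loop; ``step`` is a plain
NumPy reference implementation of a single event used for contract tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import math
import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (
    EV_BIND,
    EV_GROW,
    EV_UNBIND,
    STATUS_ABSORBED,
    STATUS_EVENT_BUDGET,
    STATUS_FILLED,
    STATUS_MAX_TIME,
    STATUS_REACHED_LENGTH,
)
from .constants import SITE_LENGTH_NM

__all__ = [
    "LatticeParams",
    "LatticeState",
    "Trajectory",
    "local_on_rate",
    "local_off_rate",
    "total_propensity",
    "step",
    "apply_growth",
    "simulate",
    "time_averaged_coverage",
    "config_time_distribution",
    "stationary_log_weight",
]


@dataclass(frozen=True)
class LatticeParams:
    """Rate and geometry parameters of the two-row lattice model."""

    kon: float
    koff: float
    w: float = 1.0
    c: float = 1.0
    v_grow: float = 0.0  # sites / s
    site_length_nm: float = SITE_LENGTH_NM
    n0: int = 1
    max_time: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kon < 0 or self.koff < 0 or self.v_grow < 0:
            raise ValueError("rates must be non-negative")
        if self.w < 0 or self.c < 0:
            raise ValueError("cooperativity factors must be non-negative")
        if self.site_length_nm <= 0:
            raise ValueError("site_length_nm must be positive")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


@dataclass
class LatticeState:
    """Occupancy snapshot: 2 x N binary matrix plus the current time."""

    occupancy: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
        if self.occupancy.ndim != 2 or self.occupancy.shape[0] != 2:
            raise ValueError("occupancy must be a 2 x N array")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")

    @property
    def N(self) -> int:
        return self.occupancy.shape[1]

    @classmethod
    def empty(cls, n: int) -> "LatticeState":
        return cls(np.zeros((2, n), dtype=np.int8))

    @classmethod
    def full(cls, n: int) -> "LatticeState":
        return cls(np.ones((2, n), dtype=np.int8))


def _neighbour_factors(occ: np.ndarray, i: int, j: int) -> tuple[int, int]:
    N = occ.shape[1]
    if not (0 <= i < N) or j not in (0, 1):
        raise IndexError(f"site ({i},{j}) out of range for N={N}")
    a = 0
    if i > 0 and occ[j, i - 1]:
        a += 1
    if i < N - 1 and occ[j, i + 1]:
        a += 1
    b = int(occ[1 - j, i])
    return a, b


def local_on_rate(state: LatticeState, params: LatticeParams, i: int, j: int) -> float:
    """Association rate of unoccupied site (i, j): k_on * w^a * c^b."""
    a, b = _neighbour_factors(state.occupancy, i, j)
    if state.occupancy[j, i]:
        raise ValueError(f"site ({i},{j}) is occupied; on-rate undefined")
    return params.kon * params.w**a * params.c**b


def local_off_rate(state: LatticeState, params: LatticeParams, i: int, j: int) -> float:
    """Dissociation rate of occupied site (i, j): k_off / (w^a * c^b)."""
    a, b = _neighbour_factors(state.occupancy, i, j)
    if not state.occupancy[j, i]:
        raise ValueError(f"site ({i},{j}) is empty; off-rate undefined")
    return params.koff / (params.w**a * params.c**b)


def _rate_matrix(state: LatticeState, params: LatticeParams) -> np.ndarray:
    """Per-site event rates, shape (2, N): on-rate if empty, off-rate if occupied."""
    occ = state.occupancy
    N = occ.shape[1]
    rates = np.empty((2, N), dtype=float)
    for j in range(2):
        for i in range(N):
            a, b = _neighbour_factors(occ, i, j)
            fac = params.w**a * params.c**b
            rates[j, i] = params.koff / fac if occ[j, i] else params.kon * fac
    return rates


def total_propensity(state: LatticeState, params: LatticeParams) -> float:
    """Sum of all per-site event rates plus the growth rate."""
    return float(_rate_matrix(state, params).sum() + params.v_grow)


def apply_growth(state: LatticeState, new_time: float, v_grow: float) -> LatticeState:
    """Advance time and extend the lattice to floor(new_time * v_grow) sites.

    The site count never decreases; appended barbed-end columns are empty.
    """
    if new_time < state.t:
        raise ValueError("new_time must not precede current time")
    n_new = max(state.N, int(math.floor(new_time * v_grow)))
    occ = np.zeros((2, n_new), dtype=np.int8)
    occ[:, : state.N] = state.occupancy
    return LatticeState(occ, t=new_time)


class AbsorbingStateError(RuntimeError):
    """Raised when the total propensity is zero and no event can occur."""


def step(
    state: LatticeState, params: LatticeParams, rng: np.random.Generator
) -> tuple[LatticeState, float]:
    """One Gillespie event (reference implementation).

    Draws the waiting time from Exponential(total propensity), selects a
    bind/unbind/growth event with probability proportional to its rate
    (row-major site order, growth last) and applies it.
    """
    rates = _rate_matrix(state, params)
    flat = np.append(rates.ravel(), params.v_grow)
    R = flat.sum()
    if R <= 0:
        raise AbsorbingStateError("total propensity is zero")
    dt = rng.exponential(1.0 / R)
    t_new = state.t + dt
    k = int(np.searchsorted(np.cumsum(flat), rng.uniform(0, R), side="right"))
    k = min(k, flat.size - 1)
    if k == flat.size - 1:
        return apply_growth(state, t_new, params.v_grow), dt
    j, i = divmod(k, state.N)
    occ = state.occupancy.copy()
    occ[j, i] = 1 - occ[j, i]
    return LatticeState(occ, t=t_new), dt


@dataclass
class Trajectory:
    """Event log of one simulation, replayable into snapshots."""

    params: LatticeParams
    seed: int
    initial_occupancy: np.ndarray
    times: np.ndarray
    codes: np.ndarray  # 0 bind, 1 unbind, 2 grow
    sites: np.ndarray
    rows: np.ndarray
    final_state: LatticeState
    status: int
    occ_integral: float = 0.0
    accum_time: float = 0.0
    config_time: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return len(self.times)

    def replay(self, until: float | None = None) -> LatticeState:
        """Reconstruct the occupancy at time ``until`` from the event log."""
        t_stop = self.final_state.t if until is None else until
        occ = self.initial_occupancy.copy()
        t = 0.0
        for k in range(self.n_events):
            if self.times[k] > t_stop:
                break
            t = self.times[k]
            code = self.codes[k]
            if code == EV_GROW:
                n_new = int(self.sites[k])
                if n_new > occ.shape[1]:
                    pad = np.zeros((2, n_new - occ.shape[1]), dtype=np.int8)
                    occ = np.concatenate([occ, pad], axis=1)
            else:
                occ[self.rows[k], self.sites[k]] = 1 if code == EV_BIND else 0
        return LatticeState(occ, t=max(t, min(t_stop, self.final_state.t)))

    def snapshots(self, frame_times: np.ndarray) -> list[LatticeState]:
        """Occupancy snapshots at each requested time (single replay pass)."""
        frame_times = np.asarray(frame_times, dtype=float)
        out: list[LatticeState] = []
        occ = self.initial_occupancy.copy()
        k = 0
        for ft in frame_times:
            while k < self.n_events and self.times[k] <= ft:
                code = self.codes[k]
                if code == EV_GROW:
                    n_new = int(self.sites[k])
                    if n_new > occ.shape[1]:
                        pad = np.zeros((2, n_new - occ.shape[1]), dtype=np.int8)
                        occ = np.concatenate([occ, pad], axis=1)
                else:
                    occ[self.rows[k], self.sites[k]] = 1 if code == EV_BIND else 0
                k += 1
            out.append(LatticeState(occ.copy(), t=ft))
        return out

    def molecules(self) -> pd.DataFrame:
        """Per-molecule table: (molecule_id, row, site, t_bind, t_unbind).

        Molecules never slide, so a molecule is one bind event, optionally
        closed by the next unbind at the same site.  ``t_unbind`` is NaN for
        molecules still bound at the end (right-censored).  Molecules present
        in the initial state get t_bind = 0.
        """
        occ0 = self.initial_occupancy
        current: dict[tuple[int, int], int] = {}
        recs: list[list] = []
        for j, i in zip(*np.nonzero(occ0)):
            mid = len(recs)
            recs.append([mid, int(j), int(i), 0.0, np.nan])
            current[(int(j), int(i))] = mid
        for k in range(self.n_events):
            code = self.codes[k]
            if code == EV_GROW:
                continue
            key = (int(self.rows[k]), int(self.sites[k]))
            if code == EV_BIND:
                mid = len(recs)
                recs.append([mid, key[0], key[1], float(self.times[k]), np.nan])
                current[key] = mid
            else:
                mid = current.pop(key)
                recs[mid][4] = float(self.times[k])
        return pd.DataFrame(
            recs, columns=["molecule_id", "row", "site", "t_bind", "t_unbind"]
        )


def _kernel_seed(params: LatticeParams, rng: np.random.Generator | None) -> int:
    if params.seed is not None:
        ss = np.random.SeedSequence(params.seed)
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    if rng is not None:
        return int(rng.integers(0, 2**31 - 1))
    return int(np.random.SeedSequence().generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate(
    params: LatticeParams,
    rng: np.random.Generator | None = None,
    *,
    stop_at_n: int | None = None,
    initial_state: LatticeState | None = None,
    stop_when_full: bool = True,
    log_events: bool = True,
    max_events: int = 4_000_000,
    track_config: bool = False,
    accum_after: float = 0.0,
) -> Trajectory:
    """Run the Gillespie simulation until max_time (or earlier termination).

    Termination: ``t >= max_time``; a completely filled fixed lattice
    (``v_grow == 0`` and ``stop_when_full``); zero total propensity
    (absorbing); or the site count reaching ``stop_at_n`` (used to snapshot
    a growing filament at a target length).

    ``track_config`` accumulates the time spent in each of the 4^n0 lattice
    configurations (fixed small lattices only) for detailed-balance checks;
    ``accum_after`` discards burn-in from the time-average accumulators.
    Identical ``params.seed`` gives a bit-identical trajectory.
    """
    if initial_state is not None:
        n0 = initial_state.N
        init = initial_state.occupancy.astype(np.int8)
    else:
        n0 = params.n0
        init = np.zeros((2, n0), dtype=np.int8)
    if track_config and (params.v_grow > 0 or n0 > 6):
        raise ValueError("config tracking requires a fixed lattice with n0 <= 6")

    cap = n0
    if params.v_grow > 0:
        cap = max(cap, int(math.floor(params.max_time * params.v_grow)) + 1)
        if stop_at_n is not None:
            cap = max(n0, min(cap, stop_at_n))
    occ = np.zeros((2, cap), dtype=np.int8)
    occ[:, :n0] = init

    seed = _kernel_seed(params, rng)
    target = stop_at_n if stop_at_n is not None else cap + 1
    (t, N, n_ev, ev_t, ev_code, ev_site, ev_row, occ_int, accum_t, cfg_t, status) = (
        _kernels.kmc_run(
            occ,
            n0,
            params.kon,
            params.koff,
            params.w,
            params.c,
            params.v_grow,
            params.max_time,
            target,
            stop_when_full,
            seed,
            log_events,
            max_events,
            track_config,
            accum_after,
        )
    )
    if status == STATUS_EVENT_BUDGET:
        raise RuntimeError(
            f"event log budget ({max_events}) exhausted at t={t:.3g}; "
            "raise max_events or disable log_events"
        )
    final = LatticeState(occ[:, :N].copy(), t=t)
    return Trajectory(
        params=params,
        seed=seed,
        initial_occupancy=init.copy(),
        times=ev_t[:n_ev].copy(),
        codes=ev_code[:n_ev].copy(),
        sites=ev_site[:n_ev].copy(),
        rows=ev_row[:n_ev].copy(),
        final_state=final,
        status=int(status),
        occ_integral=float(occ_int),
        accum_time=float(accum_t),
        config_time=cfg_t.copy() if track_config else None,
    )


def time_averaged_coverage(
    params: LatticeParams,
    *,
    burn_in: float = 0.0,
    rng: np.random.Generator | None = None,
    initial_state: LatticeState | None = None,
) -> float:
    """Long-run mean per-site occupancy of a fixed lattice (time average)."""
    if params.v_grow != 0:
        raise ValueError("time averaging is defined for fixed lattices only")
    traj = simulate(
        params,
        rng,
        initial_state=initial_state,
        stop_when_full=False,
        log_events=False,
        accum_after=burn_in,
    )
    n = initial_state.N if initial_state is not None else params.n0
    if traj.accum_time <= 0:
        raise RuntimeError("no time accumulated past burn-in")
    return traj.occ_integral / (traj.accum_time * 2 * n)


def config_time_distribution(
    params: LatticeParams,
    *,
    burn_in: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fraction of time spent in each of the 4^n0 configurations."""
    traj = simulate(
        params,
        rng,
        stop_when_full=False,
        log_events=False,
        track_config=True,
        accum_after=burn_in,
    )
    ct = traj.config_time
    return ct / ct.sum()


def stationary_log_weight(config: np.ndarray, K: float, w: float, c: float) -> float:
    """log of the detailed-balance stationary weight of one configuration.

    pi propto K^n * (w^2)^p_row * (c^2)^p_cross with n occupied sites,
    p_row same-row adjacent occupied pairs, p_cross doubly occupied columns.
    """
    occ = np.asarray(config)
    n = occ.sum()
    p_row = int((occ[0, :-1] & occ[0, 1:]).sum() + (occ[1, :-1] & occ[1, 1:]).sum())
    p_cross = int((occ[0] & occ[1]).sum())
    return float(n * np.log(K) + 2 * p_row * np.log(w) + 2 * p_cross * np.log(c))
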