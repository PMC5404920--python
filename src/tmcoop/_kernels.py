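"""Numba kernel for the two-row lattice kinetic Monte Carlo simulator.

Layout: per-site event rates live in a flat array of length 2*cap + 1
(row-major over the two rows, growth event last), with 64-slot block sums
so that event selection is a short two-level cumulative scan and rate
updates after an event touch only the flipped site, its two same-row
neighbours and the opposite site.  Totals are recomputed from scratch
periodically to bound floating-point drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOCK = 64

# termination status codes
STATUS_MAX_TIME = 0
STATUS_FILLED = 1
STATUS_ABSORBED = 2
STATUS_EVENT_BUDGET = 3
STATUS_REACHED_LENGTH = 4

EV_BIND = 0
EV_UNBIND = 1
EV_GROW = 2


@njit(cache=True)
def _site_rate(occ, N, i, j, kon, koff, w, c):
    a = 0
    if i > 0 and occ[j, i - 1] == 1:
        a += 1
    if i < N - 1 and occ[j, i + 1] == 1:
        a += 1
    b = occ[1 - j, i]
    fac = w**a * c**b
    if occ[j, i] == 1:
        return koff / fac
    return kon * fac


@njit(cache=True)
def _set_rate(rates, bsum, idx, val):
    old = rates[idx]
    rates[idx] = val
    bsum[idx // BLOCK] += val - old
    return val - old


@njit(cache=True)
def _refresh_site(occ, N, i, j, cap, kon, koff, w, c, rates, bsum):
    idx = j * cap + i
    return _set_rate(rates, bsum, idx, _site_rate(occ, N, i, j, kon, koff, w, c))


@njit(cache=True)
def _rebuild(rates, bsum):
    nb = bsum.shape[0]
    total = 0.0
    for b in range(nb):
        s = 0.0
        lo = b * BLOCK
        hi = min(lo + BLOCK, rates.shape[0])
        for k in range(lo, hi):
            s += rates[k]
        bsum[b] = s
        total += s
    return total


@njit(cache=True)
def kmc_run(
    occ,
    n0,
    kon,
    koff,
    w,
    c,
    v_grow,
    max_time,
    stop_at_n,
    stop_when_full,
    seed,
    log_events,
    max_events,
    track_config,
    accum_after,
):
    """Run the Gillespie loop; see lattice.simulate for the public contract.

    Returns (t, N, n_ev, ev_t, ev_code, ev_site, ev_row, occ_integral,
    accum_time, config_time, status).
    """
    np.random.seed(seed)
    cap = occ.shape[1]
    M = 2 * cap + 1
    grow_idx = 2 * cap
    rates = np.zeros(M, dtype=np.float64)
    bsum = np.zeros((M + BLOCK - 1) // BLOCK, dtype=np.float64)

    N = n0
    n_occ = 0
    for j in range(2):
        for i in range(N):
            if occ[j, i] == 1:
                n_occ += 1
    for j in range(2):
        for i in range(N):
            _refresh_site(occ, N, i, j, cap, kon, koff, w, c, rates, bsum)
    _set_rate(rates, bsum, grow_idx, v_grow)
    total = _rebuild(rates, bsum)

    cfg = 0
    if track_config:
        for j in range(2):
            for i in range(N):
                if occ[j, i] == 1:
                    cfg |= 1 << (j * n0 + i)
        config_time = np.zeros(4**n0, dtype=np.float64)
    else:
        config_time = np.zeros(1, dtype=np.float64)

    log_cap = max_events if log_events else 1
    ev_t = np.empty(log_cap, dtype=np.float64)
    ev_code = np.empty(log_cap, dtype=np.int8)
    ev_site = np.empty(log_cap, dtype=np.int32)
    ev_row = np.empty(log_cap, dtype=np.int8)

    t = 0.0
    n_ev = 0
    occ_integral = 0.0
    accum_time = 0.0
    status = STATUS_MAX_TIME
    iters = 0

    if stop_when_full and v_grow == 0.0 and n_occ == 2 * N:
        return (t, N, n_ev, ev_t, ev_code, ev_site, ev_row, occ_integral,
                accum_time, config_time, STATUS_FILLED)

    while True:
        iters += 1
        if iters % 65536 == 0:
            total = _rebuild(rates, bsum)
        if total <= 0.0:
            status = STATUS_ABSORBED
            break
        u1 = np.random.random()
        while u1 <= 0.0:
            u1 = np.random.random()
        dt = -np.log(u1) / total
        t_new = t + dt
        t_stop = t_new
        stopping = False
        if t_new >= max_time:
            t_stop = max_time
            stopping = True
        if t_stop > accum_after:
            d = t_stop - max(t, accum_after)
            occ_integral += n_occ * d
            accum_time += d
            if track_config:
                config_time[cfg] += d
        if stopping:
            t = max_time
            status = STATUS_MAX_TIME
            break
        t = t_new

        # select event by two-level cumulative scan
        r = np.random.random() * total
        b = 0
        nb = bsum.shape[0]
        while b < nb - 1 and r >= bsum[b]:
            r -= bsum[b]
            b += 1
        idx = b * BLOCK
        hi = min(idx + BLOCK, M)
        while idx < hi - 1 and r >= rates[idx]:
            r -= rates[idx]
            idx += 1
        # skip zero-rate slot hit by rounding
        if rates[idx] <= 0.0:
            total = _rebuild(rates, bsum)
            continue

        if idx == grow_idx:
            newN = int(np.floor(t * v_grow))
            if newN > cap:
                newN = cap
            if newN > N:
                oldN = N
                N = newN
                for j in range(2):
                    for i in range(oldN, N):
                        occ[j, i] = 0
                        _refresh_site(occ, N, i, j, cap, kon, koff, w, c, rates, bsum)
                total = _rebuild(rates, bsum)
                if log_events:
                    if n_ev >= log_cap:
                        status = STATUS_EVENT_BUDGET
                        break
                    ev_t[n_ev] = t
                    ev_code[n_ev] = EV_GROW
                    ev_site[n_ev] = N
                    ev_row[n_ev] = -1
                    n_ev += 1
                if N >= stop_at_n:
                    status = STATUS_REACHED_LENGTH
                    break
        else:
            j = idx // cap
            i = idx - j * cap
            if occ[j, i] == 1:
                occ[j, i] = 0
                n_occ -= 1
                code = EV_UNBIND
            else:
                occ[j, i] = 1
                n_occ += 1
                code = EV_BIND
            total += _refresh_site(occ, N, i, j, cap, kon, koff, w, c, rates, bsum)
            total += _refresh_site(occ, N, i, 1 - j, cap, kon, koff, w, c, rates, bsum)
            if i > 0:
                total += _refresh_site(occ, N, i - 1, j, cap, kon, koff, w, c, rates, bsum)
            if i < N - 1:
                total += _refresh_site(occ, N, i + 1, j, cap, kon, koff, w, c, rates, bsum)
            if track_config:
                cfg ^= 1 << (j * n0 + i)
            if log_events:
                if n_ev >= log_cap:
                    status = STATUS_EVENT_BUDGET
                    break
                ev_t[n_ev] = t
                ev_code[n_ev] = code
                ev_site[n_ev] = i
                ev_row[n_ev] = j
                n_ev += 1
            if stop_when_full and v_grow == 0.0 and n_occ == 2 * N:
                status = STATUS_FILLED
                break

    return (t, N, n_ev, ev_t, ev_code, ev_site, ev_row, occ_integral,
            accum_time, config_time, status)
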