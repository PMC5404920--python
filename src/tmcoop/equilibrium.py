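"""Exact equilibrium coverage of the two-row binding lattice.

The kinetic rates (on-rate multiplied, off-rate divided, by ``w`` per
occupied same-row neighbour and by ``c`` for an occupied opposite site)
satisfy detailed balance with respect to the Gibbs measure

    pi(config)  propto  K^n  *  (w^2)^p_row  *  (c^2)^p_cross

where ``K = k_on/k_off`` is the per-site equilibrium constant, ``n`` the
number of occupied sites, ``p_row`` the number of same-row adjacent occupied
pairs and ``p_cross`` the number of doubly-occupied columns.  The squares
arise because each factor acts once on the forward and once (inverted) on
the reverse rate.

This is a two-row Ising lattice gas: a one-dimensional chain of columns,
each column carrying the 4 joint states of a site pair, so every equilibrium
property follows from a 4 x 4 transfer matrix.  Two independent routes are
provided -- exhaustive enumeration for small N and the transfer matrix for
any N (including the infinite-chain limit) -- and they agree to machine
precision, which is what qualifies them as an oracle for the kinetic Monte
Carlo simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumSpec",
    "enumerate_equilibrium",
    "transfer_matrix_coverage",
    "column_state_fractions",
]

# column states s = (x_row0, x_row1): 00, 10, 01, 11
_N_PER_STATE = np.array([0, 1, 1, 2], dtype=float)
_CROSS_PER_STATE = np.array([0, 0, 0, 1], dtype=float)

_ENUM_MAX_N = 10


@dataclass(frozen=True)
class EquilibriumSpec:
    """Thermodynamic parameters of the fixed-length two-row lattice.

    ``N=None`` denotes the infinite-chain limit.
    """

    K: float
    w: float = 1.0
    c: float = 1.0
    N: int | None = None

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.w <= 0 or self.c <= 0:
            raise ValueError("cooperativity factors must be positive")
        if self.N is not None and self.N < 1:
            raise ValueError("N must be >= 1 (or None for infinite)")


def _popcount(a: np.ndarray) -> np.ndarray:
    return np.bitwise_count(a)


def enumerate_equilibrium(spec: EquilibriumSpec) -> float:
    """Mean per-site occupancy by exhaustive summation over all 2^(2N) states.

    Only feasible for small lattices; refuses N > 10 (use the transfer
    matrix instead, it is exact for any N).
    """
    if spec.N is None:
        raise ValueError("enumeration needs a finite N; use transfer_matrix_coverage")
    n = spec.N
    if n > _ENUM_MAX_N:
        raise ValueError(
            f"N={n} too large for 4^N enumeration; use transfer_matrix_coverage"
        )
    rows = np.arange(2**n, dtype=np.uint64)
    occ = _popcount(rows).astype(float)  # occupied sites per row config
    adj = _popcount(rows & (rows >> np.uint64(1))).astype(float)  # same-row pairs
    cross = _popcount(rows[:, None] & rows[None, :]).astype(float)

    logK, logw, logc = np.log(spec.K), np.log(spec.w), np.log(spec.c)
    logwt = (
        (occ[:, None] + occ[None, :]) * logK
        + 2.0 * (adj[:, None] + adj[None, :]) * logw
        + 2.0 * cross * logc
    )
    logwt -= logwt.max()
    wt = np.exp(logwt)
    n_tot = occ[:, None] + occ[None, :]
    return float((wt * n_tot).sum() / (wt.sum() * 2 * n))


def _column_weights(spec: EquilibriumSpec) -> tuple[np.ndarray, np.ndarray]:
    """(D, B): per-column statistical weights and inter-column bond weights."""
    D = spec.K**_N_PER_STATE * (spec.c**2) ** _CROSS_PER_STATE
    x0 = np.array([0, 1, 0, 1], dtype=float)
    x1 = np.array([0, 0, 1, 1], dtype=float)
    shared = x0[:, None] * x0[None, :] + x1[:, None] * x1[None, :]
    B = (spec.w**2) ** shared
    return D, B


def _chain_expectation(spec: EquilibriumSpec, value: np.ndarray) -> float:
    """Average per column of a per-column-state observable ``value[s]``."""
    D, B = _column_weights(spec)
    if spec.N is None:
        A = B * D[None, :]
        lam, vecs = np.linalg.eig(A)
        k = int(np.argmax(lam.real))
        r = np.abs(vecs[:, k].real)
        lam_l, vecs_l = np.linalg.eig(A.T)
        kl = int(np.argmax(lam_l.real))
        left = np.abs(vecs_l[:, kl].real)
        p = left * r
        p /= p.sum()
        return float(p @ value)
    # finite open chain: forward recursion for Z and sum_k <value at column k>
    f = D.copy()
    g = D * value
    for _ in range(spec.N - 1):
        fB = f @ B
        g = (g @ B) * D + fB * D * value
        f = fB * D
        s = f.sum()
        f /= s
        g /= s
    return float(g.sum() / (f.sum() * spec.N))


def transfer_matrix_coverage(spec: EquilibriumSpec) -> float:
    """Mean per-site occupancy via the 4x4 column transfer matrix.

    Finite N uses an open-boundary forward recursion; ``N=None`` takes the
    occupancy expectation in the dominant-eigenvector measure.
    """
    return _chain_expectation(spec, _N_PER_STATE) / 2.0


def column_state_fractions(spec: EquilibriumSpec) -> dict[str, float]:
    """Equilibrium fractions of empty / singly / doubly occupied columns."""
    empty = _chain_expectation(spec, np.array([1.0, 0, 0, 0]))
    single = _chain_expectation(spec, np.array([0.0, 1, 1, 0]))
    double = _chain_expectation(spec, np.array([0.0, 0, 0, 1]))
    return {"empty": empty, "single": single, "double": double}
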