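"""Concentration-response quantification: Hill fits and rate arithmetic.

The binding curve is fit to the Hill equation in the form

    theta = [L]^n / (K_d + [L]^n)

(the apparent dissociation constant K_d carries units of [L]^n in this
form; the half-saturation concentration EC50 = K_d^(1/n) is reported
alongside).  The Hill coefficient n is invariant to any linear rescaling
of the concentration axis, so simulated coverage curves can be fit
directly against the microscopic on-rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "free_concentration",
    "fit_hill",
    "severing_rate",
]


@dataclass(frozen=True)
class HillFit:
    K_d: float  # units of [L]^n
    n: float
    amplitude: float  # 1.0 unless fit with a free plateau
    rmse: float

    @property
    def ec50(self) -> float:
        """Half-saturation concentration, K_d^(1/n)."""
        return self.K_d ** (1.0 / self.n)


def free_concentration(
    added_nM: float,
    occupancy: float,
    f_actin_nM: float = 250.0,
    ratio: float = 4.0,
) -> float:
    """Free ligand concentration (uM) after subtracting the bound pool.

    (added_nM - f_actin_nM * occupancy / ratio) * 0.001, with the F-actin
    concentration and the 1:ratio bound-ligand:actin stoichiometry setting
    how much ligand is sequestered at the measured occupancy.
    """
    if added_nM < 0 or occupancy < 0 or occupancy > 1:
        raise ValueError("inputs out of range")
    free = (added_nM - f_actin_nM * occupancy / ratio) * 0.001
    if free < 0:
        raise ValueError(
            f"negative free concentration ({free:.4g} uM): bound pool exceeds "
            "added ligand; check stoichiometry inputs"
        )
    return free


def _hill(L, K_d, n):
    return L**n / (K_d + L**n)


def fit_hill(
    concentrations,
    occupancies,
    free_amplitude: bool = False,
) -> HillFit:
    """Nonlinear least-squares Hill fit of occupancy vs concentration.

    Requires points on both sides of half-saturation (relative to the
    plateau when ``free_amplitude``).  The initializer takes n from the
    slope of logit(theta) vs ln[L] in the transition region.
    """
    L = np.asarray(concentrations, dtype=float)
    th = np.asarray(occupancies, dtype=float)
    if L.size != th.size or L.size < 3:
        raise ValueError("need >= 3 matched points")
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    plateau = th.max() if free_amplitude else 1.0
    rel = th / plateau
    if not (np.any(rel < 0.5) and np.any(rel > 0.5)):
        raise ValueError("data must span both sides of half-saturation")

    # logit-slope initializer on the transition points
    mid = (rel > 0.02) & (rel < 0.98)
    if mid.sum() >= 2:
        y = np.log(rel[mid] / (1 - rel[mid]))
        n0 = float(np.polyfit(np.log(L[mid]), y, 1)[0])
        n0 = min(max(abs(n0), 0.2), 100.0)
    else:
        n0 = 2.0
    # EC50 initializer: concentration nearest half-saturation
    ec50_0 = float(L[np.argmin(np.abs(rel - 0.5))])

    if free_amplitude:
        def model(x, log_ec50, n, A):
            return A * _hill(x, np.exp(log_ec50 * n), n)
        p0 = [np.log(ec50_0), n0, float(plateau)]
        bounds = ([-np.inf, 1e-3, 1e-6], [np.inf, 200.0, 1.2])
    else:
        def model(x, log_ec50, n):
            return _hill(x, np.exp(log_ec50 * n), n)
        p0 = [np.log(ec50_0), n0]
        bounds = ([-np.inf, 1e-3], [np.inf, 200.0])

    popt, _ = curve_fit(model, L, th, p0=p0, bounds=bounds, maxfev=20000)
    log_ec50, n = float(popt[0]), float(popt[1])
    amp = float(popt[2]) if free_amplitude else 1.0
    K_d = float(np.exp(log_ec50 * n))
    rmse = float(np.sqrt(np.mean((model(L, *popt) - th) ** 2)))
    return HillFit(K_d=K_d, n=n, amplitude=amp, rmse=rmse)


def severing_rate(n_events: int, total_filament_um: float, duration_s: float) -> float:
    """Severing events per micron of filament per second."""
    if total_filament_um <= 0 or duration_s <= 0:
        raise ValueError("filament length and duration must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return n_events / (total_filament_um * duration_s)
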