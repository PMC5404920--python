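"""Where and when does the first tropomyosin land on a growing filament?

With a uniform association rate per length (kon_len) on a filament growing
at v_grow, the first-binding time follows a Rayleigh-type law
P(tau) = a tau exp(-a tau^2/2), a = kon_len * v_grow, and the age of the
receiving site follows an erfc law.  A discrete-time Monte Carlo twin
checks both, and the maximum-likelihood estimator recovers kon_len.
"""

import numpy as np

from tmcoop import (
    FirstBindingParams,
    fit_kon,
    simulate_first_binding_batch,
)

params = FirstBindingParams(kon_len=4e-6, v_grow=47.5, seed=1)
tau_star = 1.0 / np.sqrt(params.a)
print(f"kon_len = {params.kon_len:.1e} /s/nm, v_grow = {params.v_grow} nm/s")
print(f"most likely first-binding time tau* = 1/sqrt(a) = {tau_star:.1f} s")

events = simulate_first_binding_batch(params, 2000)
times = np.array([e.t_bind for e in events])
ages = np.array([e.age_s for e in events])
print(f"Monte Carlo (n=2000): median binding time {np.median(times):.1f} s "
      f"(theory {np.sqrt(2 * np.log(2) / params.a):.1f} s)")
print(f"mean site age at binding {ages.mean():.1f} s "
      f"-> first landings favour older, pointed-end-proximal lattice")

fit = fit_kon(times, v_grow=params.v_grow, rng=np.random.default_rng(0))
print(f"recovered kon_len = {fit.kon_len:.2e} /s/nm "
      f"(95% CI {fit.ci_low:.2e} .. {fit.ci_high:.2e})")
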