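"""Does the second tropomyosin cable prefer the groove opposite the first?

The counting model scores every admissible placement of a second cable on
a 100-nm grid: non-overlapping placements count twice (two free grooves),
overlapping runs are weighted by the indirect-cooperativity factor c, and
p2 = N2/(N1+N2) is the overlap probability.  A bootstrap over a set of
observed geometries predicts per-occupancy-bin overlap fractions under
candidate c values, and a likelihood scan estimates c from overlap flags.
"""

import numpy as np

from tmcoop import (
    SecondBindingGeometry,
    bootstrap_binned_fractions,
    estimate_c,
    overlap_probability,
)
from tmcoop.synth import gen_second_binding

geom = SecondBindingGeometry(L_a=10, L_1=2, x_1=4, L_2=2)
for c in (0.5, 1.0, 2.0):
    print(f"worked geometry (La=10, L1=2, x1=4, L2=2): p2(c={c}) = "
          f"{overlap_probability(geom, c):.4f}")
print("p2 rises with c: indirect cooperativity biases binding opposite the first cable")

df, meta = gen_second_binding(c_true=2.0, n=37, seed=3)
events = [
    SecondBindingGeometry(int(r.La), int(r.L1), int(r.x1), int(r.L2),
                          bool(r.overlapped))
    for r in df.itertuples()
]
print(f"\nsynthetic experiment: {len(events)} events generated at c_true = "
      f"{meta['c_true']}")
for c in (0.5, 1.0, 2.0):
    res = bootstrap_binned_fractions(events, c=c, n_boot=5000, seed=5)
    bins = ", ".join(
        f"{k}: {v['mean']:.2f}+-{v['sd']:.2f}" for k, v in res.bins.items()
    )
    print(f"  model c={c}: expected overlap fraction per occupancy bin -> {bins}")

est = estimate_c(events, rng=np.random.default_rng(0))
print(f"maximum-likelihood c = {est.c_hat:.2f} "
      f"(95% CI {est.ci_low:.2f} .. {est.ci_high:.2f}); "
      f"LR test vs c=1: p = {est.p_value_vs_c1:.3f}")
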