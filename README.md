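# tmcoop

Models and quantification for **cooperative tropomyosin loading on growing
actin filaments**.

Fission-yeast tropomyosin (Cdc8) coats actin filaments with extreme
cooperativity: almost no binding below ~1 uM, near-complete coating by
~2 uM (Hill coefficient ~15).  An actin filament offers two helical
grooves, each accommodating an end-to-end tropomyosin cable, which raises
a mechanistic question: how much of the cooperativity comes from
**end-to-end contacts** between neighbouring tropomyosins in the same
groove, and how much from **indirect coupling through the filament** to
the cable in the opposite groove?

`tmcoop` implements the modelling toolkit needed to ask that question
quantitatively:

* **Two-row lattice kinetic Monte Carlo** (`tmcoop.lattice`) — each
  lattice site is one tropomyosin footprint (21.6 nm = 8 x 2.7 nm); an
  empty site binds at `k_on * w^a * c^b` and an occupied one unbinds at
  `k_off / (w^a c^b)`, with `a` the occupied same-row neighbours
  (end-to-end factor `w`) and `b` the facing-groove occupancy (indirect
  factor `c`).  Filament growth is a stochastic event appending sites at
  the barbed end.  Exact Gillespie dynamics, numba-accelerated,
  bit-reproducible under a seed.
* **Exact equilibrium oracles** (`tmcoop.equilibrium`) — the stationary
  law `pi ~ K^n (w^2)^p_row (c^2)^p_cross` evaluated by brute enumeration
  and by a 4x4 transfer matrix (the system is a two-row Ising chain),
  used as ground truth for the simulator.
* **TIRFM-style observation model** (`tmcoop.observe`) — 20% molecular
  labeling, +/-100 nm (4-site) optical broadening, groove summation to
  fluorescence levels {0,1,2}; kymographs, coverage statistics and cable
  spreading velocities.
* **First-binding theory** (`tmcoop.firstbind`) — on a filament growing
  at `v_grow` with association rate per length `kon_len`, the first
  binding time is Rayleigh-distributed,
  `P(tau) = a tau exp(-a tau^2/2)` with `a = kon_len v_grow`, and the
  receiving site's age follows an erfc law; plus a discrete-time Monte
  Carlo twin and a censoring-aware maximum-likelihood estimator.
* **Second-binding counting model** (`tmcoop.secondbind`) — the
  probability `p2 = N2/(N1+N2)` that a second cable lands opposite the
  first on a 100-nm grid, with overlap placements weighted by `c`;
  occupancy-binned bootstrap predictions and a likelihood estimate of `c`.
* **Residence-time analysis** (`tmcoop.survival`) — Kaplan-Meier with
  right-censoring, single-exponential fits `f0 exp(-x/T1)`, and the
  buried-molecule identity `k_off_measured = k_off_model / w^2 / c`.
* **Concentration-response quantification** (`tmcoop.quantify`) — Hill
  fits `theta = [L]^n / (K_d + [L]^n)`, the free-ligand correction
  `([added] - [F-actin] * occupancy / 4) / 1000`, severing-rate
  arithmetic.
* **Synthetic data** (`tmcoop.synth`) — seeded generators for every input
  table with ground truth recorded in metadata.

## Worked example

Where does the *first* tropomyosin land on a growing filament, and can we
recover the association rate from the event times?

```python
import numpy as np
from tmcoop import FirstBindingParams, simulate_first_binding_batch, fit_kon

params = FirstBindingParams(kon_len=4e-6, v_grow=47.5, seed=1)
events = simulate_first_binding_batch(params, 2000)
times  = np.array([e.t_bind for e in events])
fit    = fit_kon(times, v_grow=params.v_grow, rng=np.random.default_rng(0))
print(f"tau* = {1/np.sqrt(params.a):.1f} s, median = {np.median(times):.1f} s")
print(f"kon_len = {fit.kon_len:.2e} ({fit.ci_low:.2e} .. {fit.ci_high:.2e})")
```

prints

```
tau* = 72.5 s, median = 87.1 s
kon_len = 4.06e-06 (3.91e-06 .. 4.24e-06)
```

i.e. the most likely first-binding time at the fitted association rate
(4e-6 s^-1 nm^-1) is ~72 s after nucleation, and the maximum-likelihood
estimator recovers the generative rate with a ~8% confidence band at
n = 2000 filaments.

The directory `examples/` holds one short script per capability
(kymograph rendering, oracle agreement, first/second binding, residence
times, Hill scans); each builds a small input, runs the method and prints
annotated numbers.  A thin CLI mirrors the main entry points:

```bash
tmcoop equilibrium --k 0.05 --w 40 --c 1.25 --infinite
tmcoop second-binding p2 --la 10 --l1 2 --x1 4 --l2 2 --c 2
tmcoop synth residence --seed 4 --out out/ && tmcoop survival --table out/residence.csv
```

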