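# Methods

## The lattice model

An actin filament carries two helical grooves, each of which can be coated
by an end-to-end polymer ("cable") of tropomyosin coiled-coil dimers.  A
fission-yeast tropomyosin dimer spans four actin monomers along one
long-pitch strand — eight monomers of the filament overall — so the
filament is modelled as a two-row lattice whose columns are tropomyosin
footprints of length l = 8 x 2.7 nm = 21.6 nm.  Site (i, j) (column i,
groove j) is occupied (x_ij = 1) or empty (x_ij = 0).

Rates.  An empty site binds at

    k_on * w^a * c^b

and an occupied site unbinds at `k_off / (w^a * c^b)`, where

* `a in {0, 1, 2}` is the number of occupied immediate neighbours in the
  same row (end-to-end cooperativity, factor `w`); filament ends have at
  most one neighbour and there are no phantom sites or periodic wrap;
* `b in {0, 1}` is the occupancy of the facing site in the other row
  (indirect cooperativity through the filament, factor `c`).

Because each factor multiplies the on-rate and divides the off-rate, a
fixed-length lattice satisfies detailed balance with respect to

    pi(config) ~ K^n * (w^2)^p_row * (c^2)^p_cross ,   K = k_on / k_off,

with `n` occupied sites, `p_row` same-row adjacent occupied pairs and
`p_cross` doubly occupied columns.  This is a two-row Ising lattice gas;
its equilibrium is computed exactly in `equilibrium.py` both by brute
enumeration (N <= 10) and by a 4x4 column transfer matrix (any N,
including the infinite limit), and the two agree to 1e-10.  These serve as
the ground-truth oracle for the kinetic simulator.

Growth.  Filament elongation is one more stochastic event of rate
`v_grow` (sites/s).  When it fires at time t the site count becomes
`max(N, floor(t * v_grow))`, appending empty columns at the barbed end
(site 0 is the pointed end, matching the convention that the oldest
lattice is at the pointed end).  `v_grow` defaults to 2.2 sites/s
(~47.5 nm/s), a typical barbed-end elongation rate at 1.5 uM Mg-ATP-actin;
no measured value constrains it, and results that depend on it — notably
the steepness of simulated loading curves, see Limitations — should be
read with that assumption in mind.

Dynamics are solved by an exact Gillespie algorithm: waiting times are
exponential in the total propensity, the event is chosen proportionally to
its rate (row-major site order, growth last), and only the flipped site,
its two same-row neighbours and the facing site have their rates updated.
The hot loop is a numba kernel with two-level (64-slot block) cumulative
selection; totals are rebuilt every 65 536 events to bound float drift.
A single seeded RNG drives the whole run and identical seeds give
bit-identical trajectories.  A plain-NumPy single-event `step()` with the
same conventions is the reference implementation used in contract tests.
Molecules never slide; sub-footprint defects cannot be represented (the
lattice is deliberately not refined below one footprint).

Fixed lattices terminate at `max_time`, at complete filling (the default,
matching the original stopping rule; disabled for time-averaging runs), or
when the propensity reaches zero; growing filaments terminate at
`max_time` or at a requested target length.

## Observation model

Three post-processing steps turn raw occupancy into a TIRFM-like signal:

1. labeling — only a fraction (default 0.2) of molecules carry a dye;
   occupied sites are kept with that probability.  Per-molecule mode
   assigns a persistent label at binding (temporally coherent kymographs);
   per-snapshot mode resamples every frame.  For a single snapshot the two
   are statistically identical, which is why coverage readouts use the
   per-snapshot form.
2. broadening — optical resolution ~100 nm: each visible site is dilated
   by +/-4 sites within its row, clipped at the filament ends.
3. row sum — the grooves are not resolved; the two rows are summed to a
   fluorescence level of 0, 1 or 2.

The order label -> broaden -> sum is fixed and regression-tested.
Coverage statistics (total occupancy, single- and double-coated fractions,
`total = (single + 2 * double) / 2`) are always computed on the raw
occupancy.  Kymographs mark columns beyond the current barbed end with a
sentinel (-1) to distinguish "no filament yet" from "filament, dark".
Cable spreading velocities are the least-squares slopes of the outermost
lit site over the best-fitting window of at least 15 s, separately for the
barbed- and pointed-directed edges.

## Coverage scans and the Hill coefficient

`hill_from_lattice_scan` reproduces the loading-curve quantification: for
fixed (k_off, w, c), k_on is scanned across the loading transition; at
each k_on, 24 replicate filaments are grown and their processed
fluorescence is read the moment each reaches 6 um (the filament length at
which experimental coverage was quantified); mean coverage vs k_on is fit
to the Hill form

    theta = [L]^n / (K_d + [L]^n)

with a free amplitude, because labeling holes keep the processed signal
below saturation.  `K_d` in this form carries units of `[L]^n`; the
half-saturation point EC50 = K_d^(1/n) is reported alongside.  The Hill
exponent is invariant to linear rescaling of the abscissa, so k_on is used
directly with no concentration calibration.

The k_on grid is placed adaptively: the equilibrium half-coverage point
from the transfer matrix seeds a coarse scan (nucleation on a growing
filament shifts the kinetic transition above the equilibrium one); the
fine grid is then 9 geometric points over [k_mid/1.6, k_mid*1.6] around
the kinetic half-coverage crossing.  Near the transition individual
filaments are close to all-or-nothing, so the fitted exponent is noisy;
averaging independent scans reduces its spread without changing what is
being estimated.

## First-binding theory

For a filament growing at `v_grow` (nm/s) with a uniform association rate
per length `kon_len` (s^-1 nm^-1), the binding hazard is
`k(t) = a t` with `a = kon_len * v_grow`, giving

* survival `P1(t) = exp(-a t^2 / 2)`,
* first-binding density `P(tau) = a tau exp(-a tau^2 / 2)` (Rayleigh,
  mode `1/sqrt(a)`),
* site-age density `sqrt(pi a / 2) * erfc(tau_age sqrt(a/2))` (binding
  position is uniform over the current length; its closed-form CDF
  `sqrt(pi) u erfc(u) + 1 - exp(-u^2)`, `u = tau_age sqrt(a/2)`, is used
  for KS tests).

The discrete-time Monte Carlo twin uses per-step binding probability
`1 - exp(-a t dt)`; its default step is `0.05 / sqrt(a)` (5% of the modal
time), and distribution-level comparisons use `0.01 / sqrt(a)` so that
grid discretisation stays well below the KS resolution at n = 5000.
Unbound filaments at `max_time` are returned right-censored.  The MLE for
`a` is `2 n_uncensored / sum(tau_i^2)` with censored times entering the
sum, and `kon_len = a / v_grow`; CIs are bootstrap percentile intervals.
The default `kon_len = 4e-6 s^-1 nm^-1` is the value that reproduces
observed first-binding times.

## Second-binding counting model

Geometries live on a 100-nm grid (the experimental resolution): filament
length `L_a`, first cable `L_1` at `x_1`, second cable `L_2`.  Placements
of the second cable strictly clear of the first count twice (two free
grooves); overlapping placements count once with the overlap weighted by
`c` — `N2(c) = U + c V` with purely geometric U, V, which makes
likelihood scans over c cheap.  `p2 = N2/(N1+N2)`.  Choices inherited
verbatim from the counting rule, kept deliberately:

* strict inequalities leave placements exactly abutting the first cable in
  neither count (`inclusive_ends=True` closes them for sensitivity
  analysis);
* an overhanging second cable (`L_2 > L_1`) attributes its whole tail to
  the overlap term of the branch its start falls in, so mirror geometries
  can differ slightly; reflection symmetry holds whenever `L_2 <= L_1`,
  and one asymmetric case is pinned in the tests.

Current occupancy is `L_1 / (2 L_a)` (never above 50%), binned into
0-12.5%, 12.5-25% and 25-50% with half-open edges (the top bin closes at
50%).  The bootstrap re-runs an observed event set with Bernoulli(p2)
outcomes (default 5000 replicates) and reports per-bin overlap fractions;
empty bins are absent, not zero.  `estimate_c` maximises the Bernoulli
likelihood on a geometric c grid (1.0 always included), with a resampled-
events bootstrap CI and a 1-dof likelihood-ratio test against c = 1.

## Residence times

Survival of bound molecules is estimated with the Kaplan-Meier
product-limit estimator (deaths before censorings at ties; delegated to
lifelines) and fit to `f0 exp(-x / T1)` by nonlinear least squares on the
KM curve — the convention used for the single-molecule measurements — with
a censored MLE (`T1 = sum(durations)/n_uncensored`) as the alternative
that stays well behaved under heavy censoring.  For a molecule buried in a
fully coated cable the identity `k_off_measured = k_off_model / w^2 / c`
links the microscopic lattice parameters to the measured single-molecule
off-rate; `residence_times_from_trajectory` extracts interior-site dwell
times from a simulated coated cable (molecules binding late in the run can
be excluded to keep censoring negligible) and the suite verifies the
identity by KS test.

## Synthetic data

`synth.py` generates every tabular input with known ground truth recorded
in a metadata JSON next to the CSV; outputs are byte-identical under a
fixed seed and recovery tests read truth only from the metadata.  What the
generators do and do not emulate:

* first-binding events come from the same discrete-time model the theory
  describes — they carry its sampling noise but none of the experimental
  localisation error or the ambiguity of scoring a "stable" first event;
* second-binding geometries are drawn from configurable distributions
  chosen to populate all three occupancy bins (filament length uniform on
  5-60 grid units, first cable uniform up to the filament length, second
  cable up to a third of it); the real geometry distribution is unknown,
  so recovery results say nothing about geometry-driven confounding;
* residence tables are ideal exponentials with sharp-window censoring — no
  tracking loss, no minimum-track-length selection;
* occupancy curves are Hill-shaped with additive truncated Gaussian noise,
  clipped to [0, 1]; real error bars are SEM over few reactions.

Passing recovery tests therefore demonstrates estimator correctness under
the models' own assumptions, not robustness to real-data artefacts.

## Numerical choices and problem sizes

* Tolerances: oracle cross-checks at 1e-10; KMC-vs-oracle at 3 standard
  errors over independent replicate runs (with a 1e-3 floor on the SE so
  the criterion never sharpens below Monte Carlo resolution); KS tests at
  p > 0.01; parameter recovery at 10% seed-averaged.
* Hill fits are initialised from the logit-log slope and optimised in
  (log EC50, n) space, which stays well conditioned at n ~ 15 where
  K_d = EC50^n spans hundreds of orders of magnitude.
* The coverage-scan acceptance computation uses 24 replicates x 9 k_on
  points per scan and averages 12 scans per parameter set (~2600 simulated
  filaments each), chosen so the scan-to-scan spread of the Hill exponent
  (SD ~0.4-0.8 for a single scan) shrinks well below the comparison band.
* Event logs are preallocated (4e6 events by default); long equilibrium
  runs disable logging and accumulate time-averaged occupancy (and, on
  lattices of up to six columns, per-configuration dwell times) in-kernel,
  after a burn-in that discards the relaxation transient.

## Limitations

* The simulated Hill exponent depends strongly on the assumed growth rate
  (roughly, slower growth leaves more time to equilibrate and steepens the
  transition: rerunning the identical pipeline at 1.1 / 2.2 / 3.3 sites/s
  moves the indirect-cooperativity set's exponent from ~18 to ~11 to ~8).
  With no measured v_grow to pin this down, exponents from
  `hill_from_lattice_scan` should be compared between parameter sets run
  at the same v_grow rather than read as absolute constants.
* No photophysics: the observation model has no point-spread function,
  camera noise or photobleaching; broadening is a hard dilation.
* The counting model is purely combinatorial — it has no kinetics, and its
  verbatim branch rules (abutting placements uncounted, overhang
  asymmetry) are conventions, not physics.
* Kaplan-Meier fitting assumes a single exponential; multi-state dwell
  processes are out of scope.
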