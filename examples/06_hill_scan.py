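"""Cooperativity of simulated loading curves: the Hill coefficient.

Scans k_on across the loading transition of the growing-filament lattice
model, reads the TIRFM-processed coverage of 6-um filaments, and fits the
Hill equation.  A reduced replicate count keeps this demo quick; the
acceptance script runs the full 24-replicate version for both published
parameter sets.
"""

from tmcoop import hill_from_lattice_scan

scan = hill_from_lattice_scan(koff=116.8, w=40.0, c=1.0, n_rep=8, seed=11)
print("end-to-end cooperativity only (k_off=116.8 /s, w=40):")
for k, cov in zip(scan.kon, scan.coverage):
    print(f"  k_on = {k:.4f} /s -> processed coverage {cov:.3f}")
print(f"Hill coefficient n = {scan.hill.n:.1f} "
      f"(half-coverage at k_on = {scan.hill.ec50:.4f} /s)")
print("n >> 1: a ~30% change in k_on switches filaments from bare to coated")
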