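"""Physical constants of the actin / tropomyosin lattice geometry.

A tropomyosin Cdc8 coiled-coil dimer spans four actin monomers along one
long-pitch strand of the filament, i.e. eight monomers of the filament
overall, so one lattice site of one cable row corresponds to a physical
length of 8 x 2.7 nm = 21.6 nm.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: axial rise per actin monomer in the filament (nm)
ACTIN_MONOMER_RISE_NM: float = 2.7

#: actin monomers spanned by one bound tropomyosin (both strands counted)
MONOMERS_PER_SITE: int = 8

#: physical length of one lattice site (nm)
SITE_LENGTH_NM: float = MONOMERS_PER_SITE * ACTIN_MONOMER_RISE_NM

#: gas constant in kcal mol^-1 K^-1
R_KCAL_PER_MOL_K: float = _sc.R / _sc.calorie / 1000.0


def coupling_free_energy_kcal_per_mol(factor: float, temperature_K: float = 298.0) -> float:
    """Free-energy stabilization equivalent to a multiplicative affinity factor.

    A cooperativity factor ``c`` on an equilibrium constant corresponds to a
    stabilization of magnitude ``k_B T ln(c)`` per molecule (``R T ln(c)`` per
    mole).  For ``factor=2`` at 298 K this is ~0.41 kcal/mol, i.e. well below
    a hydrogen bond -- a very subtle structural change suffices.

    Parameters
    ----------
    factor : multiplicative change in affinity (> 0).
    temperature_K : absolute temperature in kelvin.

    Returns
    -------
    Free-energy magnitude in kcal/mol.
    """
    if factor <= 0:
        raise ValueError("affinity factor must be positive")
    return R_KCAL_PER_MOL_K * temperature_K * abs(math.log(factor))
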