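"""Physical constants and unit conversions used throughout vcdkit.

Coordinates are stored in Angstrom, energies in Hartree, and every
user-facing energy threshold in kcal/mol.
"""

import numpy as np
import scipy.constants as _sc

#: 1 Hartree in kcal/mol (CODATA-derived).
HARTREE_TO_KCAL: float = 627.509474

#: Gas constant in kcal/(mol K).
R_KCAL_PER_MOL_K: float = 1.987204e-3

#: Default temperature (K) for Boltzmann populations.
DEFAULT_TEMPERATURE: float = 298.15

#: h / (8 pi^2 c) expressed so that B [cm^-1] = ROTCONST_CM / I [amu A^2].
ROTCONST_CM: float = _sc.h / (8.0 * np.pi**2 * (_sc.c * 100.0) * _sc.u * 1e-20)

# Molar-absorptivity prefactors: epsilon(nu) = nu * sum_i D_i L_i(nu) / 2.296e-39
# with D in esu^2 cm^2; dipole strengths are carried in 10^-40 esu^2 cm^2 and
# rotational strengths in 10^-44 esu^2 cm^2, and VCD carries the standard
# extra factor of 4.  These cancel in the normalized overlap estimate; they
# matter only for absolute intensity axes.
IR_EPSILON_PREFACTOR: float = 1e-40 / 2.296e-39
VCD_EPSILON_PREFACTOR: float = 4.0e-44 / 2.296e-39

#: Principal moments below this (amu A^2) are treated as exactly zero
#: (linear-molecule guard).
LINEAR_MOMENT_CUTOFF: float = 1e-10
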