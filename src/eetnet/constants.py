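"""Physical constants and unit-conversion factors.

Everything is derived at import time from CODATA values in
:mod:`scipy.constants` so the conversion factors used by the coupling and
rate formulas are exact rather than rounded literals.

Working units across the package:

* energies and couplings in wavenumbers (cm^-1)
* distances in Angstrom (geometry) or nm (dipole coupling law)
* transition dipoles in Debye, transition charges in elementary charges
* rates in ps^-1, time constants in ps
"""

import math

import scipy.constants as _sc

#: hc in J*cm (energy of a 1 cm^-1 photon)
HC_JCM = _sc.h * _sc.c * 100.0

#: Debye in C*m
DEBYE = 1e-21 / _sc.c

#: Boltzmann constant in cm^-1 / K
K_B_CM = _sc.k / HC_JCM

#: Coulomb prefactor for the point-dipole coupling law
#: V[cm^-1] = DIPOLE_COUPLING_CM * kappa * mu_i[D] * mu_j[D] / R[nm]^3
DIPOLE_COUPLING_CM = DEBYE**2 / (4.0 * math.pi * _sc.epsilon_0 * 1e-27) / HC_JCM

#: Coulomb prefactor for the transition-charge sum
#: V[cm^-1] = TRESP_COULOMB_CM * sum q_a[e] q_b[e] / r_ab[Angstrom]
TRESP_COULOMB_CM = _sc.e**2 / (4.0 * math.pi * _sc.epsilon_0 * 1e-10) / HC_JCM

#: Golden-rule prefactor: k[ps^-1] = FORSTER_RATE_CM * V[cm^-1]^2 * J[cm]
#: (2*pi/hbar) * (hc*V)^2 * J/(hc) = 4*pi^2*c * V^2 * J
FORSTER_RATE_CM = 4.0 * math.pi**2 * (_sc.c * 100.0) * 1e-12

#: 1 e*Angstrom expressed in Debye
EA_TO_DEBYE = _sc.e * 1e-10 / DEBYE

#: FWHM -> Gaussian standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
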