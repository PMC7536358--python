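"""Physical constants and the package-wide unit conventions.

Public quantities are expressed in the units conventional for detector
instrumentation work: keV, ns, mV, uA, fF/pF, mS, V, cm^-3.  Computations
convert to SI at function boundaries using the factors below.
"""

# fundamental constants (SI)
ELECTRON_CHARGE_C = 1.602176634e-19
BOLTZMANN_J_PER_K = 1.380649e-23
ELECTRON_REST_KEV = 510.99895

# silicon material constants
EPS_SI_F_PER_CM = 11.7 * 8.8541878128e-14
SI_DENSITY_G_CM3 = 2.33
SI_Z = 14
SI_A = 28.086
#: mean energy per electron-hole pair in silicon (standard value, eV)
PAIR_ENERGY_EV = 3.6

# low-field carrier mobilities at 300 K, cm^2/(V s)
MU_ELECTRON_CM2_VS = 1350.0
MU_HOLE_CM2_VS = 480.0

# unit conversion factors
NS = 1e-9
US = 1e-6
FF = 1e-15
PF = 1e-12
MV = 1e-3
UA = 1e-6
MS_SIEMENS = 1e-3
UM_CM = 1e-4
MM_CM = 1e-1


def pairs_from_kev(energy_kev: float) -> float:
    """Number of electron-hole pairs generated by a deposit of ``energy_kev``."""
    return energy_kev * 1e3 / PAIR_ENERGY_EV


def charge_from_kev(energy_kev: float) -> float:
    """Generated charge in coulomb for a deposit of ``energy_kev``."""
    return pairs_from_kev(energy_kev) * ELECTRON_CHARGE_C
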