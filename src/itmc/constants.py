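"""Physical constants used throughout the transport engine.

Unit conventions: lengths in cm, energies in MeV, mass densities in g/cm^3.
Photon energies are stored in MeV and converted to electron-rest-mass units
(``alpha = E / M_E_C2``) where the scattering formulas require it.  Momentum
transfers for atomic form factors are expressed in inverse Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.constants as _sc

#: classical electron radius (cm)
R_E = _sc.physical_constants["classical electron radius"][0] * 100.0

#: electron rest energy (MeV)
M_E_C2 = _sc.physical_constants["electron mass energy equivalent in MeV"][0]

#: Avogadro constant (1/mol)
N_A = _sc.N_A

#: MeV -> J
MEV_TO_J = _sc.e * 1e6

#: energy deposited in MeV per gram -> Gy (J/kg)
MEV_PER_G_TO_GY = MEV_TO_J * 1e3

#: pair-production threshold, 2 m_e c^2 (MeV); the nuclear-recoil term
#: 2 m_e c^2 (m_e / M) is negligible and dropped.
PAIR_THRESHOLD = 2.0 * M_E_C2

#: Thomson cross section (cm^2)
SIGMA_THOMSON = 8.0 * math.pi / 3.0 * R_E**2

#: Hartree energy in MeV, used to convert subshell binding energies to
#: atomic momentum units for Compton profiles.
HARTREE_MEV = _sc.physical_constants["Hartree energy in eV"][0] * 1e-6

#: inverse fine-structure constant: p_z in atomic units is dimensionless
#: momentum in units of m_e * c / 137.036.
INV_FINE_STRUCTURE = 1.0 / _sc.fine_structure


def momentum_transfer_constant() -> float:
    """Momentum-transfer scale k = m_e c / (sqrt(2) h) in 1/Angstrom.

    With q = sin(theta/2)/lambda the squared momentum transfer obeys
    q^2 = (k alpha)^2 (1 - mu) for a photon of energy alpha (rest-mass
    units) scattered through cos(theta) = mu.
    """
    return _sc.m_e * _sc.c / (math.sqrt(2.0) * _sc.h) * 1e-10


#: k = m_e c / (sqrt(2) h) in 1/Angstrom, evaluated from CODATA values
K_COH = momentum_transfer_constant()


@dataclass(frozen=True)
class PhysicsConstants:
    """Bundle of the constants the transport formulas reference."""

    r_e: float = R_E
    m_e_c2: float = M_E_C2
    k_coh: float = K_COH
    N_A: float = N_A

    def __post_init__(self) -> None:
        if min(self.r_e, self.m_e_c2, self.k_coh, self.N_A) <= 0:
            raise ValueError("physics constants must be strictly positive")


CONSTANTS = PhysicsConstants()
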