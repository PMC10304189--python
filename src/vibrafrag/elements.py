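"""Element data and physical constants.

Masses are CODATA/IUPAC standard atomic weights (amu); covalent radii are the
Cordero (2008) single-bond values (Å) commonly used for distance-based bond
perception. Only elements plausible in small-molecule organic crystals are
tabulated; :func:`mass_of` / :func:`covalent_radius` raise on anything else.
"""

from __future__ import annotations

import math

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Fe": 55.845, "Cu": 63.546, "Zn": 65.38, "Br": 79.904, "I": 126.90,
}

#: Cordero-style covalent radii, Å.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Fe": 1.32, "Cu": 1.32, "Zn": 1.22, "Br": 1.20, "I": 1.39,
}

# Physical constants (SI unless noted).
HARTREE_J = 4.3597447222071e-18
AMU_KG = 1.66053906660e-27
SPEED_OF_LIGHT_CM_S = 2.99792458e10
BOHR_ANGSTROM = 0.529177210903

#: Multiply sqrt(λ) with λ in Hartree/(amu·Å²) by this to get wavenumbers (cm⁻¹).
FREQ_CM1_PER_SQRT_EIGVAL = math.sqrt(HARTREE_J / (AMU_KG * 1e-20)) / (
    2.0 * math.pi * SPEED_OF_LIGHT_CM_S
)

#: Coulomb prefactor: E[Hartree] = q1*q2 * COULOMB_HARTREE_ANGSTROM / r[Å].
COULOMB_HARTREE_ANGSTROM = BOHR_ANGSTROM


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the packaged tables."""


def _normalize(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def mass_of(symbol: str) -> float:
    sym = _normalize(symbol)
    try:
        return ATOMIC_MASSES[sym]
    except KeyError:
        raise UnknownElementError(f"no atomic mass tabulated for element {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    sym = _normalize(symbol)
    try:
        return COVALENT_RADII[sym]
    except KeyError:
        raise UnknownElementError(f"no covalent radius tabulated for element {symbol!r}") from None
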