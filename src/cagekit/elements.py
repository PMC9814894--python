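"""Small element property tables used across the package.

Masses in unified atomic mass units, van der Waals radii in Angstroms
(Bondi set), and typical maximum covalent valences for topology sanity
checks.  Only the elements that occur in container molecules and their
small-molecule guests are listed; unknown symbols raise ``KeyError`` with
the offending symbol so that typos in atom names surface early.
"""

from __future__ import annotations

# u (atomic mass units)
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "Na": 22.990,
    "I": 126.904,
}

# Angstrom (Bondi vdW radii)
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "Na": 2.27,
    "I": 1.98,
}

# typical maximum number of covalent bonds
DEFAULT_MAX_VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 4,
    "O": 2,
    "F": 1,
    "P": 5,
    "S": 6,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

#: 1 Angstrom in Bohr radii (CODATA)
ANGSTROM_TO_BOHR = 1.0 / 0.529177210903
BOHR_TO_ANGSTROM = 0.529177210903


def mass_of(element: str) -> float:
    """Atomic mass (u) of *element*; raises ``KeyError`` on unknown symbols."""
    try:
        return ATOMIC_MASS[element]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius (Angstrom) of *element*."""
    try:
        return VDW_RADIUS[element]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def is_valid_element(symbol: str) -> bool:
    return symbol in ATOMIC_MASS
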