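"""Element data: Bondi van der Waals radii, covalent radii, atomic numbers.

Radii are in angstroms. The vdW set is Bondi's 1964 compilation (the one the
contact criterion "sum of vdW radii + 0.5 A" is defined against); covalent
radii follow the Cordero 2008 consensus values rounded to 0.01 A.
"""

from __future__ import annotations

VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Ar": 1.88, "K": 2.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Se": 1.90,
}

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Fe": 1.32, "Cu": 1.32, "Zn": 1.22, "Br": 1.20, "I": 1.39, "Se": 1.20,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Cu": 29,
    "Zn": 30, "Se": 34, "Br": 35, "I": 53,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the radius tables."""


def normalize_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in angstroms."""
    el = normalize_symbol(element)
    try:
        return VDW_RADII[el]
    except KeyError:
        raise UnknownElementError(f"no van der Waals radius for element {element!r}") from None


def covalent_radius(element: str) -> float:
    """Single-bond covalent radius in angstroms."""
    el = normalize_symbol(element)
    try:
        return COVALENT_RADII[el]
    except KeyError:
        raise UnknownElementError(f"no covalent radius for element {element!r}") from None


def atomic_number(element: str) -> int:
    el = normalize_symbol(element)
    try:
        return ATOMIC_NUMBERS[el]
    except KeyError:
        raise UnknownElementError(f"no atomic number for element {element!r}") from None
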