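"""Element data: standard atomic weights (amu) and covalent radii (Å).

Covalent radii follow the widely used single-bond values of Cordero et al.;
only elements plausible in molecular organic/inorganic crystals are listed.
Bond detection uses ``BOND_TOLERANCE`` × (r_i + r_j).
"""

from __future__ import annotations

BOND_TOLERANCE = 1.2

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.630,
    "As": 74.922, "Se": 78.971, "Br": 79.904, "Kr": 83.798, "Rb": 85.468,
    "Sr": 87.62, "Zr": 91.224, "Mo": 95.95, "Ag": 107.87, "Cd": 112.41,
    "Sn": 118.71, "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Pb": 207.2, "Bi": 208.98,
}

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Ti": 1.60, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32, "Co": 1.26,
    "Ni": 1.24, "Cu": 1.32, "Zn": 1.22, "Ga": 1.22, "Ge": 1.20,
    "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16, "Rb": 2.20,
    "Sr": 1.95, "Zr": 1.75, "Mo": 1.54, "Ag": 1.45, "Cd": 1.44,
    "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Pb": 1.46, "Bi": 1.48,
}

KNOWN_ELEMENTS = frozenset(ATOMIC_MASS)


def mass_of(symbol: str) -> float:
    try:
        return ATOMIC_MASS[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None
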