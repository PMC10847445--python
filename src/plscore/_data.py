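"""Static per-element reference data shared across modules.

Covalent radii follow the Cordero et al. compilation (values in Å).
The dispersion-coefficient table is the package's own minimal static set:
free-atom-like C6 values combined geometrically per pair, with C8 derived
from per-element multipole ratios. It deliberately omits the
coordination-number interpolation of the full D3 scheme and is intended
for testing and toy systems, not production dispersion energetics.
"""

from __future__ import annotations

# --- covalent radii, Å -----------------------------------------------------

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22,
    "Br": 1.20, "I": 1.39,
}

RECOGNIZED_ELEMENTS = frozenset(COVALENT_RADII)

# Default formal charges for common metal ions seen as single-atom HETATM
# records; overridable in configuration.
METAL_ION_CHARGES: dict[str, int] = {
    "Zn": 2, "Ca": 2, "Mg": 2, "Mn": 2, "Fe": 2, "Na": 1, "K": 1, "Cl": -1,
}

# Formal charges of ionizable amino-acid residues at neutral pH.
RESIDUE_CHARGES: dict[str, int] = {
    "ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1, "HIS": 0, "HIP": 1,
    "CYM": -1, "TYM": -1,
}

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "TIP3", "SPC"})

STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HIP", "HID", "HIE", "CYM", "CYX", "TYM", "NME", "FOR", "ACE",
})

# --- dispersion coefficients ----------------------------------------------
# Per-element C6 (Ha·bohr^6) and multipole ratio Q used to derive C8:
#   C6_AB = sqrt(C6_A * C6_B)
#   C8_AB = 3 * C6_AB * sqrt(Q_A * Q_B)
# Static table; see module docstring for scope.

_C6_FREE: dict[str, float] = {
    "H": 7.59, "C": 49.11, "N": 25.27, "O": 15.51, "F": 9.69,
    "S": 134.0, "Cl": 94.6, "Br": 162.0, "I": 385.0, "Zn": 126.7,
}

_Q_MULTIPOLE: dict[str, float] = {
    "H": 2.007, "C": 4.842, "N": 3.971, "O": 3.609, "F": 3.350,
    "S": 7.319, "Cl": 6.854, "Br": 8.002, "I": 9.919, "Zn": 5.686,
}

DISPERSION_ELEMENTS = frozenset(_C6_FREE)


def builtin_c6c8(elem_a: str, elem_b: str) -> tuple[float, float]:
    """Return (C6, C8) in Ha·bohr^6 / Ha·bohr^8 for an element pair."""
    if elem_a not in _C6_FREE or elem_b not in _C6_FREE:
        missing = [e for e in (elem_a, elem_b) if e not in _C6_FREE]
        raise KeyError(f"no dispersion coefficients for element(s): {missing}")
    c6 = (_C6_FREE[elem_a] * _C6_FREE[elem_b]) ** 0.5
    c8 = 3.0 * c6 * (_Q_MULTIPOLE[elem_a] * _Q_MULTIPOLE[elem_b]) ** 0.5
    return c6, c8


# --- classical test-backend parameters -------------------------------------
# Lennard-Jones sigma (Å) / epsilon (kcal/mol) and Born-like radii (Å).

LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.030), "C": (3.40, 0.086), "N": (3.25, 0.170),
    "O": (3.00, 0.210), "S": (3.60, 0.250), "P": (3.70, 0.200),
    "F": (2.90, 0.060), "Cl": (3.40, 0.300), "Br": (3.60, 0.320),
    "I": (3.90, 0.400), "Zn": (2.00, 0.250), "Na": (2.60, 0.030),
    "K": (3.10, 0.030), "Ca": (2.70, 0.240), "Mg": (2.20, 0.880),
}

BORN_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80, "P": 1.85,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Zn": 1.40, "Na": 1.60,
    "K": 2.00, "Ca": 1.70, "Mg": 1.50,
}

# Unit conversions.
HARTREE_TO_KCAL = 627.509
ANGSTROM_TO_BOHR = 1.8897259886
COULOMB_KCAL = 332.0636  # kcal·Å/(mol·e²)
GAS_CONSTANT_KCAL = 1.98720e-3  # kcal/(mol·K)
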