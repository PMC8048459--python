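"""Physical constants, unit conversion factors, and per-element lookup tables.

All internal quantities use nm, kJ/mol, amu, and radians (degrees only at
I/O boundaries). Every conversion factor used anywhere in the package lives
here so emitted parameters are reproducible from a single table.
"""

from __future__ import annotations

# --- unit conversions -------------------------------------------------------

#: kJ/mol per Hartree
HARTREE_TO_KJ_PER_MOL = 2625.4996

#: nm per Bohr
BOHR_TO_NM = 0.0529177

#: Hessian scale factor Hartree/Bohr^2 -> kJ mol^-1 nm^-2
HARTREE_PER_BOHR2_TO_KJ_PER_MOL_NM2 = HARTREE_TO_KJ_PER_MOL / BOHR_TO_NM**2

# --- fundamental constants (CODATA 2018) ------------------------------------

AVOGADRO = 6.02214076e23          # mol^-1
SPEED_OF_LIGHT_CM_S = 2.99792458e10   # cm/s
AMU_KG = 1.66053906660e-27        # kg

#: Converts a mass-weighted Hessian eigenvalue (kJ mol^-1 nm^-2 amu^-1)
#: into angular frequency squared (s^-2).
EIGENVALUE_TO_OMEGA2 = 1.0e3 / (AVOGADRO * AMU_KG * 1.0e-18)

# --- geometry tolerances (defaults; config-overridable by callers) ----------

COINCIDENT_ATOM_TOL_NM = 1e-6
COLLINEAR_ANGLE_TOL_RAD = 1e-4

# --- element tables ---------------------------------------------------------

#: isotope-averaged atomic masses (amu), keyed by element symbol
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "I": 126.90447,
}

#: element symbols by atomic number (the span the checkpoint reader accepts)
ELEMENT_BY_NUMBER = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 26: "Fe", 30: "Zn",
    34: "Se", 35: "Br", 53: "I",
}

ATOMIC_NUMBER_BY_ELEMENT = {v: k for k, v in ELEMENT_BY_NUMBER.items()}

#: single-bond covalent radii (nm), used for bond-graph inference
COVALENT_RADII_NM = {
    "H": 0.031, "He": 0.028,
    "Li": 0.128, "Be": 0.096, "B": 0.084, "C": 0.076, "N": 0.071,
    "O": 0.066, "F": 0.057, "Ne": 0.058,
    "Na": 0.166, "Mg": 0.141, "Al": 0.121, "Si": 0.111, "P": 0.107,
    "S": 0.105, "Cl": 0.102, "Ar": 0.106,
    "K": 0.203, "Ca": 0.176, "Fe": 0.132, "Zn": 0.122,
    "Se": 0.120, "Br": 0.120, "I": 0.139,
}

#: Bondi van der Waals radii (nm), used as per-element SASA radii
VDW_RADII_NM = {
    "H": 0.120, "He": 0.140,
    "C": 0.170, "N": 0.155, "O": 0.152, "F": 0.147, "Ne": 0.154,
    "Na": 0.227, "Mg": 0.173, "Si": 0.210, "P": 0.180, "S": 0.180,
    "Cl": 0.175, "Ar": 0.188,
    "K": 0.275, "Zn": 0.139, "Se": 0.190, "Br": 0.185, "I": 0.198,
}


def mass_of(element: str) -> float:
    """Isotope-averaged mass (amu) for an element symbol."""
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
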