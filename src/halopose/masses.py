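"""Atomic and residue mass tables.

Monoisotopic masses are the most-abundant-isotope masses (CODATA/AME-derived
values as tabulated by IUPAC); average masses are conventional standard
atomic weights. Charged-species masses must be electron-corrected by the
caller (see :data:`ELECTRON`), which matters at the fourth decimal place for
singly charged peptide ions.
"""

from __future__ import annotations

#: Monoisotopic atomic masses in Da.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "F": 18.99840320,
    "I": 126.904473,
    "Se": 79.9165218,
}

#: Standard atomic weights (abundance-weighted averages) in Da.
AVERAGE: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
    "P": 30.973761,
    "Cl": 35.453,
    "Br": 79.904,
    "F": 18.9984032,
    "I": 126.90447,
    "Se": 78.96,
}

#: Proton mass in Da (already electron-corrected: m(H) - m(e)).
PROTON: float = 1.00727646677

#: Electron mass in Da.
ELECTRON: float = 0.00054857990946

#: Elemental composition of the 20 canonical amino-acid residues
#: (residue = amino acid minus one water; peptide = sum of residues + H2O).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Average atomic masses of common elements used for center-of-mass work, amu.
#: Keyed by element symbol; looked up from PDB atom names.
ELEMENT_MASSES_AMU: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Heavy-atom names used here (NZ, CE, CZ3, C5, CG, CA, OD1, SD ...) start
    with the element letter; hydrogen names may start with a digit (1HB).
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        return "H"
    return name[0].upper()


def element_mass_amu(atom_name: str) -> float:
    """Mass in amu for a PDB atom name, via :func:`element_from_atom_name`."""
    element = element_from_atom_name(atom_name)
    try:
        return ELEMENT_MASSES_AMU[element]
    except KeyError:
        raise KeyError(
            f"no mass tabulated for element {element!r} (atom {atom_name!r})"
        ) from None
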