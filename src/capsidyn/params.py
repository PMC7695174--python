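"""Bonded equilibrium values (Amber-ff03-valued) and hybridization tables.

The structure-based model takes stabilizing interactions from the
reference conformation, but bond and angle *equilibria* are assigned the
values of the Amber ff03 parameter set wherever a parameter exists; the
table below is a condensed, type-based transcription (atom names are
mapped to Amber atom-type classes per residue, and equilibria are looked
up by type tuple).  Terms with no tabulated value fall back to the
reference geometry -- the caller decides whether that fallback is
allowed, and it is always logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ParameterTable", "ParameterLookupError", "STANDARD_RESIDUES",
           "is_sp2", "UnknownResidueError"]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ParameterLookupError(KeyError):
    """A bonded term has no tabulated equilibrium value."""


class UnknownResidueError(KeyError):
    """A residue name is not covered by the parameter/hybridization tables."""


# --- atom-name -> Amber type-class mapping -------------------------------
_BACKBONE_TYPES = {"N": "N", "CA": "CT", "C": "C", "O": "O", "OXT": "O2"}

# side-chain atoms that deviate from the aliphatic default (CT / N3 / OH / S)
_SIDECHAIN_TYPES: dict[str, dict[str, str]] = {
    "ARG": {"NE": "N2", "CZ": "CA", "NH1": "N2", "NH2": "N2"},
    "ASN": {"CG": "C", "OD1": "O", "ND2": "N"},
    "ASP": {"CG": "C", "OD1": "O2", "OD2": "O2"},
    "GLN": {"CD": "C", "OE1": "O", "NE2": "N"},
    "GLU": {"CD": "C", "OE1": "O2", "OE2": "O2"},
    "HIS": {"CG": "CC", "ND1": "NA", "CD2": "CV", "CE1": "CR", "NE2": "NB"},
    "PHE": {"CG": "CA", "CD1": "CA", "CD2": "CA", "CE1": "CA", "CE2": "CA",
            "CZ": "CA"},
    "TYR": {"CG": "CA", "CD1": "CA", "CD2": "CA", "CE1": "CA", "CE2": "CA",
            "CZ": "C", "OH": "OH"},
    "TRP": {"CG": "C*", "CD1": "CW", "CD2": "CB", "NE1": "NA", "CE2": "CN",
            "CE3": "CA", "CZ2": "CA", "CZ3": "CA", "CH2": "CA"},
    "CYS": {"SG": "SH"},
    "MET": {"SD": "S"},
    "SER": {"OG": "OH"},
    "THR": {"OG1": "OH"},
    "LYS": {"NZ": "N3"},
}

_AROMATIC_TYPES = {"CA", "CC", "CV", "CR", "CB", "C*", "CW", "CN", "NA", "NB"}

# --- equilibrium bond lengths by type pair, nm (ff03 / parm99 values) ----
_BOND_EQ: dict[frozenset, float] = {
    frozenset(s): v for s, v in [
        (("N", "CT"), 0.1449), (("CT", "C"), 0.1522), (("C", "N"), 0.1335),
        (("C", "O"), 0.1229), (("C", "O2"), 0.1250), (("CT", "CT"), 0.1526),
        (("CT", "OH"), 0.1410), (("CT", "N3"), 0.1471), (("CT", "S"), 0.1810),
        (("CT", "SH"), 0.1810), (("S", "S"), 0.2038), (("CA", "CA"), 0.1400),
        (("CA", "CT"), 0.1510), (("C", "OH"), 0.1364), (("CA", "N2"), 0.1340),
        (("CT", "N2"), 0.1463), (("CT", "N"), 0.1449), (("C", "CA"), 0.1409),
        (("CC", "CT"), 0.1504), (("CC", "NA"), 0.1385), (("CC", "CV"), 0.1375),
        (("CR", "NA"), 0.1343), (("CR", "NB"), 0.1335), (("CV", "NB"), 0.1394),
        (("C*", "CT"), 0.1495), (("C*", "CW"), 0.1352), (("C*", "CB"), 0.1459),
        (("CW", "NA"), 0.1381), (("CB", "CN"), 0.1419), (("CN", "NA"), 0.1380),
        (("CB", "CA"), 0.1404), (("CN", "CA"), 0.1400),
    ]
}
# symmetric-pair entries (same type twice) need explicit keys
_BOND_EQ[frozenset(("CT",))] = 0.1526
_BOND_EQ[frozenset(("CA",))] = 0.1400
_BOND_EQ[frozenset(("S",))] = 0.2038

# --- equilibrium angles by type triple, degrees --------------------------
_ANGLE_EQ: dict[tuple, float] = {}
for (a, b, c), v in [
    (("N", "CT", "C"), 110.1), (("CT", "C", "N"), 116.6), (("C", "N", "CT"), 121.9),
    (("CT", "C", "O"), 120.4), (("N", "C", "O"), 122.9), (("CT", "CT", "CT"), 109.5),
    (("CT", "CT", "C"), 111.1), (("CT", "CT", "N"), 109.7), (("N", "CT", "CT"), 109.7),
    (("CT", "CT", "OH"), 109.5), (("CT", "CT", "S"), 114.7), (("CT", "S", "S"), 103.7),
    (("CT", "CT", "SH"), 108.6), (("CT", "CT", "N3"), 111.2), (("CT", "S", "CT"), 98.9),
    (("CA", "CA", "CA"), 120.0), (("CA", "CA", "CT"), 120.0), (("CT", "C", "O2"), 117.0),
    (("O2", "C", "O2"), 126.0), (("CT", "CT", "N2"), 111.2), (("CT", "N2", "CA"), 123.2),
    (("N2", "CA", "N2"), 120.0), (("CT", "C", "CA"), 120.0), (("C", "CA", "CA"), 120.0),
    (("CA", "C", "OH"), 120.0), (("O", "C", "N"), 122.9),
]:
    _ANGLE_EQ[(a, b, c)] = v
    _ANGLE_EQ[(c, b, a)] = v

# --- sp2 / planar atoms for dihedral classification ----------------------
# backbone amide atoms are planar in every residue
_SP2_BACKBONE = {"C", "N", "O", "OXT"}
_SP2_SIDECHAIN: dict[str, set[str]] = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "ASN": {"CG", "OD1", "ND2"},
    "ASP": {"CG", "OD1", "OD2"},
    "GLN": {"CD", "OE1", "NE2"},
    "GLU": {"CD", "OE1", "OE2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}


def is_sp2(res_name: str, atom_name: str) -> bool:
    """Whether an atom belongs to a planar (sp2-hybridized) group.

    Raises :class:`UnknownResidueError` for residues outside the 20
    standard amino acids.
    """
    res = res_name.upper()
    if res not in STANDARD_RESIDUES:
        raise UnknownResidueError(f"residue {res_name!r} not in hybridization table")
    name = atom_name.upper()
    if name in _SP2_BACKBONE:
        return True
    return name in _SP2_SIDECHAIN.get(res, set())


def atom_type(res_name: str, atom_name: str) -> str:
    """Amber type class for an atom, by residue and atom name."""
    res = res_name.upper()
    if res not in STANDARD_RESIDUES:
        raise UnknownResidueError(f"residue {res_name!r} not in parameter table")
    name = atom_name.upper()
    if name in _BACKBONE_TYPES:
        return _BACKBONE_TYPES[name]
    side = _SIDECHAIN_TYPES.get(res, {})
    if name in side:
        return side[name]
    if name.startswith("C"):
        return "CT"
    if name.startswith("O"):
        return "OH"
    if name.startswith("N"):
        return "N3"
    if name.startswith("S"):
        return "S"
    raise ParameterLookupError(f"no type class for atom {atom_name!r} in {res_name!r}")


@dataclass
class ParameterTable:
    """Equilibrium bond lengths (nm) and angles (radians) by bonded term.

    Lookup is by ``(residue_name, atom-name tuple)``; extra entries can be
    supplied to override or extend the shipped ff03-valued table.
    Lookup failure raises :class:`ParameterLookupError`.
    """

    extra_bonds: dict = field(default_factory=dict)
    extra_angles: dict = field(default_factory=dict)

    def bond_length(self, res_name: str, names: tuple[str, str]) -> float:
        key = (res_name.upper(), tuple(n.upper() for n in names))
        if key in self.extra_bonds:
            return self.extra_bonds[key]
        types = frozenset({atom_type(res_name, names[0]), atom_type(res_name, names[1])})
        if types in _BOND_EQ:
            return _BOND_EQ[types]
        raise ParameterLookupError(f"no bond parameter for {names} in {res_name}")

    def angle(self, res_name: str, names: tuple[str, str, str]) -> float:
        import math

        key = (res_name.upper(), tuple(n.upper() for n in names))
        if key in self.extra_angles:
            return self.extra_angles[key]
        triple = tuple(atom_type(res_name, n) for n in names)
        if triple in _ANGLE_EQ:
            return math.radians(_ANGLE_EQ[triple])
        raise ParameterLookupError(f"no angle parameter for {names} in {res_name}")
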