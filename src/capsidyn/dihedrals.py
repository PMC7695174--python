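"""Dihedral enumeration and rigid/flexible classification.

Rigid dihedrals are those whose central bond joins two planar
(sp2-hybridized) atoms -- the peptide omega bond, ring systems and
side-chain carboxyl/amide/guanidinium planes.  They receive a
periodicity-2 cosine potential with minima at 0 and 180 degrees.  All
remaining proper dihedrals (phi, psi, side-chain chi) are flexible and
are assigned a minimum at the reference conformation's value, so they
specifically stabilize the reference state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import infer_bonds, neighbor_table
from .params import is_sp2
from .structures import MolecularStructure

__all__ = ["DihedralTerm", "classify_dihedrals", "dihedral_angle"]

#: dihedrals are enumerated only when both reference internal angles lie
#: in the 30-150 degree band (sin >= 0.5).  A torsion about a nearly
#: straight triple is numerically ill-defined, and thermal excursions
#: through collinearity would make its force non-conservative; atomistic
#: backbone/side-chain angles (~100-125 degrees) are far inside the band
_MIN_SIN_ANGLE = 0.5


@dataclass(frozen=True)
class DihedralTerm:
    """A proper dihedral: four atom indices, class, reference angle (rad)."""

    atoms: tuple[int, int, int, int]
    kind: str                     # "rigid" | "flexible"
    native_angle: float
    force_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "flexible"):
            raise ValueError(f"unknown dihedral class {self.kind!r}")


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle (radians, IUPAC convention) of four points."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _sin_bond_angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.sqrt(max(0.0, 1.0 - min(1.0, abs(cosang)) ** 2)))


def classify_dihedrals(structure: MolecularStructure,
                       bonds: np.ndarray | None = None) -> list[DihedralTerm]:
    """Enumerate one proper dihedral per rotatable central bond and classify it.

    For each covalent bond ``j-k`` where both atoms have at least one
    further neighbour, the dihedral ``i-j-k-l`` with the lowest-index
    flanking atoms is emitted.  Classification is *rigid* iff both ``j``
    and ``k`` are planar/sp2 per the hybridization table (errors on
    residues outside the standard set).  Dihedrals whose reference
    geometry is near-collinear are skipped (torsion undefined).
    """
    bonds = infer_bonds(structure) if bonds is None else np.asarray(bonds)
    nb = neighbor_table(bonds, structure.n_atoms)
    pos = structure.positions
    res = structure.residue_names
    names = structure.atom_names
    terms: list[DihedralTerm] = []
    res_of = structure.residue_indices
    for j, k in bonds:
        j, k = int(j), int(k)
        if abs(int(res_of[j]) - int(res_of[k])) > 1:
            continue          # bracing bond, not a backbone torsion axis
        others_j = sorted(n_ for n_ in nb[j] - {k}
                          if abs(int(res_of[n_]) - int(res_of[j])) <= 1)
        others_k = sorted(n_ for n_ in nb[k] - {j}
                          if abs(int(res_of[n_]) - int(res_of[k])) <= 1)
        if not others_j or not others_k:
            continue
        i, l = others_j[0], others_k[0]
        if i == l:
            continue
        if (_sin_bond_angle(pos[i], pos[j], pos[k]) < _MIN_SIN_ANGLE
                or _sin_bond_angle(pos[j], pos[k], pos[l]) < _MIN_SIN_ANGLE):
            continue
        rigid = is_sp2(str(res[j]), str(names[j])) and is_sp2(str(res[k]), str(names[k]))
        terms.append(DihedralTerm(
            atoms=(i, j, k, l),
            kind="rigid" if rigid else "flexible",
            native_angle=dihedral_angle(pos[i], pos[j], pos[k], pos[l]),
        ))
    return terms
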