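"""Covalent-bond inference and bonded-exclusion bookkeeping."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structures import MolecularStructure

__all__ = ["infer_bonds", "bonded_exclusions", "neighbor_table"]

# covalent radii, nm (heavy atoms of proteins + common extras)
_COVALENT_RADIUS = {
    "C": 0.076, "N": 0.071, "O": 0.066, "S": 0.105, "P": 0.107,
    "H": 0.031, "SE": 0.120, "F": 0.057, "CL": 0.102, "BR": 0.120,
}
_DEFAULT_RADIUS = 0.077
_BOND_TOLERANCE = 1.25


def infer_bonds(structure: MolecularStructure) -> np.ndarray:
    """Return (m, 2) covalent bond pairs (atom indices, i < j).

    Explicit bonds attached to the structure take precedence.  Otherwise
    bonds are detected by the covalent-distance criterion
    ``d < 1.25 (r_cov_i + r_cov_j)``, restricted to atoms of the same
    chain (peptide C--N linkages included; chains are covalently
    independent).
    """
    if structure.bonds is not None:
        b = np.asarray(structure.bonds, dtype=np.int64)
        return np.sort(b, axis=1)
    radii = np.array([_COVALENT_RADIUS.get(str(e).upper(), _DEFAULT_RADIUS)
                      for e in structure.elements])
    max_cut = _BOND_TOLERANCE * 2 * radii.max()
    tree = cKDTree(structure.positions)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(structure.positions[i] - structure.positions[j], axis=1)
    ok = (d < _BOND_TOLERANCE * (radii[i] + radii[j]))
    ok &= structure.chain_ids[i] == structure.chain_ids[j]
    return np.sort(pairs[ok].astype(np.int64), axis=1)


def neighbor_table(bonds: np.ndarray, n_atoms: int) -> list[set[int]]:
    """Adjacency sets of the covalent graph."""
    nb: list[set[int]] = [set() for _ in range(n_atoms)]
    for a, b in bonds:
        nb[int(a)].add(int(b))
        nb[int(b)].add(int(a))
    return nb


def bonded_exclusions(bonds: np.ndarray, n_atoms: int,
                      residue_indices: np.ndarray | None = None,
                      ) -> set[tuple[int, int]]:
    """All 1-2, 1-3 and 1-4 atom pairs of the covalent graph (i < j).

    Every directly bonded pair is excluded.  When ``residue_indices``
    is given, the 1-3/1-4 expansion walks only bonds between atoms of
    the same or adjacent residues: long-range bracing bonds of coarse
    bead models (which are restraints, not chemistry) then do not
    vaporize the excluded volume around the atoms they join.  Atomistic
    covalent bonds always join adjacent residues, so this changes
    nothing for real structures.
    """
    nb_all = neighbor_table(bonds, n_atoms)
    if residue_indices is None:
        nb_walk = nb_all
    else:
        res = np.asarray(residue_indices)
        walk_bonds = [b for b in bonds
                      if abs(int(res[int(b[0])]) - int(res[int(b[1])])) <= 1]
        nb_walk = neighbor_table(np.array(walk_bonds, dtype=np.int64)
                                 if walk_bonds else np.empty((0, 2), dtype=np.int64),
                                 n_atoms)
    excl: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        if a != b:
            excl.add((a, b) if a < b else (b, a))

    for a in range(n_atoms):
        for b in nb_all[a]:
            add(a, b)                       # 1-2 (all bonds)
        for b in nb_walk[a]:
            for c in nb_walk[b]:
                add(a, c)                   # 1-3
                for d in nb_walk[c]:
                    add(a, d)               # 1-4
    return excl
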