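"""Array-backed molecular structures with chain annotations.

Coordinates are stored in nanometres throughout the package; PDB files
(which use angstroms) are converted on read/write by :mod:`capsidyn.pdbio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChainAnnotation",
    "MolecularStructure",
    "EmptyStructureError",
    "InvalidTransformError",
    "expand_assembly",
    "radius_of_gyration",
    "rmsd",
]

#: elements treated as hydrogen when filtering to heavy atoms
_HYDROGEN = {"H", "D", "T"}


class EmptyStructureError(ValueError):
    """Raised when an operation receives a structure with no atoms."""


class InvalidTransformError(ValueError):
    """Raised when an assembly transform is not a proper rigid motion."""


@dataclass(frozen=True)
class ChainAnnotation:
    """Per-chain metadata: monomer position class and tail residue range.

    Parameters
    ----------
    chain_id : str
        Unique chain identifier.
    position_label : str
        Monomer position class (``A``--``G`` for a T=7 shell; hexon
        positions A--F, penton position G).
    tail_range : tuple of int
        Inclusive 1-based residue interval of the terminal tail.
    """

    chain_id: str
    position_label: str
    tail_range: tuple[int, int] = (2, 25)

    def __post_init__(self) -> None:
        lo, hi = self.tail_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid tail_range {self.tail_range!r}")


@dataclass
class MolecularStructure:
    """A set of atoms with chain/residue bookkeeping, positions in nm.

    Atom order groups by chain, then residue.  Field arrays all have
    length ``n_atoms``.
    """

    elements: np.ndarray          # str
    atom_names: np.ndarray        # str
    residue_indices: np.ndarray   # int, 1-based as deposited
    residue_names: np.ndarray     # str, 3-letter codes
    chain_ids: np.ndarray         # str
    positions: np.ndarray         # (n, 3) float, nm
    chains: list[ChainAnnotation] = field(default_factory=list)
    source: str = ""
    bonds: np.ndarray | None = None   # optional explicit (m, 2) atom-index pairs

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = len(self.positions)
        for name in ("elements", "atom_names", "residue_indices",
                     "residue_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        seen = [a.chain_id for a in self.chains]
        if len(seen) != len(set(seen)):
            raise ValueError("duplicate chain ids in annotations")

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def chain_id_order(self) -> list[str]:
        order: list[str] = []
        for cid in self.chain_ids:
            if not order or order[-1] != cid:
                order.append(str(cid))
        return order

    @property
    def n_chains(self) -> int:
        return len(set(self.chain_ids.tolist()))

    def annotation(self, chain_id: str) -> ChainAnnotation:
        for ann in self.chains:
            if ann.chain_id == chain_id:
                return ann
        raise KeyError(f"chain {chain_id!r} has no annotation")

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def atom_indices(self, chain_id: str,
                     residue_range: tuple[int, int] | None = None) -> np.ndarray:
        """Atom indices of a chain, optionally restricted to a residue interval."""
        mask = self.chain_mask(chain_id)
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.residue_indices >= lo) & (self.residue_indices <= hi)
        return np.flatnonzero(mask)

    def tail_atom_indices(self, chain_id: str) -> np.ndarray:
        ann = self.annotation(chain_id)
        return self.atom_indices(chain_id, ann.tail_range)

    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.elements.astype(str)), list(_HYDROGEN))

    # -- derived structures -------------------------------------------
    def select(self, mask: np.ndarray, source_suffix: str = "") -> "MolecularStructure":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        kept_chains = set(self.chain_ids[idx].tolist())
        return MolecularStructure(
            elements=self.elements[idx].copy(),
            atom_names=self.atom_names[idx].copy(),
            residue_indices=self.residue_indices[idx].copy(),
            residue_names=self.residue_names[idx].copy(),
            chain_ids=self.chain_ids[idx].copy(),
            positions=self.positions[idx].copy(),
            chains=[a for a in self.chains if a.chain_id in kept_chains],
            source=self.source + source_suffix,
        )

    def with_positions(self, positions: np.ndarray) -> "MolecularStructure":
        out = replace(self)
        out.positions = np.asarray(positions, dtype=float).copy()
        if out.positions.shape != self.positions.shape:
            raise ValueError("positions shape mismatch")
        return out


def radius_of_gyration(structure_or_positions,
                       mass_weighted: bool = False,
                       masses: np.ndarray | None = None) -> float:
    """Radius of gyration Rg = sqrt(sum w_i |r_i - rbar|^2 / sum w_i), nm.

    Default is unweighted over the supplied atoms (the usual convention
    for heavy-atom models); pass ``mass_weighted=True`` together with
    ``masses`` to weight by atomic mass.
    """
    if isinstance(structure_or_positions, MolecularStructure):
        pos = structure_or_positions.positions
    else:
        pos = np.asarray(structure_or_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] == 0:
        raise EmptyStructureError("radius_of_gyration needs at least one atom")
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted=True requires masses")
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(len(pos))
    com = np.average(pos, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1), weights=w)))


def rmsd(a: np.ndarray, b: np.ndarray, superimpose: bool = False) -> float:
    """Root-mean-square coordinate deviation between two (n, 3) arrays, nm.

    With ``superimpose=True`` an optimal rigid-body (Kabsch) fit is applied
    first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have matching shape")
    if superimpose:
        from scipy.spatial.transform import Rotation

        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a, b)
        b = rot.apply(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_transform(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise InvalidTransformError("rotation must be a 3x3 matrix")
    if not np.allclose(rot.T @ rot, np.eye(3), atol=tol):
        raise InvalidTransformError("rotation is not orthonormal")
    if np.linalg.det(rot) < 0:
        raise InvalidTransformError("improper rotation (det < 0)")
    return rot


def expand_assembly(asym: MolecularStructure,
                    transforms: Sequence[tuple[np.ndarray, np.ndarray]],
                    ) -> MolecularStructure:
    """Build a full assembly by applying rigid transforms to an asymmetric unit.

    Each transform is a ``(rotation, translation)`` pair (3x3 matrix, nm
    3-vector).  Chain ids are disambiguated by transform index; chain
    annotations (position labels, tail ranges) are inherited by every copy.
    The canonical use is building a 420-chain T=7 shell from 60 symmetry
    copies of a 7-chain asymmetric subunit.
    """
    if asym.n_atoms == 0:
        raise EmptyStructureError("cannot expand an empty structure")
    if len(transforms) == 0:
        raise ValueError("need at least one transform")
    blocks, chain_blocks, anns = [], [], []
    for t_idx, (rot, trans) in enumerate(transforms):
        rot = _check_transform(rot)
        trans = np.asarray(trans, dtype=float).reshape(3)
        blocks.append(asym.positions @ rot.T + trans)
        suffix = "" if len(transforms) == 1 else f"_{t_idx}"
        chain_blocks.append(np.array([c + suffix for c in asym.chain_ids.astype(str)]))
        for ann in asym.chains:
            anns.append(replace(ann, chain_id=ann.chain_id + suffix))
    reps = len(transforms)
    return MolecularStructure(
        elements=np.tile(asym.elements, reps),
        atom_names=np.tile(asym.atom_names, reps),
        residue_indices=np.tile(asym.residue_indices, reps),
        residue_names=np.tile(asym.residue_names, reps),
        chain_ids=np.concatenate(chain_blocks),
        positions=np.vstack(blocks),
        chains=anns,
        source=asym.source + f" [assembly x{reps}]",
    )


def concatenate(parts: Iterable[MolecularStructure], source: str = "") -> MolecularStructure:
    """Concatenate structures with disjoint chain ids into one."""
    parts = list(parts)
    if not parts:
        raise EmptyStructureError("nothing to concatenate")
    return MolecularStructure(
        elements=np.concatenate([p.elements for p in parts]),
        atom_names=np.concatenate([p.atom_names for p in parts]),
        residue_indices=np.concatenate([p.residue_indices for p in parts]),
        residue_names=np.concatenate([p.residue_names for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        positions=np.vstack([p.positions for p in parts]),
        chains=[a for p in parts for a in p.chains],
        source=source or parts[0].source,
    )
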