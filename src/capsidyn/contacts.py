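"""Shadow contact maps for structure-based (Go-like) models.

A pair of atoms within a distance cutoff in the reference conformation is
a *native contact* unless a third atom occludes the line of sight between
them (the Shadow screening construction): atom ``k``, modelled as a
sphere, occludes the pair ``(i, j)`` if its centre lies within ``r_ij``
of atom ``i`` and the segment ``i -> j`` passes within the occluding
radius of ``k``'s centre.  Atoms directly bonded to ``i`` or ``j``
occlude with a shrunken radius so that covalent neighbours do not
screen genuine packing contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .connectivity import bonded_exclusions, infer_bonds, neighbor_table
from .structures import MolecularStructure

__all__ = ["ShadowParams", "ContactMap", "shadow_contact_map", "scale_contact_minima"]

#: occluding radius used for atoms covalently bonded to either endpoint, nm
BONDED_OCCLUDER_RADIUS = 0.05


@dataclass(frozen=True)
class ShadowParams:
    """Shadow-map parameters.

    contact_cutoff : nm, pair-inclusion distance (default 0.6)
    shadow_radius : nm, occluding-sphere radius (default 0.1)
    min_residue_separation : minimum intra-chain sequence separation
        (default 3; inter-chain pairs are never sequence-filtered)
    """

    contact_cutoff: float = 0.6
    shadow_radius: float = 0.1
    min_residue_separation: int = 3

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.shadow_radius < 0:
            raise ValueError("shadow_radius must be non-negative")
        if self.min_residue_separation < 1:
            raise ValueError("min_residue_separation must be >= 1")
        if self.contact_cutoff < self.shadow_radius:
            raise ValueError("contact_cutoff must be >= shadow_radius")


@dataclass
class ContactMap:
    """Native contact pairs with reference distances and scaled minima.

    ``sigma`` starts equal to ``r_native`` and is rescaled by
    :func:`scale_contact_minima`.
    """

    atom_i: np.ndarray
    atom_j: np.ndarray
    r_native: np.ndarray
    sigma: np.ndarray
    chain_i: np.ndarray
    chain_j: np.ndarray
    intermolecular: np.ndarray
    reference: str = ""
    params: ShadowParams | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_i)
        for name in ("atom_j", "r_native", "sigma", "chain_i", "chain_j",
                     "intermolecular"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.atom_i >= self.atom_j):
            raise ValueError("contact pairs must satisfy i < j")
        keys = self.atom_i.astype(np.int64) * (self.atom_j.max() + 1 if n else 1) \
            + self.atom_j.astype(np.int64)
        if n and len(np.unique(keys)) != n:
            raise ValueError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.atom_i)

    @property
    def n_contacts(self) -> int:
        return len(self)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.atom_i.tolist(), self.atom_j.tolist()))

    def subset(self, mask: np.ndarray) -> "ContactMap":
        return ContactMap(
            atom_i=self.atom_i[mask], atom_j=self.atom_j[mask],
            r_native=self.r_native[mask], sigma=self.sigma[mask],
            chain_i=self.chain_i[mask], chain_j=self.chain_j[mask],
            intermolecular=self.intermolecular[mask],
            reference=self.reference, params=self.params,
        )


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points ``p`` (m, 3) to the segment a->b."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(p))
    closest = a + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1)


def shadow_contact_map(structure: MolecularStructure,
                       params: ShadowParams | None = None,
                       bonds: np.ndarray | None = None) -> ContactMap:
    """Build the Shadow contact map of a reference conformation.

    Candidate pairs are all atom pairs within ``contact_cutoff``; a pair
    survives iff no third atom occludes it (see module docstring).
    Intra-chain pairs closer in sequence than ``min_residue_separation``
    and 1-2/1-3/1-4 bonded pairs are excluded.
    """
    params = params or ShadowParams()
    pos = structure.positions
    if len(pos) < 2:
        raise ValueError("need at least two atoms")
    bonds = infer_bonds(structure) if bonds is None else np.asarray(bonds)
    excl = bonded_exclusions(bonds, structure.n_atoms,
                             structure.residue_indices)
    nb = neighbor_table(bonds, structure.n_atoms)

    tree = cKDTree(pos)
    pairs = tree.query_pairs(params.contact_cutoff, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    keep_i, keep_j, keep_r = [], [], []
    chain_ids = structure.chain_ids
    res_idx = structure.residue_indices
    for i, j in pairs:
        i, j = int(i), int(j)
        if (i, j) in excl:
            continue
        same_chain = chain_ids[i] == chain_ids[j]
        if same_chain and abs(int(res_idx[i]) - int(res_idx[j])) < params.min_residue_separation:
            continue
        rij = float(np.linalg.norm(pos[j] - pos[i]))
        cand = tree.query_ball_point(pos[i], rij)
        cand = [k for k in cand if k != i and k != j]
        if cand:
            cand = np.asarray(cand)
            radii = np.where(
                [(k in nb[i]) or (k in nb[j]) for k in cand],
                BONDED_OCCLUDER_RADIUS, params.shadow_radius)
            dseg = _segment_distance(pos[cand], pos[i], pos[j])
            if np.any(dseg < radii):
                continue
        keep_i.append(i)
        keep_j.append(j)
        keep_r.append(rij)

    ai = np.asarray(keep_i, dtype=np.int64)
    aj = np.asarray(keep_j, dtype=np.int64)
    r = np.asarray(keep_r, dtype=float)
    ci = chain_ids[ai] if len(ai) else np.empty(0, dtype=chain_ids.dtype)
    cj = chain_ids[aj] if len(aj) else np.empty(0, dtype=chain_ids.dtype)
    return ContactMap(
        atom_i=ai, atom_j=aj, r_native=r, sigma=r.copy(),
        chain_i=ci, chain_j=cj, intermolecular=(ci != cj),
        reference=structure.source, params=params,
    )


def scale_contact_minima(cmap: ContactMap, scale_factor: float = 0.95) -> ContactMap:
    """Rescale every contact minimum: ``sigma *= scale_factor``.

    The reference distances ``r_native`` are untouched (they still define
    the contact-formation criterion); repeated application composes
    multiplicatively.  The default 0.95 slightly compresses the native
    basin so that the free-energy minimum in the radius of gyration
    coincides with the mature reference rather than overshooting it.
    """
    if not 0 < scale_factor <= 1:
        raise ValueError("scale_factor must be in (0, 1]")
    return replace(cmap, sigma=cmap.sigma * scale_factor,
                   r_native=cmap.r_native.copy())
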