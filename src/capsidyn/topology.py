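"""Single-basin structure-based force-field topologies.

The potential is defined entirely from one reference ("native")
conformation, making that conformation the energy minimum:

* harmonic bonds/angles with ff03-valued equilibria (reference-geometry
  fallback, logged),
* rigid dihedrals ``k (1 - cos 2 phi)`` (minima at 0 and 180 deg),
* flexible dihedrals ``k [(1 - cos d) + (1/2)(1 - cos 3d)]`` with
  ``d = phi - phi_native``,
* native contacts (Shadow map) as 6-12 Lennard-Jones wells of depth
  ``epsilon`` with minimum at ``sigma = scale x r_native`` (Gaussian-well
  form available as an option),
* an ``r^-12`` excluded-volume repulsion between all remaining
  non-excluded pairs -- the steric term the model is built to probe.

All energies are in reduced units (``epsilon = 1`` per contact).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .connectivity import bonded_exclusions, infer_bonds, neighbor_table
from .contacts import ContactMap, ShadowParams, scale_contact_minima, shadow_contact_map
from .dihedrals import DihedralTerm, classify_dihedrals
from .params import ParameterLookupError, ParameterTable
from .structures import MolecularStructure

__all__ = ["ForceFieldTopology", "EnergyBreakdown", "build_topology",
           "potential_energy"]

logger = logging.getLogger(__name__)

# default stiffnesses, reduced units
BOND_K = 2000.0          # eps / nm^2
ANGLE_K = 40.0           # eps / rad^2
RIGID_DIHEDRAL_K = 10.0  # eps
EV_RADIUS = 0.25         # nm
EV_STRENGTH = 1.0        # eps
EV_CUTOFF = 0.6          # nm (energy-shifted truncation)
CONTACT_DIHEDRAL_RATIO = 2.0   # total contact energy : total flexible-dihedral energy


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    contact: float
    excluded_volume: float

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.contact
                + self.excluded_volume)


@dataclass
class ForceFieldTopology:
    """A complete structure-based topology (see module docstring)."""

    n_atoms: int
    bonds: np.ndarray            # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray           # (na, 3) int
    theta0: np.ndarray
    angle_k: np.ndarray
    dihedrals: np.ndarray        # (nd, 4) int
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray
    dihedral_rigid: np.ndarray   # bool
    contacts: ContactMap
    exclusions: set = field(default_factory=set)  # (i, j) pairs, i < j
    epsilon: float = 1.0
    contact_form: str = "lj612"  # or "gaussian"
    gaussian_width: float = 0.05
    ev_radius: float = EV_RADIUS
    ev_strength: float = EV_STRENGTH
    ev_cutoff: float = EV_CUTOFF
    masses: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.ones(self.n_atoms)
        if self.contact_form not in ("lj612", "gaussian"):
            raise ValueError(f"unknown contact form {self.contact_form!r}")

    @property
    def dihedral_terms(self) -> list[DihedralTerm]:
        return [DihedralTerm(tuple(int(x) for x in a),
                             "rigid" if r else "flexible", float(p), float(k))
                for a, p, k, r in zip(self.dihedrals, self.dihedral_phi0,
                                      self.dihedral_k, self.dihedral_rigid)]

    # -- packed arrays for the integrator kernels ---------------------
    def nonbonded_exclusion_keys(self) -> np.ndarray:
        """Sorted int64 keys (i * n + j) of pairs excluded from excluded-volume:
        bonded 1-2/1-3/1-4 pairs plus native-contact pairs."""
        n = self.n_atoms
        keys = {i * n + j for i, j in self.exclusions}
        keys.update(int(i) * n + int(j)
                    for i, j in zip(self.contacts.atom_i, self.contacts.atom_j))
        return np.array(sorted(keys), dtype=np.int64)

    def forces(self, positions: np.ndarray) -> np.ndarray:
        """Forces (n, 3) at the given positions, via the compiled kernels."""
        from .kernels import evaluate_forces

        f, _ = evaluate_forces(self, np.asarray(positions, dtype=float))
        return f

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        """Native JSON serialization (schema: top-level keys mirror fields;
        index arrays as nested lists; contact map under ``contacts``)."""
        payload = {
            "n_atoms": self.n_atoms,
            "epsilon": self.epsilon,
            "contact_form": self.contact_form,
            "gaussian_width": self.gaussian_width,
            "ev_radius": self.ev_radius,
            "ev_strength": self.ev_strength,
            "ev_cutoff": self.ev_cutoff,
            "bonds": self.bonds.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "bond_k": self.bond_k.tolist(),
            "angles": self.angles.tolist(),
            "theta0": self.theta0.tolist(),
            "angle_k": self.angle_k.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "dihedral_phi0": self.dihedral_phi0.tolist(),
            "dihedral_k": self.dihedral_k.tolist(),
            "dihedral_rigid": self.dihedral_rigid.astype(int).tolist(),
            "exclusions": sorted([int(i), int(j)] for i, j in self.exclusions),
            "contacts": {
                "atom_i": self.contacts.atom_i.tolist(),
                "atom_j": self.contacts.atom_j.tolist(),
                "r_native": self.contacts.r_native.tolist(),
                "sigma": self.contacts.sigma.tolist(),
                "chain_i": self.contacts.chain_i.astype(str).tolist(),
                "chain_j": self.contacts.chain_j.astype(str).tolist(),
                "reference": self.contacts.reference,
            },
            "notes": list(self.notes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ForceFieldTopology":
        with open(path) as fh:
            d = json.load(fh)
        ci = np.array(d["contacts"]["chain_i"], dtype=str)
        cj = np.array(d["contacts"]["chain_j"], dtype=str)
        cmap = ContactMap(
            atom_i=np.array(d["contacts"]["atom_i"], dtype=np.int64),
            atom_j=np.array(d["contacts"]["atom_j"], dtype=np.int64),
            r_native=np.array(d["contacts"]["r_native"], dtype=float),
            sigma=np.array(d["contacts"]["sigma"], dtype=float),
            chain_i=ci, chain_j=cj, intermolecular=(ci != cj),
            reference=d["contacts"].get("reference", ""),
        )
        return cls(
            n_atoms=d["n_atoms"],
            bonds=np.array(d["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_r0=np.array(d["bond_r0"], dtype=float),
            bond_k=np.array(d["bond_k"], dtype=float),
            angles=np.array(d["angles"], dtype=np.int64).reshape(-1, 3),
            theta0=np.array(d["theta0"], dtype=float),
            angle_k=np.array(d["angle_k"], dtype=float),
            dihedrals=np.array(d["dihedrals"], dtype=np.int64).reshape(-1, 4),
            dihedral_phi0=np.array(d["dihedral_phi0"], dtype=float),
            dihedral_k=np.array(d["dihedral_k"], dtype=float),
            dihedral_rigid=np.array(d["dihedral_rigid"], dtype=bool),
            contacts=cmap,
            exclusions={(int(i), int(j)) for i, j in d["exclusions"]},
            epsilon=d["epsilon"], contact_form=d["contact_form"],
            gaussian_width=d["gaussian_width"], ev_radius=d["ev_radius"],
            ev_strength=d["ev_strength"], ev_cutoff=d["ev_cutoff"],
            notes=list(d.get("notes", [])),
        )

    def write_gromacs_top(self, path) -> None:
        """Optional GROMACS-top-dialect export, for interoperability only.

        Units follow GROMACS conventions (nm, kJ/mol with epsilon = 1
        kJ/mol); functional-form type codes are listed in the header
        comment.  This writer is one-way; the JSON schema is the native
        serialization.
        """
        with open(path, "w") as fh:
            fh.write("; structure-based topology export\n"
                     "; bonds: func 1 (harmonic); angles: func 1 (harmonic)\n"
                     "; dihedrals: func 1, rigid = periodicity 2, flexible = "
                     "periodicity 1 + 3\n"
                     "; pairs: func 1, 6-12 with minimum at sigma (C6/C12 form)\n")
            fh.write("\n[ atoms ]\n;   nr  type  resnr  atom  cgnr  charge  mass\n")
            for i in range(self.n_atoms):
                fh.write(f"{i + 1:6d}  X  1  X  1  0.0  {self.masses[i]:.3f}\n")
            fh.write("\n[ bonds ]\n;  ai  aj  func  r0  k\n")
            for (a, b), r0, k in zip(self.bonds, self.bond_r0, self.bond_k):
                fh.write(f"{a + 1:6d} {b + 1:6d}  1  {r0:.6f}  {2 * k:.3f}\n")
            fh.write("\n[ angles ]\n;  ai  aj  ak  func  theta0(deg)  k\n")
            for (a, b, c), t0, k in zip(self.angles, self.theta0, self.angle_k):
                fh.write(f"{a + 1:6d} {b + 1:6d} {c + 1:6d}  1  "
                         f"{np.degrees(t0):.4f}  {k:.3f}\n")
            fh.write("\n[ dihedrals ]\n;  ai  aj  ak  al  func  phi0(deg)  k  mult\n")
            for (a, b, c, d), p0, k, rig in zip(self.dihedrals, self.dihedral_phi0,
                                                self.dihedral_k, self.dihedral_rigid):
                if rig:
                    fh.write(f"{a + 1:6d} {b + 1:6d} {c + 1:6d} {d + 1:6d}  1  "
                             f"0.0  {k:.4f}  2\n")
                else:
                    fh.write(f"{a + 1:6d} {b + 1:6d} {c + 1:6d} {d + 1:6d}  1  "
                             f"{np.degrees(p0):.4f}  {k:.4f}  1\n")
                    fh.write(f"{a + 1:6d} {b + 1:6d} {c + 1:6d} {d + 1:6d}  1  "
                             f"{np.degrees(p0):.4f}  {0.5 * k:.4f}  3\n")
            fh.write("\n[ pairs ]\n;  ai  aj  func  C6  C12\n")
            for i, j, s in zip(self.contacts.atom_i, self.contacts.atom_j,
                               self.contacts.sigma):
                c6 = 2 * self.epsilon * s ** 6
                c12 = self.epsilon * s ** 12
                fh.write(f"{i + 1:6d} {j + 1:6d}  1  {c6:.8e}  {c12:.8e}\n")
            fh.write("\n[ exclusions ]\n")
            for i, j in sorted(self.exclusions):
                fh.write(f"{i + 1:6d} {j + 1:6d}\n")


def build_topology(reference: MolecularStructure,
                   shadow: ShadowParams | None = None,
                   scale_factor: float = 0.95,
                   param_table: ParameterTable | None = None,
                   bonds: np.ndarray | None = None,
                   allow_reference_fallback: bool = True,
                   contact_form: str = "lj612",
                   epsilon: float = 1.0,
                   bond_k: float = BOND_K,
                   angle_k: float = ANGLE_K,
                   rigid_dihedral_k: float = RIGID_DIHEDRAL_K,
                   contact_dihedral_ratio: float = CONTACT_DIHEDRAL_RATIO,
                   ev_radius: float = EV_RADIUS,
                   ev_strength: float = EV_STRENGTH,
                   contact_filter=None,
                   ) -> ForceFieldTopology:
    """Build the single-basin topology from an (expanded/mature) reference.

    Equilibrium bond lengths and angles come from the parameter table
    where available; otherwise the reference geometry is used and the
    fallback is logged (set ``allow_reference_fallback=False`` to make
    missing parameters an error).  Angles whose reference value is
    near-collinear are dropped (coarse pseudo-atom chains only).
    """
    shadow = shadow or ShadowParams()
    table = param_table or ParameterTable()
    pos = reference.positions
    bonds = infer_bonds(reference) if bonds is None else np.sort(
        np.asarray(bonds, dtype=np.int64), axis=1)
    n = reference.n_atoms
    nb = neighbor_table(bonds, n)

    fallback_bonds = fallback_angles = 0
    bond_r0 = np.empty(len(bonds))
    for idx, (a, b) in enumerate(bonds):
        a, b = int(a), int(b)
        ref_len = float(np.linalg.norm(pos[a] - pos[b]))
        same_res = (reference.chain_ids[a] == reference.chain_ids[b]
                    and reference.residue_indices[a] == reference.residue_indices[b])
        try:
            res = str(reference.residue_names[a])
            names = (str(reference.atom_names[a]), str(reference.atom_names[b]))
            if not same_res and {n_.upper() for n_ in names} != {"C", "N"}:
                raise ParameterLookupError("inter-residue non-peptide bond")
            bond_r0[idx] = table.bond_length(res, names)
        except KeyError:
            if not allow_reference_fallback:
                raise
            bond_r0[idx] = ref_len
            fallback_bonds += 1

    # angles: every bonded triple a-b-c along the backbone/side chains;
    # long-range bracing bonds (residue separation > 1, as in coarse
    # shell models) carry no angle terms
    res_of = reference.residue_indices
    ang_list, theta0_list = [], []
    for b in range(n):
        neigh = sorted(nb[b])
        for x in range(len(neigh)):
            for y in range(x + 1, len(neigh)):
                a, c = neigh[x], neigh[y]
                if (abs(int(res_of[a]) - int(res_of[b])) > 1
                        or abs(int(res_of[c]) - int(res_of[b])) > 1):
                    continue
                u = pos[a] - pos[b]
                v = pos[c] - pos[b]
                cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
                theta_ref = float(np.arccos(np.clip(cosang, -1, 1)))
                if not (np.radians(10) < theta_ref < np.radians(170)):
                    continue      # torsionally/angularly degenerate; skip
                try:
                    res = str(reference.residue_names[b])
                    names = tuple(str(reference.atom_names[i]) for i in (a, b, c))
                    same_res = (
                        reference.chain_ids[a] == reference.chain_ids[b] == reference.chain_ids[c]
                        and reference.residue_indices[a] == reference.residue_indices[b]
                        == reference.residue_indices[c])
                    canonical = {n_.upper() for n_ in names} in (
                        {"CA", "C", "N"}, {"O", "C", "N"})
                    if not same_res and not canonical:
                        raise ParameterLookupError("non-canonical inter-residue angle")
                    theta = table.angle(res, names)
                except KeyError:
                    if not allow_reference_fallback:
                        raise
                    theta = theta_ref
                    fallback_angles += 1
                ang_list.append((a, b, c))
                theta0_list.append(theta)
    angles = (np.array(ang_list, dtype=np.int64) if ang_list
              else np.empty((0, 3), dtype=np.int64))

    dih_terms = classify_dihedrals(reference, bonds=bonds)
    if n >= 2:
        cmap = scale_contact_minima(
            shadow_contact_map(reference, shadow, bonds=bonds), scale_factor)
        if contact_filter is not None:
            # optional contact-map vetting (e.g. a generator declaring
            # certain structural elements as bare steric features with
            # no stabilizing role); the predicate keeps a pair when True
            keep = np.asarray(contact_filter(cmap.atom_i, cmap.atom_j,
                                             reference), dtype=bool)
            cmap = cmap.subset(keep)
    else:
        empty = np.empty(0, dtype=np.int64)
        cmap = ContactMap(atom_i=empty, atom_j=empty.copy(),
                          r_native=np.empty(0), sigma=np.empty(0),
                          chain_i=np.empty(0, dtype=str),
                          chain_j=np.empty(0, dtype=str),
                          intermolecular=np.empty(0, dtype=bool),
                          reference=reference.source)

    n_flex = sum(1 for t in dih_terms if t.kind == "flexible")
    flex_k = (epsilon * len(cmap) / (contact_dihedral_ratio * n_flex)
              if n_flex else 0.0)
    dihedrals = (np.array([t.atoms for t in dih_terms], dtype=np.int64)
                 if dih_terms else np.empty((0, 4), dtype=np.int64))
    dih_rigid = np.array([t.kind == "rigid" for t in dih_terms], dtype=bool)
    dih_k = np.where(dih_rigid, rigid_dihedral_k, flex_k)
    dih_phi0 = np.array([t.native_angle for t in dih_terms], dtype=float)

    notes = []
    if fallback_bonds or fallback_angles:
        msg = (f"reference-geometry fallback used for {fallback_bonds} bonds "
               f"and {fallback_angles} angles")
        logger.info(msg)
        notes.append(msg)

    return ForceFieldTopology(
        n_atoms=n,
        bonds=bonds, bond_r0=bond_r0, bond_k=np.full(len(bonds), bond_k),
        angles=angles, theta0=np.array(theta0_list, dtype=float),
        angle_k=np.full(len(angles), angle_k),
        dihedrals=dihedrals, dihedral_phi0=dih_phi0, dihedral_k=dih_k,
        dihedral_rigid=dih_rigid,
        contacts=cmap,
        exclusions=bonded_exclusions(bonds, n, reference.residue_indices),
        epsilon=epsilon, contact_form=contact_form,
        ev_radius=ev_radius, ev_strength=ev_strength,
        notes=notes,
    )


# ---------------------------------------------------------------------
# reference (pure-numpy) potential energy; the integrator kernels must
# agree with this path to 1e-10
# ---------------------------------------------------------------------

def potential_energy(topology: ForceFieldTopology,
                     positions: np.ndarray) -> EnergyBreakdown:
    """Evaluate the potential energy with per-term breakdown.

    This is the no-neighbour-list reference path: the excluded-volume sum
    runs over every non-excluded pair within the cutoff.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (topology.n_atoms, 3):
        raise ValueError(f"positions shape {pos.shape} does not match "
                         f"topology ({topology.n_atoms} atoms)")
    t = topology

    e_bond = 0.0
    if len(t.bonds):
        d = np.linalg.norm(pos[t.bonds[:, 0]] - pos[t.bonds[:, 1]], axis=1)
        e_bond = float(np.sum(0.5 * t.bond_k * (d - t.bond_r0) ** 2))

    e_angle = 0.0
    if len(t.angles):
        u = pos[t.angles[:, 0]] - pos[t.angles[:, 1]]
        v = pos[t.angles[:, 2]] - pos[t.angles[:, 1]]
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e_angle = float(np.sum(0.5 * t.angle_k * (theta - t.theta0) ** 2))

    e_dih = 0.0
    if len(t.dihedrals):
        p = pos[t.dihedrals]
        b1 = p[:, 1] - p[:, 0]
        b2 = p[:, 2] - p[:, 1]
        b3 = p[:, 3] - p[:, 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
        phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))
        rigid = t.dihedral_rigid
        e_rigid = np.sum(t.dihedral_k[rigid] * (1 - np.cos(2 * phi[rigid])))
        dphi = phi[~rigid] - t.dihedral_phi0[~rigid]
        e_flex = np.sum(t.dihedral_k[~rigid]
                        * ((1 - np.cos(dphi)) + 0.5 * (1 - np.cos(3 * dphi))))
        e_dih = float(e_rigid + e_flex)

    e_contact = 0.0
    if len(t.contacts):
        d = np.linalg.norm(pos[t.contacts.atom_i] - pos[t.contacts.atom_j], axis=1)
        sr = t.contacts.sigma / d
        if t.contact_form == "lj612":
            e_contact = float(np.sum(t.epsilon * (sr ** 12 - 2 * sr ** 6)))
        else:
            e_contact = float(np.sum(-t.epsilon * np.exp(
                -(d - t.contacts.sigma) ** 2 / (2 * t.gaussian_width ** 2))))

    e_ev = 0.0
    tree = cKDTree(pos)
    pairs = tree.query_pairs(t.ev_cutoff, output_type="ndarray")
    if len(pairs):
        n = t.n_atoms
        keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
        excl_keys = t.nonbonded_exclusion_keys()
        mask = ~np.isin(keys, excl_keys)
        pp = pairs[mask]
        if len(pp):
            d = np.linalg.norm(pos[pp[:, 0]] - pos[pp[:, 1]], axis=1)
            shift = (t.ev_radius / t.ev_cutoff) ** 12
            e_ev = float(np.sum(t.ev_strength * ((t.ev_radius / d) ** 12 - shift)))

    return EnergyBreakdown(bond=e_bond, angle=e_angle, dihedral=e_dih,
                           contact=e_contact, excluded_volume=e_ev)
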