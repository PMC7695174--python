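"""Synthetic miniature shells for desk-scale pipeline runs.

The generator emulates the statistical and steric structure of a
maturing phage shell without any real capsid geometry: a closed
quasi-uniform spherical mesh of pseudo-atoms (one bead per residue,
emitted through the standard structure types so every downstream module
runs unmodified), partitioned into chains by Voronoi patches around
chain centres.  Each chain owns one trans-shell cavity: a circular hole
punched in the mesh at the patch centre, rimmed by an explicit bead ring
whose radius -- the *cavity half-width* -- is the per-position-class
steric control parameter.  Terminal tails attach at the rim: interior
and compacted in the compact state, threaded through the hole and lying
along the outer surface towards a neighbouring patch in the expanded
reference (which gives every tail mature-specific intermolecular
contacts).

Two reference conformations are produced with a radius ratio matching
the ~25:28.5 nm compact:expanded relationship of the real system.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .structures import ChainAnnotation, MolecularStructure

__all__ = ["ToyShellSpec", "ToyShellPair", "InfeasibleShellError",
           "make_toy_shell", "make_unit_fixtures",
           "DEFAULT_CAVITY_WIDTHS", "ORDERED_CAVITY_WIDTHS"]

#: bead spacing along chains and the mesh, nm (CA-like virtual bond)
BEAD_SPACING = 0.38
#: spacing of beads along each cavity rim ring, nm
RING_SPACING = 0.35
#: height of the threaded tail (and its anchor ridge) above the outer
#: surface, nm.  Must exceed contact_cutoff + excluded-volume radius so
#: that no mature-specific contact can be "formed" from the shell
#: interior through the one-bead-thick toy wall.
TAIL_HEIGHT = 0.70
#: lateral offset of the tail path from the centre-to-centre geodesic,
#: nm.  The offset direction is antisymmetric between mutually-targeting
#: chains (lane convention), so head-on tail paths never collide and --
#: being 2 x 0.31 = 0.62 nm apart, just beyond the contact cutoff --
#: never share native contacts, keeping per-chain Q independent.
TAIL_LATERAL = 0.31
#: lateral offset between the tail path and the anchor ridge, nm
RIDGE_OFFSET = 0.33
#: clearance between the rim ring and the surrounding mesh, nm; small
#: enough that the ring-mesh annulus is sterically impassable, so the
#: only trans-shell route is the hole itself
HOLE_CLEARANCE = 0.24

#: default per-class cavity half-widths (nm), mirroring the observed
#: kinetic ordering E > D > C ~ F ~ G ~ B > A as a testable construction.
#: The range sits where the excluded-volume cost of a bead passing the
#: rim varies steeply with the half-width (~3 eps at 0.28 nm down to
#: ~0.01 eps at 0.50 nm), so rim sterics are rate-limiting.
DEFAULT_CAVITY_WIDTHS = {"A": 0.28, "B": 0.405, "C": 0.42, "D": 0.46,
                         "E": 0.50, "F": 0.415, "G": 0.41}
#: strictly ordered widths for rank-correlation experiments
ORDERED_CAVITY_WIDTHS = {"A": 0.28, "B": 0.34, "C": 0.38, "D": 0.41,
                         "E": 0.44, "F": 0.47, "G": 0.50}


class InfeasibleShellError(ValueError):
    """The requested geometry cannot be realized (e.g. tail longer than
    the cavity path, or cavity narrower than the excluded-volume size)."""


@dataclass(frozen=True)
class ToyShellSpec:
    """Generative parameters of the synthetic mini-capsid.

    residues_per_chain is a per-chain size target: the mesh density is
    derived from it, and actual per-chain counts vary by a few beads
    because Voronoi patches are not exactly equal.
    """

    n_position_classes: int = 7
    chains_per_class: int = 3
    residues_per_chain: int = 42
    tail_length: int = 4
    compact_radius: float = 2.24
    expanded_radius: float = 2.55
    cavity_half_widths: dict = field(default_factory=lambda: dict(DEFAULT_CAVITY_WIDTHS))
    kinked_classes: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expanded_radius <= self.compact_radius:
            raise ValueError("expanded_radius must exceed compact_radius")
        if not 1 <= self.tail_length < self.residues_per_chain:
            raise ValueError("need 1 <= tail_length < residues_per_chain")
        if self.n_position_classes < 1 or self.chains_per_class < 1:
            raise ValueError("need at least one class and one chain per class")
        if any(w <= 0 for w in self.cavity_half_widths.values()):
            raise ValueError("cavity widths must be positive")

    @property
    def labels(self) -> list[str]:
        return list(string.ascii_uppercase[:self.n_position_classes])

    @property
    def n_chains(self) -> int:
        return self.n_position_classes * self.chains_per_class

    def width(self, label: str) -> float:
        try:
            return float(self.cavity_half_widths[label])
        except KeyError:
            raise KeyError(f"no cavity width for class {label!r}") from None


@dataclass
class ToyShellPair:
    """Compact and expanded reference conformations of one toy shell."""

    compact: MolecularStructure
    expanded_reference: MolecularStructure
    annotations: list[ChainAnnotation]
    cavity_map: dict
    spec: ToyShellSpec

    @property
    def bonds(self) -> np.ndarray:
        return self.expanded_reference.bonds


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _tangent_frame(center: np.ndarray, towards: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent basis at a sphere point, t pointing towards a
    second direction."""
    t = towards - (towards @ center) * center
    t /= np.linalg.norm(t)
    b = np.cross(center, t)
    return t, b


def _surface_point(center: np.ndarray, direction: np.ndarray, arc: float,
                   radius: float, height: float = 0.0) -> np.ndarray:
    """Point at geodesic distance ``arc`` from ``center`` along a tangent
    ``direction``, lifted ``height`` above the sphere of ``radius``."""
    ang = arc / radius
    unit = np.cos(ang) * center + np.sin(ang) * direction
    return (radius + height) * unit


def make_toy_shell(spec: ToyShellSpec | None = None,
                   seed: int | None = None) -> ToyShellPair:
    """Generate a compact/expanded toy-shell pair (deterministic per seed)."""
    spec = spec or ToyShellSpec()
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    R = spec.expanded_radius
    ratio = spec.compact_radius / spec.expanded_radius
    labels = spec.labels
    widths = {lab: spec.width(lab) for lab in labels}

    if min(widths.values()) < 0.19:
        raise InfeasibleShellError(
            "cavity half-width below 0.19 nm: narrower than the excluded-"
            "volume size, no tail can pass")

    centers = _fibonacci_sphere(spec.n_chains)
    # balanced, seed-shuffled label assignment: position classes are not
    # tied to fixed sites on the sphere, so site-specific geometric
    # quirks average out across replicate shells
    chain_labels = [labels[i % len(labels)] for i in range(spec.n_chains)]
    chain_labels = [chain_labels[i] for i in rng.permutation(spec.n_chains)]

    # centre-to-centre geodesic separations
    cosm = np.clip(centers @ centers.T, -1, 1)
    np.fill_diagonal(cosm, -1)
    nearest = np.argsort(-cosm, axis=1)[:, :2]          # two nearest neighbours
    min_sep_arc = R * np.arccos(cosm.max(axis=1))

    tail_arc = (spec.tail_length - 1) * BEAD_SPACING
    if np.any(tail_arc >= 0.95 * min_sep_arc):
        raise InfeasibleShellError(
            f"tail ({tail_arc:.2f} nm) longer than the cavity path to the "
            "neighbouring patch: tail tip would fall into the neighbour's cavity")
    max_hole = max(widths.values()) + HOLE_CLEARANCE
    if max_hole >= 0.5 * min_sep_arc.min():
        raise InfeasibleShellError("cavity holes would merge with neighbouring patches")

    # mesh budget from the per-chain residue target
    body_target = spec.n_chains * (spec.residues_per_chain - spec.tail_length)
    ring_counts = {lab: max(6, int(round(2 * np.pi * widths[lab] / RING_SPACING)))
                   for lab in labels}
    total_rings = sum(ring_counts[chain_labels[c]] for c in range(spec.n_chains))
    hole_area = sum(np.pi * (widths[chain_labels[c]] + HOLE_CLEARANCE) ** 2
                    for c in range(spec.n_chains))
    sphere_area = 4 * np.pi * R ** 2
    n_mesh_target = body_target - total_rings
    n_generate = max(spec.n_chains * 4,
                     int(round(n_mesh_target / max(0.05, 1 - hole_area / sphere_area))))
    mesh_dirs = _fibonacci_sphere(n_generate)

    # punch cavity holes
    keep = np.ones(n_generate, dtype=bool)
    for c in range(spec.n_chains):
        ang = np.arccos(np.clip(mesh_dirs @ centers[c], -1, 1))
        keep &= R * ang > widths[chain_labels[c]] + HOLE_CLEARANCE
    mesh_dirs = mesh_dirs[keep]

    # fill coverage defects: a quasi-uniform spiral leaves occasional
    # spots where no wall bead is near enough to present a steric
    # barrier, which would give tails class-independent leak routes.
    # Add beads until every wall point (outside the cavities) has a mesh
    # bead within the coverage radius of a triangular lattice.
    from scipy.spatial import cKDTree

    coverage = 0.25
    probe = _fibonacci_sphere(8 * n_generate)
    outside_holes = np.ones(len(probe), dtype=bool)
    for c in range(spec.n_chains):
        ang = np.arccos(np.clip(probe @ centers[c], -1, 1))
        # inside the punched disc the rim rings provide the seal; from
        # the punch boundary outwards the filler repairs raggedness,
        # staying >= HOLE_CLEARANCE away from the rim ring beads
        outside_holes &= R * ang > widths[chain_labels[c]] + HOLE_CLEARANCE
    probe = probe[outside_holes]
    for _ in range(8):
        d, _idx = cKDTree(mesh_dirs * R).query(probe * R)
        bad = np.flatnonzero(d > coverage)
        if len(bad) == 0:
            break
        # greedily add the worst gap centres, skipping near-duplicates
        order = bad[np.argsort(-d[bad])]
        added: list[np.ndarray] = []
        for b in order:
            p = probe[b]
            if all(R * np.arccos(min(1.0, float(p @ q))) > 0.30 for q in added):
                added.append(p)
        mesh_dirs = np.vstack([mesh_dirs, np.array(added)])

    owner = np.argmax(mesh_dirs @ centers.T, axis=1)

    per_chain_ids = _chain_id_sequence(spec.n_chains)
    L = spec.tail_length

    # pass 1: local frames, native tail paths and the anchor ridges that
    # flank them.  Each chain's tail runs towards its nearest neighbour;
    # the ridge beads sit past the patch boundary and are owned by the
    # chain whose territory they fall in, which makes the tail's
    # mature-specific anchor contacts intermolecular.
    frames = []
    for c in range(spec.n_chains):
        t_hat, b_hat = _tangent_frame(centers[c], centers[nearest[c, 0]])
        frames.append((t_hat, b_hat))

    def path_point(c: int, arc: float, height: float, lateral: float,
                   direction=None) -> np.ndarray:
        t_hat, b_hat = frames[c]
        d = t_hat if direction is None else direction
        return (_surface_point(centers[c], d, arc, R, height)
                + lateral * b_hat)

    tails_exp = np.empty((spec.n_chains, L, 3))
    tails_cmp = np.empty((spec.n_chains, L, 3))
    # owner -> list of (bead positions, bonds local to that group)
    ridge_by_owner: dict[int, list[tuple[list[np.ndarray], list[tuple[int, int]]]]] = {
        c: [] for c in range(spec.n_chains)}
    for c in range(spec.n_chains):
        lab = chain_labels[c]
        kinked = lab in spec.kinked_classes
        t_hat, b_hat = frames[c]
        boundary_arc = 0.5 * R * np.arccos(
            np.clip(centers[c] @ centers[nearest[c, 0]], -1, 1))
        phase0 = rng.uniform(0.0, 2 * np.pi)

        def path_height(k: int) -> float:
            # a rising ladder near the hole keeps the native zipper
            # continuous (reachable reward at every threading step);
            # beads that could carry intermolecular contacts are held at
            # full height so they cannot be "formed" from the interior
            if k == 0:
                return 0.18
            if k * BEAD_SPACING >= boundary_arc - 0.2:
                return TAIL_HEIGHT
            return min(TAIL_HEIGHT, 0.35 + 0.20 * (k - 1))

        w_c = widths[lab]

        def path_arc(k: int) -> float:
            return k * BEAD_SPACING

        def tail_point(k: int) -> np.ndarray:
            return path_point(c, path_arc(k), path_height(k), TAIL_LATERAL)

        for k in range(L):            # k = 0 -> proximal bead (residue L)
            bead = L - k
            tails_exp[c, bead - 1] = tail_point(k)
            # compact: a loose helix hanging inward from the rim (seeded
            # phase and jitter give distinct replicas); residual clashes
            # between neighbouring interior tails are removed by a
            # deterministic relaxation pass afterwards
            inward = spec.compact_radius - 0.45 - 0.28 * k
            phase = 1.6 * k + phase0
            helix = (0.0 if k == 0 else 0.20) * (np.cos(phase) * t_hat
                                                 + np.sin(phase) * b_hat)
            tails_cmp[c, bead - 1] = (inward * centers[c] + helix
                                      + rng.normal(0.0, 0.01, 3))

        # anchor ridge: an elevated bead row flanking the whole tail
        # path.  The proximal section (this chain's patch) is a single
        # row owned by the chain itself -- an intramolecular zipper that
        # drives threading.  The distal section, past the patch
        # boundary, belongs to the target neighbour and is built as a
        # double-decker row plus a tip cap, so the fully-translocated
        # tail is held by several mature-specific intermolecular
        # contacts.
        if (L - 1) * BEAD_SPACING < boundary_arc + 0.10:
            raise InfeasibleShellError(
                "tail too short to reach past the patch boundary: no "
                "intermolecular anchor sites exist")

        def ridge_point(k: int, extra_height: float = 0.0) -> np.ndarray:
            p = path_point(c, path_arc(k), path_height(k),
                           TAIL_LATERAL + RIDGE_OFFSET)
            if extra_height:
                p = p * (1.0 + extra_height / np.linalg.norm(p))
            return p

        target = int(nearest[c, 0])
        proximal: list[np.ndarray] = []
        distal: list[np.ndarray] = []
        distal_bonds: list[tuple[int, int]] = []
        bottom_of: dict[int, int] = {}
        top_of: dict[int, int] = {}
        for k in range(1, L):
            if kinked and k == L - 2:
                continue      # the collar replaces this anchor station
            if k * BEAD_SPACING < boundary_arc - 0.2:
                proximal.append(ridge_point(k))
                continue
            bi = len(distal)
            distal.append(ridge_point(k))
            bottom_of[k] = bi
            if k - 1 in bottom_of:
                distal_bonds.append((bottom_of[k - 1], bi))
            ti = len(distal)
            distal.append(ridge_point(k, extra_height=BEAD_SPACING))
            top_of[k] = ti
            distal_bonds.append((bi, ti))
            if k - 1 in top_of:
                distal_bonds.append((top_of[k - 1], ti))
            if k - 1 in bottom_of:
                distal_bonds.append((bottom_of[k - 1], ti))   # diagonal brace
        # tip cap: terminal docking site straight ahead of the tail tip
        cap = path_point(c, L * BEAD_SPACING, TAIL_HEIGHT, TAIL_LATERAL)
        ci_local = len(distal)
        distal.append(cap)
        if L - 1 in bottom_of:
            distal_bonds.append((bottom_of[L - 1], ci_local))
            distal_bonds.append((top_of[L - 1], ci_local))
        if proximal:
            ridge_by_owner[c].append(
                (proximal, [(g, g + 1) for g in range(len(proximal) - 1)], False))
        ridge_by_owner[target].append((distal, distal_bonds, False))

        if kinked:
            # "kinked" cavity: a tight collar ring around the exit path,
            # between the distal anchor groups, that the tail must
            # thread mid-route.  It is a bare steric feature (all its
            # contacts are stripped), producing a long-lived
            # intermediate at partial Q.
            arc_c = (L - 2) * BEAD_SPACING
            ang_c = arc_c / R
            pc = path_point(c, arc_c, TAIL_HEIGHT, TAIL_LATERAL)
            t2 = -np.sin(ang_c) * centers[c] + np.cos(ang_c) * t_hat
            u = pc / np.linalg.norm(pc)
            u = u - (u @ t2) * t2
            u /= np.linalg.norm(u)
            v = np.cross(t2, u)
            collar = [pc + 0.26 * (np.cos(th) * u + np.sin(th) * v)
                      for th in 2 * np.pi * np.arange(6) / 6]
            collar_bonds = [(g, (g + 1) % 6) for g in range(6)]                 + [(g, (g + 2) % 6) for g in range(6)]
            ridge_by_owner[target].append((collar, collar_bonds, True))

    # pass 2: assemble chains (tail, rim ring, mesh patch, hosted ridges)
    elements, atom_names, res_idx, res_names, chain_ids = [], [], [], [], []
    pos_exp, pos_cmp = [], []
    bonds: list[tuple[int, int]] = []
    annotations: list[ChainAnnotation] = []
    cavity_map: dict = {}
    offset = 0
    for c in range(spec.n_chains):
        lab = chain_labels[c]
        cid = per_chain_ids[c]
        w = widths[lab]
        center = centers[c]
        t_hat, b_hat = frames[c]

        # the cavity rim: a closed, braced ring of beads at radius w in
        # the wall plane; the tail's proximal residue attaches to the
        # first rim bead through the serial backbone
        m = ring_counts[lab]
        ring_exp = np.empty((m, 3))
        for r_i in range(m):
            th = 2 * np.pi * r_i / m
            d_hat = np.cos(th) * t_hat + np.sin(th) * b_hat
            ring_exp[r_i] = _surface_point(center, d_hat, w, R, 0.0)
        m_ring_total = len(ring_exp)

        # mesh patch, serialized band-by-band for sane bonded terms
        patch = mesh_dirs[owner == c]
        if len(patch) == 0:
            raise InfeasibleShellError(
                f"chain {cid}: no mesh beads in patch (shell too small)")
        arcs = R * np.arccos(np.clip(patch @ center, -1, 1))
        azim = np.arctan2(patch @ b_hat, patch @ t_hat)
        band = np.round((arcs - w) / BEAD_SPACING).astype(int)
        order = np.lexsort((azim, band))
        patch_exp = R * patch[order]

        parts = [tails_exp[c], ring_exp, patch_exp]
        n_body = L + m_ring_total + len(patch_exp)
        # consecutive-residue backbone through tail, base, rings, mesh
        bonds.extend((offset + i, offset + i + 1) for i in range(n_body - 1))

        def ring_at(r_i: int) -> int:
            return offset + L + r_i % m

        mesh_start = offset + L + m_ring_total
        for r_i in range(m):
            # close the ring, brace second neighbours, and tie every
            # rim bead to its two nearest mesh beads so the aperture
            # width is a stiff per-class constant
            bonds.append((ring_at(r_i), ring_at(r_i + 1)))
            bonds.append((ring_at(r_i), ring_at(r_i + 2)))
            d2 = np.sum((patch_exp - ring_exp[r_i]) ** 2, axis=1)
            for support in np.argsort(d2)[:2]:
                bonds.append((ring_at(r_i), mesh_start + int(support)))

        # hosted anchor ridges: internal bracing as specified by the
        # group, and every low bead tripod-bonded to its three nearest
        # ring/mesh beads so the elevated rows are trilaterated to the
        # wall
        body_exp = np.vstack([ring_exp, patch_exp])
        ridge_pos = []
        bare_residues: list[int] = []
        r_off = n_body
        for group_pos, group_bonds, bare in ridge_by_owner[c]:
            g_off = offset + r_off + len(ridge_pos)
            for p in group_pos:
                idx = offset + r_off + len(ridge_pos)
                height = np.linalg.norm(p) - R
                if height < 0.95:
                    d2 = np.sum((body_exp - p) ** 2, axis=1)
                    for support in np.argsort(d2)[:3]:
                        bonds.append((offset + L + int(support), idx))
                if bare:
                    bare_residues.append(r_off + len(ridge_pos) + 1)
                ridge_pos.append(p)
            bonds.extend((g_off + a, g_off + b) for a, b in group_bonds)
        if ridge_pos:
            parts.append(np.array(ridge_pos))

        chain_pos_exp = np.vstack(parts)
        chain_pos_cmp = chain_pos_exp * ratio
        chain_pos_cmp[:L] = tails_cmp[c]
        n_res = len(chain_pos_exp)

        elements.append(np.full(n_res, "C"))
        atom_names.append(np.full(n_res, "CA"))
        res_idx.append(np.arange(1, n_res + 1))
        res_names.append(np.full(n_res, "GLY"))
        chain_ids.append(np.full(n_res, cid))
        pos_exp.append(chain_pos_exp)
        pos_cmp.append(chain_pos_cmp)
        offset += n_res
        annotations.append(ChainAnnotation(chain_id=cid, position_label=lab,
                                           tail_range=(1, L)))
        cavity_map[cid] = {"position_label": lab, "half_width": w,
                           "center_direction": center.tolist(),
                           "path_direction": t_hat.tolist(),
                           "kinked": bool(lab in spec.kinked_classes),
                           "throat_residues": (L + 1, L + m_ring_total),
                           "bare_residues": tuple(bare_residues)}

    bond_arr = np.unique(np.sort(np.array(bonds, dtype=np.int64), axis=1), axis=0)

    def build(pos_list, tag):
        return MolecularStructure(
            elements=np.concatenate(elements),
            atom_names=np.concatenate(atom_names),
            residue_indices=np.concatenate(res_idx),
            residue_names=np.concatenate(res_names),
            chain_ids=np.concatenate(chain_ids),
            positions=np.vstack(pos_list),
            chains=list(annotations),
            source=f"toy shell ({tag}, seed {seed})",
            bonds=bond_arr.copy(),
        )

    compact = build(pos_cmp, "compact")
    expanded = build(pos_exp, "expanded reference")
    tail_mask = compact.residue_indices <= L
    bond_r0 = np.linalg.norm(expanded.positions[bond_arr[:, 0]]
                             - expanded.positions[bond_arr[:, 1]], axis=1)
    compact.positions = _relax_interior_tails(
        compact.positions, tail_mask, bond_arr, bond_r0)
    pair = ToyShellPair(
        compact=compact,
        expanded_reference=expanded,
        annotations=annotations,
        cavity_map=cavity_map,
        spec=spec,
    )
    _sanity_check(pair)
    return pair


def _relax_interior_tails(positions: np.ndarray, movable_mask: np.ndarray,
                          bonds: np.ndarray, bond_r0: np.ndarray,
                          n_iter: int = 500, target_clearance: float = 0.30,
                          ) -> np.ndarray:
    """Deterministic steepest-descent declash of the interior tails.

    Moves only the masked (tail) beads, under the excluded-volume
    repulsion against everything plus their backbone bonds, until no
    non-bonded pair involving a tail is closer than the target
    clearance.  A pure function of its inputs.
    """
    from scipy.spatial import cKDTree

    pos = positions.copy()
    movable = movable_mask.astype(bool)
    bkeys = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in bonds}
    tail_bonds = [(int(a), int(b), r0) for (a, b), r0 in zip(bonds, bond_r0)
                  if movable[a] or movable[b]]
    for _ in range(n_iter):
        f = np.zeros_like(pos)
        tree = cKDTree(pos)
        pairs = tree.query_pairs(0.40, output_type="ndarray")
        worst = 1.0
        if len(pairs):
            sel = movable[pairs[:, 0]] | movable[pairs[:, 1]]
            pairs = pairs[sel]
        for i, j in pairs:
            i, j = int(i), int(j)
            if (i, j) in bkeys:
                continue
            d = pos[j] - pos[i]
            r = float(np.linalg.norm(d))
            worst = min(worst, r)
            if r < 1e-6:
                continue
            mag = min(30.0, 12.0 * (0.25 / r) ** 12 / r)
            f[i] -= mag * d / r
            f[j] += mag * d / r
        if worst >= target_clearance:
            break
        for a, b, r0 in tail_bonds:
            d = pos[b] - pos[a]
            r = float(np.linalg.norm(d))
            pull = 50.0 * (r - r0)
            f[a] += pull * d / r
            f[b] -= pull * d / r
        step = np.clip(0.004 * f[movable], -0.02, 0.02)
        pos[movable] += step
    return pos


def throat_contact_filter(pair: ToyShellPair):
    """Keep-predicate for :func:`capsidyn.topology.build_topology`.

    The throat (base bead and rim rings) is a bare steric gate: it
    contributes excluded volume only, never stabilization of the
    threaded tail.  This predicate drops same-chain contacts between
    tail residues and throat residues, so cavity passage cost is set
    purely by the rim geometry.
    """
    L = pair.spec.tail_length
    throat_hi = {ann.chain_id: pair.cavity_map[ann.chain_id]["throat_residues"][1]
                 for ann in pair.annotations}
    bare = {ann.chain_id: set(pair.cavity_map[ann.chain_id].get("bare_residues", ()))
            for ann in pair.annotations}

    def keep(atom_i, atom_j, structure):
        res = structure.residue_indices
        ch = structure.chain_ids.astype(str)
        hi = np.array([throat_hi[c] for c in ch])
        is_tail = res <= L
        is_throat = (res > L) & (res <= hi)
        is_bare = np.array([int(r) in bare[c] for c, r in zip(ch, res)])
        same = ch[atom_i] == ch[atom_j]
        drop = same & ((is_tail[atom_i] & is_throat[atom_j])
                       | (is_throat[atom_i] & is_tail[atom_j]))
        drop |= is_bare[atom_i] | is_bare[atom_j]
        return ~drop

    return keep


def _chain_id_sequence(n: int) -> list[str]:
    pool = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n <= len(pool):
        return [pool[i] for i in range(n)]
    return [f"c{i:03d}" for i in range(n)]


def _sanity_check(pair: ToyShellPair) -> None:
    from .structures import radius_of_gyration

    rg_c = radius_of_gyration(pair.compact)
    rg_e = radius_of_gyration(pair.expanded_reference)
    if rg_e <= rg_c:
        raise InfeasibleShellError("expanded Rg does not exceed compact Rg")
    # steric sanity: no severe clash in the expanded reference
    from scipy.spatial import cKDTree

    tree = cKDTree(pair.expanded_reference.positions)
    close = tree.query_pairs(0.12)
    if close:
        raise InfeasibleShellError(
            f"expanded reference has {len(close)} atom pairs closer than "
            "0.12 nm (tail paths collide); adjust spec")


# ---------------------------------------------------------------------
# small deterministic unit fixtures
# ---------------------------------------------------------------------

def _nerf(a, b, c, bond, angle, dihedral):
    """Place a fourth point from internal coordinates (angles in radians)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(dihedral),
                  bond * np.sin(angle) * np.sin(dihedral)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_unit_fixtures() -> dict:
    """Deterministic small systems with hand-computable properties.

    Returns a dict with:

    * ``harmonic_dimer`` -- two bonded beads 0.38 nm apart;
    * ``random_cloud`` -- 30 atoms uniform in a 1.5 nm box (fixed seed),
      residue indices spaced so no pair is sequence-filtered;
    * ``dipeptide`` -- an alanine dipeptide analog (two ALA residues,
      heavy atoms, ideal internal coordinates) for dihedral
      classification: its peptide omega bond is the only rigid dihedral.
    """
    dimer = MolecularStructure(
        elements=np.array(["C", "C"]),
        atom_names=np.array(["CA", "CA"]),
        residue_indices=np.array([1, 2]),
        residue_names=np.array(["GLY", "GLY"]),
        chain_ids=np.array(["A", "A"]),
        positions=np.array([[0.0, 0.0, 0.0], [BEAD_SPACING, 0.0, 0.0]]),
        chains=[ChainAnnotation("A", "A", (1, 1))],
        bonds=np.array([[0, 1]]),
        source="harmonic dimer fixture",
    )

    rng = np.random.default_rng(2024)
    n_cloud = 30
    cloud = MolecularStructure(
        elements=np.full(n_cloud, "C"),
        atom_names=np.full(n_cloud, "CA"),
        residue_indices=np.arange(n_cloud) * 5 + 1,
        residue_names=np.full(n_cloud, "GLY"),
        chain_ids=np.full(n_cloud, "A"),
        positions=rng.uniform(0, 1.5, (n_cloud, 3)),
        chains=[ChainAnnotation("A", "A", (1, 1))],
        bonds=np.empty((0, 2), dtype=np.int64),
        source="random cloud fixture (seed 2024)",
    )

    deg = np.radians
    # residue 1: N CA C O CB ; residue 2: N CA C O CB (heavy atoms)
    p = np.zeros((10, 3))
    p[0] = [0.0, 0.0, 0.0]                      # N1
    p[1] = [0.1449, 0.0, 0.0]                   # CA1
    p[2] = _nerf(p[0] + [0, 0.1, 0], p[0], p[1], 0.1522, deg(110.1), deg(180))  # C1
    p[3] = _nerf(p[0], p[1], p[2], 0.1229, deg(120.4), deg(-30.0))  # O1
    p[4] = _nerf(p[2], p[0], p[1], 0.1526, deg(110.5), deg(-122.0))  # CB1
    p[5] = _nerf(p[0], p[1], p[2], 0.1335, deg(116.6), deg(150.0))  # N2 (psi)
    p[6] = _nerf(p[1], p[2], p[5], 0.1449, deg(121.9), deg(175.0))  # CA2 (omega)
    p[7] = _nerf(p[2], p[5], p[6], 0.1522, deg(110.1), deg(-60.0))  # C2 (phi)
    p[8] = _nerf(p[5], p[6], p[7], 0.1229, deg(120.4), deg(45.0))   # O2
    p[9] = _nerf(p[2], p[5], p[6], 0.1526, deg(110.5), deg(62.0))   # CB2
    dipeptide = MolecularStructure(
        elements=np.array(["N", "C", "C", "O", "C", "N", "C", "C", "O", "C"]),
        atom_names=np.array(["N", "CA", "C", "O", "CB",
                             "N", "CA", "C", "O", "CB"]),
        residue_indices=np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]),
        residue_names=np.full(10, "ALA"),
        chain_ids=np.full(10, "A"),
        positions=p,
        chains=[ChainAnnotation("A", "A", (1, 1))],
        source="alanine dipeptide analog fixture",
    )

    return {"harmonic_dimer": dimer, "random_cloud": cloud,
            "dipeptide": dipeptide}
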