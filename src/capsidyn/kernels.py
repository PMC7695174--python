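"""Compiled force and Langevin-integration kernels.

Single-threaded numba kernels: bit-reproducible given the seed.  The
force evaluation must agree with the pure-numpy reference path
(:func:`capsidyn.topology.potential_energy`) to 1e-10; the excluded
volume term uses a Verlet neighbour list with a skin, rebuilt whenever
any atom has moved more than half the skin since the last build.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_topology", "evaluate_forces", "run_langevin_loop"]

_SKIN = 0.25  # nm


def pack_topology(topology):
    """Flatten a ForceFieldTopology into the tuple the kernels take."""
    t = topology
    form = 0 if t.contact_form == "lj612" else 1
    return (
        np.ascontiguousarray(t.bonds, dtype=np.int64),
        np.ascontiguousarray(t.bond_r0, dtype=np.float64),
        np.ascontiguousarray(t.bond_k, dtype=np.float64),
        np.ascontiguousarray(t.angles, dtype=np.int64),
        np.ascontiguousarray(t.theta0, dtype=np.float64),
        np.ascontiguousarray(t.angle_k, dtype=np.float64),
        np.ascontiguousarray(t.dihedrals, dtype=np.int64),
        np.ascontiguousarray(t.dihedral_phi0, dtype=np.float64),
        np.ascontiguousarray(t.dihedral_k, dtype=np.float64),
        np.ascontiguousarray(t.dihedral_rigid.astype(np.uint8)),
        np.ascontiguousarray(t.contacts.atom_i, dtype=np.int64),
        np.ascontiguousarray(t.contacts.atom_j, dtype=np.int64),
        np.ascontiguousarray(t.contacts.sigma, dtype=np.float64),
        np.float64(t.epsilon),
        np.int64(form),
        np.float64(t.gaussian_width),
        np.float64(t.ev_radius),
        np.float64(t.ev_strength),
        np.float64(t.ev_cutoff),
        np.ascontiguousarray(t.nonbonded_exclusion_keys(), dtype=np.int64),
    )


@njit(inline="always")
def _is_excluded(i, j, n, excl_keys):
    key = i * n + j
    lo = 0
    hi = excl_keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if excl_keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl_keys.shape[0] and excl_keys[lo] == key


@njit(cache=True)
def _build_pairs_bruteforce(pos, cutoff, excl_keys):
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < cut2 and not _is_excluded(i, j, n, excl_keys):
                count += 1
    pairs = np.empty((count, 2), dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < cut2 and not _is_excluded(i, j, n, excl_keys):
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True)
def _build_pairs(pos, cutoff, excl_keys):
    """Cell-list pair search (deterministic traversal order), falling back
    to the brute-force scan when the bounding box is too large for a
    sensible grid.  Two passes (count, then fill) so no reallocation
    happens inside the hot loop."""
    n = pos.shape[0]
    xmin = np.empty(3)
    xmax = np.empty(3)
    for c in range(3):
        lo = pos[0, c]
        hi = pos[0, c]
        for i in range(1, n):
            v = pos[i, c]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        xmin[c] = lo
        xmax[c] = hi
    dims = np.empty(3, dtype=np.int64)
    for c in range(3):
        dims[c] = max(1, int((xmax[c] - xmin[c]) / cutoff))
    n_cells = dims[0] * dims[1] * dims[2]
    if n_cells > 8 * n + 1024:
        return _build_pairs_bruteforce(pos, cutoff, excl_keys)

    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(n_cells + 1, dtype=np.int64)
    for i in range(n):
        cx = min(dims[0] - 1, int((pos[i, 0] - xmin[0]) / cutoff))
        cy = min(dims[1] - 1, int((pos[i, 1] - xmin[1]) / cutoff))
        cz = min(dims[2] - 1, int((pos[i, 2] - xmin[2]) / cutoff))
        cell_of[i] = (cx * dims[1] + cy) * dims[2] + cz
        counts[cell_of[i] + 1] += 1
    for c in range(1, n_cells + 1):
        counts[c] += counts[c - 1]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order[fill[cell_of[i]]] = i
        fill[cell_of[i]] += 1

    cut2 = cutoff * cutoff
    total = 0
    pairs = np.empty((0, 2), dtype=np.int64)
    for phase in range(2):
        if phase == 1:
            pairs = np.empty((total, 2), dtype=np.int64)
        k = 0
        for i in range(n):
            ci = cell_of[i]
            cz = ci % dims[2]
            cy = (ci // dims[2]) % dims[1]
            cx = ci // (dims[1] * dims[2])
            for ox in range(-1, 2):
                nx = cx + ox
                if nx < 0 or nx >= dims[0]:
                    continue
                for oy in range(-1, 2):
                    ny = cy + oy
                    if ny < 0 or ny >= dims[1]:
                        continue
                    for oz in range(-1, 2):
                        nz = cz + oz
                        if nz < 0 or nz >= dims[2]:
                            continue
                        cc = (nx * dims[1] + ny) * dims[2] + nz
                        for s in range(counts[cc], counts[cc + 1]):
                            j = order[s]
                            if j <= i:
                                continue
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            if dx * dx + dy * dy + dz * dz < cut2 \
                                    and not _is_excluded(i, j, n, excl_keys):
                                if phase == 1:
                                    pairs[k, 0] = i
                                    pairs[k, 1] = j
                                k += 1
        if phase == 0:
            total = k
    return pairs


@njit(cache=True)
def _forces(pos, f,
            bonds, bond_r0, bond_k,
            angles, theta0, angle_k,
            dih, dih_phi0, dih_k, dih_rigid,
            con_i, con_j, con_sigma, eps, con_form, gauss_w,
            ev_radius, ev_strength, ev_cutoff,
            nl_pairs,
            rest_idx, rest_ref, rest_k):
    f[:] = 0.0
    e_bond = e_angle = e_dih = e_con = e_ev = e_rest = 0.0

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += 0.5 * bond_k[b] * dr * dr
        fac = -bond_k[b] * dr / r
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    for a in range(angles.shape[0]):
        ia = angles[a, 0]
        ib = angles[a, 1]
        ic = angles[a, 2]
        ux = pos[ia, 0] - pos[ib, 0]
        uy = pos[ia, 1] - pos[ib, 1]
        uz = pos[ia, 2] - pos[ib, 2]
        vx = pos[ic, 0] - pos[ib, 0]
        vy = pos[ic, 1] - pos[ib, 1]
        vz = pos[ic, 2] - pos[ib, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosang = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosang > 1.0:
            cosang = 1.0
        elif cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        sinang = np.sqrt(1.0 - cosang * cosang)
        if sinang < 1e-8:
            sinang = 1e-8
        dth = theta - theta0[a]
        e_angle += 0.5 * angle_k[a] * dth * dth
        coef = -angle_k[a] * dth / sinang
        # F_i = coef * (cos*u_hat - v_hat)/|u|, F_k analogous
        fix = coef * (cosang * ux / nu - vx / nv) / nu
        fiy = coef * (cosang * uy / nu - vy / nv) / nu
        fiz = coef * (cosang * uz / nu - vz / nv) / nu
        fkx = coef * (cosang * vx / nv - ux / nu) / nv
        fky = coef * (cosang * vy / nv - uy / nu) / nv
        fkz = coef * (cosang * vz / nv - uz / nu) / nv
        f[ia, 0] += fix
        f[ia, 1] += fiy
        f[ia, 2] += fiz
        f[ic, 0] += fkx
        f[ic, 1] += fky
        f[ic, 2] += fkz
        f[ib, 0] -= fix + fkx
        f[ib, 1] -= fiy + fky
        f[ib, 2] -= fiz + fkz

    for d in range(dih.shape[0]):
        i = dih[d, 0]
        j = dih[d, 1]
        k = dih[d, 2]
        l = dih[d, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # m = n1 x b2_hat ; phi = atan2(m . n2, n1 . n2)  (IUPAC convention,
        # identical to dihedrals.dihedral_angle)
        mx = (n1y * b2z - n1z * b2y) / nb2
        my = (n1z * b2x - n1x * b2z) / nb2
        mz = (n1x * b2y - n1y * b2x) / nb2
        y = mx * n2x + my * n2y + mz * n2z
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        if dih_rigid[d] == 1:
            e_dih += dih_k[d] * (1.0 - np.cos(2.0 * phi))
            dU = 2.0 * dih_k[d] * np.sin(2.0 * phi)
        else:
            dphi = phi - dih_phi0[d]
            e_dih += dih_k[d] * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
            dU = dih_k[d] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        # near-collinear internal angles make the torsion force singular;
        # drop the force (not the energy) when sin^2 of either angle < 1e-3
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        if (n1sq < 1e-3 * b1sq * nb2 * nb2
                or n2sq < 1e-3 * b3sq * nb2 * nb2):
            continue
        # dphi/dr_i = |b2|/|n1|^2 n1 ; dphi/dr_l = -|b2|/|n2|^2 n2
        c1 = -dU * nb2 / n1sq
        c4 = dU * nb2 / n2sq
        f1x = c1 * n1x
        f1y = c1 * n1y
        f1z = c1 * n1z
        f4x = c4 * n2x
        f4y = c4 * n2y
        f4z = c4 * n2z
        tb = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        sb = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        f[i, 0] += f1x
        f[i, 1] += f1y
        f[i, 2] += f1z
        f[l, 0] += f4x
        f[l, 1] += f4y
        f[l, 2] += f4z
        f[j, 0] += -(1.0 + tb) * f1x + sb * f4x
        f[j, 1] += -(1.0 + tb) * f1y + sb * f4y
        f[j, 2] += -(1.0 + tb) * f1z + sb * f4z
        f[k, 0] += tb * f1x - (1.0 + sb) * f4x
        f[k, 1] += tb * f1y - (1.0 + sb) * f4y
        f[k, 2] += tb * f1z - (1.0 + sb) * f4z

    for c in range(con_i.shape[0]):
        i = con_i[c]
        j = con_j[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s = con_sigma[c]
        if con_form == 0:
            sr2 = s * s / r2
            sr6 = sr2 * sr2 * sr2
            e_con += eps * (sr6 * sr6 - 2.0 * sr6)
            fac = eps * 12.0 * (sr6 * sr6 - sr6) / r2
        else:
            r = np.sqrt(r2)
            ex = np.exp(-(r - s) * (r - s) / (2.0 * gauss_w * gauss_w))
            e_con += -eps * ex
            fac = -eps * (r - s) / (gauss_w * gauss_w) * ex / r
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    shift = (ev_radius / ev_cutoff) ** 12
    cut2 = ev_cutoff * ev_cutoff
    ev_r2 = ev_radius * ev_radius
    for p in range(nl_pairs.shape[0]):
        i = nl_pairs[p, 0]
        j = nl_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        a2 = ev_r2 / r2
        a12 = a2 * a2 * a2
        a12 = a12 * a12
        e_ev += ev_strength * (a12 - shift)
        fac = 12.0 * ev_strength * a12 / r2
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    for rix in range(rest_idx.shape[0]):
        i = rest_idx[rix]
        dx = pos[i, 0] - rest_ref[rix, 0]
        dy = pos[i, 1] - rest_ref[rix, 1]
        dz = pos[i, 2] - rest_ref[rix, 2]
        e_rest += 0.5 * rest_k * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= rest_k * dx
        f[i, 1] -= rest_k * dy
        f[i, 2] -= rest_k * dz

    return e_bond, e_angle, e_dih, e_con, e_ev, e_rest


_NO_RESTRAINT = (np.empty(0, dtype=np.int64), np.empty((0, 3)), 0.0)


def evaluate_forces(topology, positions, restraints=None, neighbor_list=True):
    """Forces and per-term energies at one configuration.

    With ``neighbor_list=False`` (default is a full-cutoff list anyway
    for a single evaluation) the excluded-volume sum is exact; this is
    the path used to validate the integrator against the numpy
    reference.
    """
    packed = pack_topology(topology)
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    excl = packed[-1]
    pairs = _build_pairs(pos, packed[-2], excl)   # exact: cutoff with no skin
    f = np.zeros_like(pos)
    rest_idx, rest_ref, rest_k = _NO_RESTRAINT
    if restraints is not None:
        rest_idx, rest_ref, rest_k = restraints
    energies = _forces(pos, f, *packed[:-1], pairs, rest_idx,
                       np.ascontiguousarray(rest_ref, dtype=np.float64),
                       np.float64(rest_k))
    return f, energies


@njit(cache=True)
def run_langevin_loop(pos, vel, masses, dt, gamma, temperature,
                      n_steps, save_interval, seed,
                      bonds, bond_r0, bond_k,
                      angles, theta0, angle_k,
                      dih, dih_phi0, dih_k, dih_rigid,
                      con_i, con_j, con_sigma, eps, con_form, gauss_w,
                      ev_radius, ev_strength, ev_cutoff, excl_keys,
                      rest_idx, rest_ref, rest_k, skin):
    """BAOAB Langevin integration; returns saved frames and diagnostics.

    Returns (saved_pos, saved_vel, saved_times, saved_pe, saved_ke,
    blowup_step) where blowup_step is -1 on success.
    """
    n = pos.shape[0]
    np.random.seed(seed)
    f = np.zeros_like(pos)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature)
    n_saves = n_steps // save_interval + 1 if save_interval > 0 else 1
    saved_pos = np.empty((n_saves, n, 3))
    saved_vel = np.empty((n_saves, n, 3))
    saved_times = np.empty(n_saves)
    saved_pe = np.empty(n_saves)
    saved_ke = np.empty(n_saves)

    list_cutoff = ev_cutoff + skin
    pairs = _build_pairs(pos, list_cutoff, excl_keys)
    pos_at_build = pos.copy()

    e = _forces(pos, f, bonds, bond_r0, bond_k, angles, theta0, angle_k,
                dih, dih_phi0, dih_k, dih_rigid,
                con_i, con_j, con_sigma, eps, con_form, gauss_w,
                ev_radius, ev_strength, ev_cutoff, pairs,
                rest_idx, rest_ref, rest_k)

    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    saved_pos[0] = pos
    saved_vel[0] = vel
    saved_times[0] = 0.0
    saved_pe[0] = e[0] + e[1] + e[2] + e[3] + e[4] + e[5]
    saved_ke[0] = ke
    isave = 1

    half_skin2 = (0.5 * skin) ** 2
    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vel[i, 0] += inv_m * f[i, 0]
            vel[i, 1] += inv_m * f[i, 1]
            vel[i, 2] += inv_m * f[i, 2]
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O
        if gamma > 0.0:
            for i in range(n):
                pref = c2 / np.sqrt(masses[i])
                vel[i, 0] = c1 * vel[i, 0] + pref * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + pref * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + pref * np.random.standard_normal()
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]

        # neighbour-list rebuild: half-skin max displacement criterion
        max_d2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos_at_build[i, 0]
            dy = pos[i, 1] - pos_at_build[i, 1]
            dz = pos[i, 2] - pos_at_build[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        # divergence guard: non-finite or absurd displacement means the
        # integration has blown up; bail out before the grid binning
        # would index garbage
        if not np.isfinite(max_d2) or max_d2 > 1e8:
            return (saved_pos[:isave], saved_vel[:isave], saved_times[:isave],
                    saved_pe[:isave], saved_ke[:isave], step)
        if max_d2 > half_skin2:
            pairs = _build_pairs(pos, list_cutoff, excl_keys)
            pos_at_build = pos.copy()

        e = _forces(pos, f, bonds, bond_r0, bond_k, angles, theta0, angle_k,
                    dih, dih_phi0, dih_k, dih_rigid,
                    con_i, con_j, con_sigma, eps, con_form, gauss_w,
                    ev_radius, ev_strength, ev_cutoff, pairs,
                    rest_idx, rest_ref, rest_k)
        # B
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vel[i, 0] += inv_m * f[i, 0]
            vel[i, 1] += inv_m * f[i, 1]
            vel[i, 2] += inv_m * f[i, 2]

        if save_interval > 0 and step % save_interval == 0:
            ok = True
            for i in range(n):
                for c in range(3):
                    if not np.isfinite(pos[i, c]) or abs(pos[i, c]) > 1e5:
                        ok = False
            if not ok:
                return (saved_pos[:isave], saved_vel[:isave], saved_times[:isave],
                        saved_pe[:isave], saved_ke[:isave], step)
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                         + vel[i, 2] ** 2)
            saved_pos[isave] = pos
            saved_vel[isave] = vel
            saved_times[isave] = step * dt
            saved_pe[isave] = e[0] + e[1] + e[2] + e[3] + e[4] + e[5]
            saved_ke[isave] = ke
            isave += 1

    return (saved_pos[:isave], saved_vel[:isave], saved_times[:isave],
            saved_pe[:isave], saved_ke[:isave], -1)
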