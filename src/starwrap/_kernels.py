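"""Numba kernels: neighbor lists, forces, and the Langevin/BAOAB MD loop.

Everything here operates on plain arrays unpacked from SystemState /
ForceField; the Python-facing API lives in :mod:`starwrap.dynamics`.
Correctness of the pair path is enforced by an all-pairs oracle in the
test suite, so the implementation is free to optimize.

Conventions: box periodic in x/y only (minimum image), open in z.
Unit masses.  Status codes returned by the integrator:
0 ok, 1 FENE overstretch, 2 non-finite coordinate, 3 box collapse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)

POT_NONE = 0
POT_WCA = 1
POT_COS = 2

STATUS_OK = 0
STATUS_FENE = 1
STATUS_NONFINITE = 2
STATUS_COLLAPSE = 3


@njit(cache=True)
def _min_image(dx, dy, lx, ly):
    if dx > 0.5 * lx:
        dx -= lx
    elif dx < -0.5 * lx:
        dx += lx
    if dy > 0.5 * ly:
        dy -= ly
    elif dy < -0.5 * ly:
        dy += ly
    return dx, dy


@njit(cache=True)
def build_pairs(pos, kind, lx, ly, cutoff, listcut2, excl, body, pi, pj):
    """Half neighbor list via a counting-sorted linked-cell sweep.

    ``cutoff`` sets the cell size (largest interaction range + skin);
    ``listcut2`` holds per-kind-pair squared list cutoffs so short-range
    pairs (e.g. head-head) are not stored out to the tail-attraction
    range.  A zero entry marks a non-interacting kind pair, which is
    dropped here.  Returns the pair count, or -1 if the preallocated
    pair arrays overflow (caller grows them and retries).  Excluded
    bonded pairs and intra-rigid-body pairs are filtered here, not in
    the force loop.
    """
    n = pos.shape[0]
    ncx = max(1, int(lx / cutoff))
    ncy = max(1, int(ly / cutoff))
    cap = pi.shape[0]

    if ncx < 3 or ncy < 3:
        # box too small for a non-degenerate periodic cell grid: the
        # half stencil would double-count wrapped neighbors, so fall
        # back to direct enumeration (only hit for small test systems)
        cnt = 0
        half_lx = 0.5 * lx
        half_ly = 0.5 * ly
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                if dx > half_lx:
                    dx -= lx
                elif dx < -half_lx:
                    dx += lx
                dy = pos[i, 1] - pos[j, 1]
                if dy > half_ly:
                    dy -= ly
                elif dy < -half_ly:
                    dy += ly
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < listcut2[kind[i], kind[j]]:
                    if body[i] >= 0 and body[i] == body[j]:
                        continue
                    if excl[i, 0] == j or excl[i, 1] == j:
                        continue
                    if cnt >= cap:
                        return -1
                    pi[cnt] = i
                    pj[cnt] = j
                    cnt += 1
        return cnt

    zlo = pos[0, 2]
    zhi = pos[0, 2]
    for i in range(n):
        z = pos[i, 2]
        if z < zlo:
            zlo = z
        if z > zhi:
            zhi = z
    ncz = max(1, int((zhi - zlo) / cutoff) + 1)
    ncell = ncx * ncy * ncz

    # counting sort beads into cells for contiguous access
    cell = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / lx * ncx) % ncx
        iy = int(pos[i, 1] / ly * ncy) % ncy
        iz = int((pos[i, 2] - zlo) / cutoff)
        if iz >= ncz:
            iz = ncz - 1
        elif iz < 0:
            iz = 0
        c = (iz * ncy + iy) * ncx + ix
        cell[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell[i]
        order[fill[c]] = i
        fill[c] += 1
    # sorted coordinate/kind copies (cache-friendly inner loops)
    px = np.empty(n)
    py = np.empty(n)
    pz = np.empty(n)
    kk = np.empty(n, dtype=np.int64)
    for k in range(n):
        i = order[k]
        px[k] = pos[i, 0]
        py[k] = pos[i, 1]
        pz[k] = pos[i, 2]
        kk[k] = kind[i]

    cut2_global = cutoff * cutoff
    cnt = 0
    half_lx = 0.5 * lx
    half_ly = 0.5 * ly
    for c in range(ncell):
        iz0 = c // (ncx * ncy)
        iy0 = (c // ncx) % ncy
        ix0 = c % ncx
        a0 = count[c]
        a1 = count[c + 1]
        for off in range(14):
            if off == 0:
                dxc, dyc, dzc = 0, 0, 0
            elif off == 1:
                dxc, dyc, dzc = 1, 0, 0
            elif off == 2:
                dxc, dyc, dzc = -1, 1, 0
            elif off == 3:
                dxc, dyc, dzc = 0, 1, 0
            elif off == 4:
                dxc, dyc, dzc = 1, 1, 0
            else:
                k = off - 5
                dxc, dyc, dzc = k % 3 - 1, (k // 3) % 3 - 1, 1
            iz1 = iz0 + dzc
            if iz1 < 0 or iz1 >= ncz:
                continue
            ix1 = (ix0 + dxc) % ncx
            iy1 = (iy0 + dyc) % ncy
            if ncx < 3 and dxc != 0 and ix1 == ix0:
                continue
            if ncy < 3 and dyc != 0 and iy1 == iy0:
                continue
            c1 = (iz1 * ncy + iy1) * ncx + ix1
            if off > 0 and c1 == c:
                continue
            b0 = count[c1]
            b1 = count[c1 + 1]
            for ka in range(a0, a1):
                xa = px[ka]
                ya = py[ka]
                za = pz[ka]
                kb0 = ka + 1 if off == 0 else b0
                for kb in range(kb0, b1):
                    dx = xa - px[kb]
                    dy = ya - py[kb]
                    dz = za - pz[kb]
                    if dx > half_lx:
                        dx -= lx
                    elif dx < -half_lx:
                        dx += lx
                    if dy > half_ly:
                        dy -= ly
                    elif dy < -half_ly:
                        dy += ly
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= cut2_global:
                        continue
                    if r2 < listcut2[kk[ka], kk[kb]]:
                        i = order[ka]
                        j = order[kb]
                        if body[i] >= 0 and body[i] == body[j]:
                            continue
                        if excl[i, 0] == j or excl[i, 1] == j:
                            continue
                        if cnt >= cap:
                            return -1
                        pi[cnt] = i
                        pj[cnt] = j
                        cnt += 1
    return cnt


@njit(cache=True)
def compute_forces(
    pos, kind, lx, ly,
    pi, pj, npairs,
    pot_tab, b_tab, wc_tab,
    bonds, bond_b, k_fene, fene_rmax,
    angles, k_angle, theta0,
    lr_partner, lig_idx,
    morse_eps, morse_r0, morse_alpha,
    forces,
):
    """All forces in one sweep.

    Returns (pair_energy, bond_energy, angle_energy, morse_energy,
    virial_xy, status).  Morse is evaluated only for currently bonded
    ligand-receptor pairs, which are skipped in the nonbonded loop.
    """
    forces[:] = 0.0
    e_pair = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_morse = 0.0
    vir = 0.0

    # per-kind-pair squared interaction cutoffs (0 marks no interaction)
    nk = pot_tab.shape[0]
    cut2_tab = np.zeros((nk, nk))
    for a in range(nk):
        for b2 in range(nk):
            p = pot_tab[a, b2]
            if p == POT_WCA:
                c = WCA_CUT * b_tab[a, b2]
                cut2_tab[a, b2] = c * c
            elif p == POT_COS:
                c = WCA_CUT * b_tab[a, b2] + wc_tab[a, b2]
                cut2_tab[a, b2] = c * c

    half_lx = 0.5 * lx
    half_ly = 0.5 * ly

    # --- nonbonded pairs -------------------------------------------------
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        ki = kind[i]
        kj = kind[j]
        cut2 = cut2_tab[ki, kj]
        if cut2 == 0.0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        if dx > half_lx:
            dx -= lx
        elif dx < -half_lx:
            dx += lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > half_ly:
            dy -= ly
        elif dy < -half_ly:
            dy += ly
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        if lr_partner[i] == j:
            continue  # bonded ligand-receptor pair: Morse only
        pot = pot_tab[ki, kj]
        b = b_tab[ki, kj]
        rc = WCA_CUT * b
        wc = wc_tab[ki, kj]
        r = np.sqrt(r2)
        fr = 0.0  # force / r
        if r < rc:
            s2 = (b * b) / r2
            s6 = s2 * s2 * s2
            e_pair += 4.0 * (s6 * s6 - s6) + 1.0
            fr += 24.0 * (2.0 * s6 * s6 - s6) / r2
        if pot == POT_COS:
            if r < rc:
                e_pair += -1.0
            else:
                # -cos^2(u) = -(1+cos 2u)/2; sin 2u = sqrt(1-cos^2 2u)
                # is exact for 2u in [0, pi], saving one trig call
                c2u = np.cos(np.pi * (r - rc) / wc)
                e_pair += -0.5 * (1.0 + c2u)
                s2u = np.sqrt(max(0.0, 1.0 - c2u * c2u))
                fr += -np.pi / (2.0 * wc) * s2u / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        vir += fx * dx + fy * dy

    # --- FENE bonds (plus the pair's WCA core) ---------------------------
    for bnd in range(bonds.shape[0]):
        i = bonds[bnd, 0]
        j = bonds[bnd, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx, dy = _min_image(dx, dy, lx, ly)
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r >= fene_rmax:
            return e_pair, e_bond, e_angle, e_morse, vir, STATUS_FENE
        x = r2 / (fene_rmax * fene_rmax)
        e_bond += -0.5 * k_fene * fene_rmax * fene_rmax * np.log(1.0 - x)
        fr = -k_fene / (1.0 - x)
        b = bond_b[bnd]
        rc = WCA_CUT * b
        if r < rc:
            s2 = (b * b) / r2
            s6 = s2 * s2 * s2
            e_bond += 4.0 * (s6 * s6 - s6) + 1.0
            fr += 24.0 * (2.0 * s6 * s6 - s6) / r2
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        vir += fx * dx + fy * dy

    # --- harmonic angles -------------------------------------------------
    for an in range(angles.shape[0]):
        a = angles[an, 0]
        b_ = angles[an, 1]
        c = angles[an, 2]
        ux = pos[a, 0] - pos[b_, 0]
        uy = pos[a, 1] - pos[b_, 1]
        ux, uy = _min_image(ux, uy, lx, ly)
        uz = pos[a, 2] - pos[b_, 2]
        vx = pos[c, 0] - pos[b_, 0]
        vy = pos[c, 1] - pos[b_, 1]
        vx, vy = _min_image(vx, vy, lx, ly)
        vz = pos[c, 2] - pos[b_, 2]
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        th = np.arccos(ct)
        dth = th - theta0
        e_angle += k_angle * dth * dth
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        coef = 2.0 * k_angle * dth / st
        # f_a = coef * (v_hat - ct*u_hat)/ru ; f_c symmetric; f_b = -f_a - f_c
        fax = coef * (vx / rv - ct * ux / ru) / ru
        fay = coef * (vy / rv - ct * uy / ru) / ru
        faz = coef * (vz / rv - ct * uz / ru) / ru
        fcx = coef * (ux / ru - ct * vx / rv) / rv
        fcy = coef * (uy / ru - ct * vy / rv) / rv
        fcz = coef * (uz / ru - ct * vz / rv) / rv
        forces[a, 0] += fax
        forces[a, 1] += fay
        forces[a, 2] += faz
        forces[c, 0] += fcx
        forces[c, 1] += fcy
        forces[c, 2] += fcz
        forces[b_, 0] -= fax + fcx
        forces[b_, 1] -= fay + fcy
        forces[b_, 2] -= faz + fcz
        vir += fax * ux + fay * uy + fcx * vx + fcy * vy

    # --- Morse over current ligand-receptor bonds ------------------------
    for li in range(lig_idx.shape[0]):
        i = lig_idx[li]
        j = lr_partner[i]
        if j < 0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx, dy = _min_image(dx, dy, lx, ly)
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ex = np.exp(-morse_alpha * (r - morse_r0))
        e_morse += morse_eps * ((1.0 - ex) * (1.0 - ex) - 1.0)
        fr = -2.0 * morse_eps * morse_alpha * ex * (1.0 - ex) / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        vir += fx * dx + fy * dy

    return e_pair, e_bond, e_angle, e_morse, vir, STATUS_OK


@njit(cache=True)
def update_bonds_kernel(
    pos, kind, lx, ly, lr_partner, lig_idx,
    pi, pj, npairs, r_form, p_form, r_break,
    kind_ligand, kind_receptor,
):
    """Stochastic bond kinetics: break overstretched, form within range.

    Candidate unbound pairs are gathered from the current neighbor list
    and processed in randomized order so the single-valence constraint is
    never violated.  Returns (n_broken, n_formed).
    """
    n_broken = 0
    for li in range(lig_idx.shape[0]):
        i = lig_idx[li]
        j = lr_partner[i]
        if j < 0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx, dy = _min_image(dx, dy, lx, ly)
        dz = pos[i, 2] - pos[j, 2]
        if dx * dx + dy * dy + dz * dz > r_break * r_break:
            lr_partner[i] = -1
            lr_partner[j] = -1
            n_broken += 1

    # gather unbound candidates within r_form
    cap = npairs
    ci = np.empty(cap, dtype=np.int64)
    cj = np.empty(cap, dtype=np.int64)
    nc = 0
    rf2 = r_form * r_form
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        ki = kind[i]
        kj = kind[j]
        if ki == kind_ligand and kj == kind_receptor:
            lig, rec = i, j
        elif kj == kind_ligand and ki == kind_receptor:
            lig, rec = j, i
        else:
            continue
        if lr_partner[lig] >= 0 or lr_partner[rec] >= 0:
            continue
        dx = pos[lig, 0] - pos[rec, 0]
        dy = pos[lig, 1] - pos[rec, 1]
        dx, dy = _min_image(dx, dy, lx, ly)
        dz = pos[lig, 2] - pos[rec, 2]
        if dx * dx + dy * dy + dz * dz <= rf2:
            ci[nc] = lig
            cj[nc] = rec
            nc += 1

    # randomized processing order (Fisher-Yates)
    for k in range(nc - 1, 0, -1):
        m = int(np.random.random() * (k + 1))
        if m > k:
            m = k
        ti = ci[k]
        ci[k] = ci[m]
        ci[m] = ti
        tj = cj[k]
        cj[k] = cj[m]
        cj[m] = tj

    n_formed = 0
    for k in range(nc):
        lig = ci[k]
        rec = cj[k]
        if lr_partner[lig] >= 0 or lr_partner[rec] >= 0:
            continue
        if np.random.random() < p_form:
            lr_partner[lig] = rec
            lr_partner[rec] = lig
            n_formed += 1
    return n_broken, n_formed


@njit(cache=True)
def _rotate_matrix(rot, wx, wy, wz, dt):
    """Apply a Rodrigues rotation exp([w]x dt) to the orientation matrix."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz) * dt
    if ang < 1e-14:
        return rot
    kx = wx * dt / ang
    ky = wy * dt / ang
    kz = wz * dt / ang
    c = np.cos(ang)
    s = np.sin(ang)
    one_c = 1.0 - c
    rr = np.empty((3, 3))
    rr[0, 0] = c + kx * kx * one_c
    rr[0, 1] = kx * ky * one_c - kz * s
    rr[0, 2] = kx * kz * one_c + ky * s
    rr[1, 0] = ky * kx * one_c + kz * s
    rr[1, 1] = c + ky * ky * one_c
    rr[1, 2] = ky * kz * one_c - kx * s
    rr[2, 0] = kz * kx * one_c - ky * s
    rr[2, 1] = kz * ky * one_c + kx * s
    rr[2, 2] = c + kz * kz * one_c
    out = rr @ rot
    # Gram-Schmidt re-orthonormalization against drift
    n0 = np.sqrt(out[0, 0] ** 2 + out[0, 1] ** 2 + out[0, 2] ** 2)
    out[0] /= n0
    d = out[0, 0] * out[1, 0] + out[0, 1] * out[1, 1] + out[0, 2] * out[1, 2]
    out[1] -= d * out[0]
    n1 = np.sqrt(out[1, 0] ** 2 + out[1, 1] ** 2 + out[1, 2] ** 2)
    out[1] /= n1
    out[2, 0] = out[0, 1] * out[1, 2] - out[0, 2] * out[1, 1]
    out[2, 1] = out[0, 2] * out[1, 0] - out[0, 0] * out[1, 2]
    out[2, 2] = out[0, 0] * out[1, 1] - out[0, 1] * out[1, 0]
    return out


@njit(cache=True)
def _sync_rigid(pos, images, rigid, body_coords, com, rot, lx, ly):
    for k in range(rigid.shape[0]):
        i = rigid[k]
        x = com[0] + rot[0, 0] * body_coords[k, 0] + rot[0, 1] * body_coords[k, 1] + rot[0, 2] * body_coords[k, 2]
        y = com[1] + rot[1, 0] * body_coords[k, 0] + rot[1, 1] * body_coords[k, 1] + rot[1, 2] * body_coords[k, 2]
        z = com[2] + rot[2, 0] * body_coords[k, 0] + rot[2, 1] * body_coords[k, 1] + rot[2, 2] * body_coords[k, 2]
        ix = np.floor(x / lx)
        iy = np.floor(y / ly)
        pos[i, 0] = x - ix * lx
        pos[i, 1] = y - iy * ly
        pos[i, 2] = z
        images[i, 0] = int(ix)
        images[i, 1] = int(iy)


@njit(cache=True)
def run_md(
    pos, vel, images, kind, body, excl,
    bonds, bond_b, angles,
    rigid, body_coords, com, rot, rigid_vel, rigid_angvel,
    lr_partner, lig_idx,
    pot_tab, b_tab, wc_tab,
    k_fene, fene_rmax, k_angle, theta0,
    morse_eps, morse_r0, morse_alpha,
    r_form, p_form, r_break, bond_every,
    box, dt, temp, gamma,
    baro_on, baro_tau, baro_ka, frozen_particle,
    n_steps, nlist_every, skin, seed,
    sample_every, out_time, out_wrape, out_nbonds, out_area, out_temp,
    traj_every, head_idx, out_heads,
    t_start,
):
    """Integrate ``n_steps`` BAOAB Langevin steps with bond kinetics and a
    zero-tension Berendsen-style area barostat.

    Returns (status, failed_step, n_samples, n_frames).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    lx = box[0]
    ly = box[1]
    nrig = rigid.shape[0]
    has_rigid = nrig > 0 and not frozen_particle

    free = np.ones(n, dtype=np.bool_)
    for k in range(nrig):
        free[rigid[k]] = False
    n_free = 0
    for i in range(n):
        if free[i]:
            n_free += 1

    mass_r = float(nrig)
    inertia = 0.0
    for k in range(nrig):
        inertia += (body_coords[k, 0] ** 2 + body_coords[k, 1] ** 2 + body_coords[k, 2] ** 2)
    inertia *= 2.0 / 3.0
    if inertia <= 0.0:
        inertia = 1.0

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(temp * (1.0 - c1 * c1))

    # per-kind-pair list cutoffs; ligand-receptor pairs must also reach
    # the bond-formation radius
    nk = pot_tab.shape[0]
    listcut2 = np.zeros((nk, nk))
    cutoff_list = 0.0
    for a in range(nk):
        for b2 in range(nk):
            p = pot_tab[a, b2]
            if p == POT_WCA:
                c = WCA_CUT * b_tab[a, b2] + skin
            elif p == POT_COS:
                c = WCA_CUT * b_tab[a, b2] + wc_tab[a, b2] + skin
            else:
                c = 0.0
            if (a == 4 and b2 == 2) or (a == 2 and b2 == 4):
                if c < r_form + skin:
                    c = r_form + skin
            listcut2[a, b2] = c * c
            if c > cutoff_list:
                cutoff_list = c

    cap = 80 * n + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    npairs = build_pairs(pos, kind, lx, ly, cutoff_list, listcut2, excl, body, pi, pj)
    while npairs < 0:
        cap *= 2
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        npairs = build_pairs(pos, kind, lx, ly, cutoff_list, listcut2, excl, body, pi, pj)

    forces = np.zeros((n, 3))
    ep, eb, ea, em, vir, status = compute_forces(
        pos, kind, lx, ly, pi, pj, npairs, pot_tab, b_tab, wc_tab,
        bonds, bond_b, k_fene, fene_rmax, angles, k_angle, theta0,
        lr_partner, lig_idx, morse_eps, morse_r0, morse_alpha, forces,
    )
    if status != STATUS_OK:
        return status, 0, 0, 0

    n_samples = 0
    n_frames = 0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            if free[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if has_rigid:
            fx = 0.0
            fy = 0.0
            fz = 0.0
            tx = 0.0
            ty = 0.0
            tz = 0.0
            for k in range(nrig):
                i = rigid[k]
                rx = rot[0, 0] * body_coords[k, 0] + rot[0, 1] * body_coords[k, 1] + rot[0, 2] * body_coords[k, 2]
                ry = rot[1, 0] * body_coords[k, 0] + rot[1, 1] * body_coords[k, 1] + rot[1, 2] * body_coords[k, 2]
                rz = rot[2, 0] * body_coords[k, 0] + rot[2, 1] * body_coords[k, 1] + rot[2, 2] * body_coords[k, 2]
                fx += forces[i, 0]
                fy += forces[i, 1]
                fz += forces[i, 2]
                tx += ry * forces[i, 2] - rz * forces[i, 1]
                ty += rz * forces[i, 0] - rx * forces[i, 2]
                tz += rx * forces[i, 1] - ry * forces[i, 0]
            rigid_vel[0] += 0.5 * dt * fx / mass_r
            rigid_vel[1] += 0.5 * dt * fy / mass_r
            rigid_vel[2] += 0.5 * dt * fz / mass_r
            rigid_angvel[0] += 0.5 * dt * tx / inertia
            rigid_angvel[1] += 0.5 * dt * ty / inertia
            rigid_angvel[2] += 0.5 * dt * tz / inertia

        # A: half drift
        for i in range(n):
            if free[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        if has_rigid:
            com[0] += 0.5 * dt * rigid_vel[0]
            com[1] += 0.5 * dt * rigid_vel[1]
            com[2] += 0.5 * dt * rigid_vel[2]
            rot[:] = _rotate_matrix(rot, rigid_angvel[0], rigid_angvel[1], rigid_angvel[2], 0.5 * dt)

        # O: Ornstein-Uhlenbeck velocity refresh
        if gamma > 0.0:
            xi = np.random.standard_normal(3 * n)
            for i in range(n):
                if free[i]:
                    k3 = 3 * i
                    vel[i, 0] = c1 * vel[i, 0] + c2 * xi[k3]
                    vel[i, 1] = c1 * vel[i, 1] + c2 * xi[k3 + 1]
                    vel[i, 2] = c1 * vel[i, 2] + c2 * xi[k3 + 2]
            if has_rigid:
                cr = np.sqrt(temp * (1.0 - c1 * c1) / mass_r)
                ca = np.sqrt(temp * (1.0 - c1 * c1) / inertia)
                for d in range(3):
                    rigid_vel[d] = c1 * rigid_vel[d] + cr * np.random.normal()
                    rigid_angvel[d] = c1 * rigid_angvel[d] + ca * np.random.normal()

        # A: half drift + wrap
        for i in range(n):
            if free[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
                ix = np.floor(pos[i, 0] / lx)
                iy = np.floor(pos[i, 1] / ly)
                if ix != 0:
                    pos[i, 0] -= ix * lx
                    images[i, 0] += int(ix)
                if iy != 0:
                    pos[i, 1] -= iy * ly
                    images[i, 1] += int(iy)
        if has_rigid:
            com[0] += 0.5 * dt * rigid_vel[0]
            com[1] += 0.5 * dt * rigid_vel[1]
            com[2] += 0.5 * dt * rigid_vel[2]
            rot[:] = _rotate_matrix(rot, rigid_angvel[0], rigid_angvel[1], rigid_angvel[2], 0.5 * dt)
        if nrig > 0:
            _sync_rigid(pos, images, rigid, body_coords, com, rot, lx, ly)

        # bond kinetics
        if bond_every > 0 and (step + 1) % bond_every == 0:
            update_bonds_kernel(
                pos, kind, lx, ly, lr_partner, lig_idx,
                pi, pj, npairs, r_form, p_form, r_break, 4, 2,
            )

        # neighbor list refresh
        if (step + 1) % nlist_every == 0:
            npairs = build_pairs(pos, kind, lx, ly, cutoff_list, listcut2, excl, body, pi, pj)
            while npairs < 0:
                cap *= 2
                pi = np.empty(cap, dtype=np.int64)
                pj = np.empty(cap, dtype=np.int64)
                npairs = build_pairs(pos, kind, lx, ly, cutoff_list, listcut2, excl, body, pi, pj)

        # forces at the new positions
        ep, eb, ea, em, vir, status = compute_forces(
            pos, kind, lx, ly, pi, pj, npairs, pot_tab, b_tab, wc_tab,
            bonds, bond_b, k_fene, fene_rmax, angles, k_angle, theta0,
            lr_partner, lig_idx, morse_eps, morse_r0, morse_alpha, forces,
        )
        if status != STATUS_OK:
            return status, step, n_samples, n_frames

        # B: half kick
        for i in range(n):
            if free[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if has_rigid:
            fx = 0.0
            fy = 0.0
            fz = 0.0
            tx = 0.0
            ty = 0.0
            tz = 0.0
            for k in range(nrig):
                i = rigid[k]
                rx = rot[0, 0] * body_coords[k, 0] + rot[0, 1] * body_coords[k, 1] + rot[0, 2] * body_coords[k, 2]
                ry = rot[1, 0] * body_coords[k, 0] + rot[1, 1] * body_coords[k, 1] + rot[1, 2] * body_coords[k, 2]
                rz = rot[2, 0] * body_coords[k, 0] + rot[2, 1] * body_coords[k, 1] + rot[2, 2] * body_coords[k, 2]
                fx += forces[i, 0]
                fy += forces[i, 1]
                fz += forces[i, 2]
                tx += ry * forces[i, 2] - rz * forces[i, 1]
                ty += rz * forces[i, 0] - rx * forces[i, 2]
                tz += rx * forces[i, 1] - ry * forces[i, 0]
            rigid_vel[0] += 0.5 * dt * fx / mass_r
            rigid_vel[1] += 0.5 * dt * fy / mass_r
            rigid_vel[2] += 0.5 * dt * fz / mass_r
            rigid_angvel[0] += 0.5 * dt * tx / inertia
            rigid_angvel[1] += 0.5 * dt * ty / inertia
            rigid_angvel[2] += 0.5 * dt * tz / inertia

        # zero-tension barostat: Berendsen-style area rescale
        if baro_on:
            ke_xy = 0.0
            for i in range(n):
                if free[i]:
                    ke_xy += vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
            if has_rigid:
                ke_xy += mass_r * (rigid_vel[0] ** 2 + rigid_vel[1] ** 2)
            area = lx * ly
            tension2d = 0.5 * (ke_xy + vir) / area
            mu = 1.0 + dt * tension2d / (2.0 * baro_tau * baro_ka)
            if mu > 1.0005:
                mu = 1.0005
            elif mu < 0.9995:
                mu = 0.9995
            lx *= mu
            ly *= mu
            if lx < 4.0:
                return STATUS_COLLAPSE, step, n_samples, n_frames
            for i in range(n):
                if free[i]:
                    pos[i, 0] *= mu
                    pos[i, 1] *= mu
            com[0] *= mu
            com[1] *= mu
            if nrig > 0:
                _sync_rigid(pos, images, rigid, body_coords, com, rot, lx, ly)

        # sampling
        if sample_every > 0 and (step + 1) % sample_every == 0:
            ke = 0.0
            for i in range(n):
                if free[i]:
                    ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            nb = 0
            for li in range(lig_idx.shape[0]):
                if lr_partner[lig_idx[li]] >= 0:
                    nb += 1
            out_time[n_samples] = t_start + (step + 1) * dt
            out_wrape[n_samples] = em
            out_nbonds[n_samples] = nb
            out_area[n_samples] = lx * ly
            out_temp[n_samples] = ke / (3.0 * n_free) if n_free > 0 else 0.0
            n_samples += 1

        if traj_every > 0 and (step + 1) % traj_every == 0:
            for hk in range(head_idx.shape[0]):
                i = head_idx[hk]
                out_heads[n_frames, hk, 0] = pos[i, 0] + images[i, 0] * lx
                out_heads[n_frames, hk, 1] = pos[i, 1] + images[i, 1] * ly
                out_heads[n_frames, hk, 2] = pos[i, 2]
            n_frames += 1

        if not np.isfinite(pos[0, 0]):
            return STATUS_NONFINITE, step, n_samples, n_frames

    box[0] = lx
    box[1] = ly
    return STATUS_OK, n_steps, n_samples, n_frames
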