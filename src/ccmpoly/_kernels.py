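"""Numba kernels: neighbor lists, forces, Brownian and Langevin integrators.

All quantities are in reduced units (sigma = 1, k_B T = 1, bead mass = 1).
The pair potential is a unit-amplitude WCA core plus an attractive 12-6
branch scaled by the type-pair well depth, truncated at ``cutoff`` (the
energy shift does not enter forces).  Chain bonds are FENE + WCA (or
harmonic in ideal-chain mode); loop bonds are capped-harmonic tethers.

Directly chain-bonded pairs are skipped inside the pair loop (j = i + 1);
loop-anchor pairs have their pair-potential contribution subtracted in a
separate tiny loop, which keeps the hot loop free of exclusion lookups.
"""

import numpy as np
from numba import njit

LJ_MIN = 2.0 ** (1.0 / 6.0)

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_NEIGH_OVERFLOW = 2


@njit(cache=True)
def _build_neighbors(pos, rlist, max_neigh, pi, pj, peps, eps_mat, types):
    """Half pair list (i < j, j != i+1) via a cell list; -1 on overflow.

    The per-pair well depth is cached at build time so the force loop does
    no table lookups.
    """
    n = pos.shape[0]
    rlist2 = rlist * rlist
    lo0 = pos[0, 0]; lo1 = pos[0, 1]; lo2 = pos[0, 2]
    hi0 = lo0; hi1 = lo1; hi2 = lo2
    for i in range(n):
        if pos[i, 0] < lo0: lo0 = pos[i, 0]
        if pos[i, 0] > hi0: hi0 = pos[i, 0]
        if pos[i, 1] < lo1: lo1 = pos[i, 1]
        if pos[i, 1] > hi1: hi1 = pos[i, 1]
        if pos[i, 2] < lo2: lo2 = pos[i, 2]
        if pos[i, 2] > hi2: hi2 = pos[i, 2]
    hi0 += 1e-9; hi1 += 1e-9; hi2 += 1e-9
    nx = max(1, int((hi0 - lo0) / rlist))
    ny = max(1, int((hi1 - lo1) / rlist))
    nz = max(1, int((hi2 - lo2) / rlist))
    ncell = nx * ny * nz
    cell_of = np.empty(n, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - lo0) / (hi0 - lo0) * nx)
        cy = int((pos[i, 1] - lo1) / (hi1 - lo1) * ny)
        cz = int((pos[i, 2] - lo2) / (hi2 - lo2) * nz)
        if cx >= nx: cx = nx - 1
        if cy >= ny: cy = ny - 1
        if cz >= nz: cz = nz - 1
        cell_of[i] = (cx * ny + cy) * nz + cz
    count = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        count[cell_of[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    npairs = 0
    for i in range(n):
        c = cell_of[i]
        cz = c % nz
        cy = (c // nz) % ny
        cx = c // (ny * nz)
        for ox in range(-1, 2):
            x = cx + ox
            if x < 0 or x >= nx:
                continue
            for oy in range(-1, 2):
                y = cy + oy
                if y < 0 or y >= ny:
                    continue
                for oz in range(-1, 2):
                    z = cz + oz
                    if z < 0 or z >= nz:
                        continue
                    cc = (x * ny + y) * nz + z
                    for idx in range(count[cc], count[cc + 1]):
                        j = order[idx]
                        if j <= i or j == i + 1:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 >= rlist2:
                            continue
                        if npairs >= max_neigh:
                            return -1
                        pi[npairs] = i
                        pj[npairs] = j
                        peps[npairs] = eps_mat[types[i], types[j]]
                        npairs += 1
    return npairs


@njit(cache=True)
def _pair_force_factor(r2, eps, use_core, cutoff2, ljmin2):
    """(dU/dr)/r with sign such that F_i = factor * (r_i - r_j)."""
    if r2 >= cutoff2:
        return 0.0
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    lj = 24.0 * inv6 * (2.0 * inv6 - 1.0) * inv2
    if r2 < ljmin2:
        return lj if use_core == 1 else 0.0
    return eps * lj


@njit(cache=True)
def _forces(pos, bond_style, bond_k, bond_len,
            loops, loop_k, loop_r0, loop_cap,
            eps_mat, types, use_core, cutoff, pi, pj, peps, npairs, force):
    """Fill ``force``; returns index of an overstretched chain bond or -1."""
    n = pos.shape[0]
    for i in range(n):
        force[i, 0] = 0.0
        force[i, 1] = 0.0
        force[i, 2] = 0.0
    cutoff2 = cutoff * cutoff
    ljmin2 = LJ_MIN * LJ_MIN

    # chain bonds (i, i+1)
    for i in range(n - 1):
        j = i + 1
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if bond_style == 0:  # FENE + WCA
            rm2 = bond_len * bond_len
            if r2 >= 0.9801 * rm2:  # about to leave the FENE domain
                return i
            fr = -bond_k / (1.0 - r2 / rm2)
            if r2 < ljmin2:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                fr += 24.0 * inv6 * (2.0 * inv6 - 1.0) * inv2
        else:  # harmonic about bond_len
            r = np.sqrt(r2)
            fr = -bond_k * (r - bond_len) / r if r > 1e-12 else 0.0
        force[i, 0] += fr * dx
        force[i, 1] += fr * dy
        force[i, 2] += fr * dz
        force[j, 0] -= fr * dx
        force[j, 1] -= fr * dy
        force[j, 2] -= fr * dz

    # non-bonded pairs (chain-bonded pairs never enter the list)
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        fr = _pair_force_factor(r2, peps[p], use_core, cutoff2, ljmin2)
        force[i, 0] += fr * dx
        force[i, 1] += fr * dy
        force[i, 2] += fr * dz
        force[j, 0] -= fr * dx
        force[j, 1] -= fr * dy
        force[j, 2] -= fr * dz

    # loop bonds: capped-harmonic tether, minus the pair term that the
    # neighbor list added for this (excluded) pair
    for b in range(loops.shape[0]):
        i = loops[b, 0]
        j = loops[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < 1e-12:
            continue
        ext = r - loop_r0
        if ext > loop_cap:
            ext = loop_cap
        elif ext < -loop_cap:
            ext = -loop_cap
        fr = -loop_k * ext / r
        # subtract the (possibly present) pair interaction for this pair;
        # beyond the cutoff the correction is zero, matching the list
        fr -= _pair_force_factor(r2, eps_mat[types[i], types[j]],
                                 use_core, cutoff2, ljmin2)
        force[i, 0] += fr * dx
        force[i, 1] += fr * dy
        force[i, 2] += fr * dz
        force[j, 0] -= fr * dx
        force[j, 1] -= fr * dy
        force[j, 2] -= fr * dz
    return -1


@njit(cache=True)
def bd_run(pos, types, bond_style, bond_k, bond_len,
           loops, loop_k, loop_r0, loop_cap,
           eps_mat, use_core, cutoff, skin,
           dt, zeta, kT, n_steps, save_every, seed, frames):
    """Overdamped (Brownian) Euler-Maruyama integration.

    x += F dt/zeta + sqrt(2 kT dt / zeta) xi.  Frames are stored every
    ``save_every`` steps.  Returns (status, detail): on overstretch, detail
    is the failing step.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    max_neigh = 200 * n + 1000
    pi = np.empty(max_neigh, np.int32)
    pj = np.empty(max_neigh, np.int32)
    peps = np.empty(max_neigh)
    rlist = cutoff + skin
    ref = pos.copy()
    npairs = _build_neighbors(pos, rlist, max_neigh, pi, pj, peps, eps_mat, types)
    if npairs < 0:
        return STATUS_NEIGH_OVERFLOW, 0
    force = np.empty((n, 3))
    amp = np.sqrt(2.0 * kT * dt / zeta)
    mob = dt / zeta
    half_skin2 = (0.5 * skin) ** 2
    isave = 0
    for step in range(n_steps):
        bad = _forces(pos, bond_style, bond_k, bond_len,
                      loops, loop_k, loop_r0, loop_cap,
                      eps_mat, types, use_core, cutoff, pi, pj, peps, npairs, force)
        if bad >= 0:
            return STATUS_OVERSTRETCH, step
        noise = np.random.standard_normal((n, 3))
        maxdisp2 = 0.0
        for i in range(n):
            pos[i, 0] += force[i, 0] * mob + amp * noise[i, 0]
            pos[i, 1] += force[i, 1] * mob + amp * noise[i, 1]
            pos[i, 2] += force[i, 2] * mob + amp * noise[i, 2]
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > half_skin2:
            npairs = _build_neighbors(pos, rlist, max_neigh, pi, pj, peps,
                                      eps_mat, types)
            if npairs < 0:
                return STATUS_NEIGH_OVERFLOW, step
            ref[:] = pos
        if (step + 1) % save_every == 0:
            frames[isave] = pos
            isave += 1
    return STATUS_OK, n_steps


@njit(cache=True)
def langevin_run(pos, vel, types, bond_style, bond_k, bond_len,
                 loops, loop_k, loop_r0, loop_cap,
                 eps_mat, use_core, cutoff, skin,
                 dt, gamma, kT, n_steps, save_every, seed, frames, kin_out):
    """BAOAB Langevin integration (unit mass); gamma = 0 is velocity Verlet.

    ``kin_out`` receives the kinetic energy at each saved frame.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    max_neigh = 200 * n + 1000
    pi = np.empty(max_neigh, np.int32)
    pj = np.empty(max_neigh, np.int32)
    peps = np.empty(max_neigh)
    rlist = cutoff + skin
    ref = pos.copy()
    npairs = _build_neighbors(pos, rlist, max_neigh, pi, pj, peps, eps_mat, types)
    if npairs < 0:
        return STATUS_NEIGH_OVERFLOW, 0
    force = np.empty((n, 3))
    bad = _forces(pos, bond_style, bond_k, bond_len,
                  loops, loop_k, loop_r0, loop_cap,
                  eps_mat, types, use_core, cutoff, pi, pj, peps, npairs, force)
    if bad >= 0:
        return STATUS_OVERSTRETCH, 0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    half_skin2 = (0.5 * skin) ** 2
    isave = 0
    for step in range(n_steps):
        noise = np.random.standard_normal((n, 3))
        maxdisp2 = 0.0
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * force[i, d]            # B
                pos[i, d] += 0.5 * dt * vel[i, d]              # A
                vel[i, d] = c1 * vel[i, d] + c2 * noise[i, d]  # O
                pos[i, d] += 0.5 * dt * vel[i, d]              # A
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > half_skin2:
            npairs = _build_neighbors(pos, rlist, max_neigh, pi, pj, peps,
                                      eps_mat, types)
            if npairs < 0:
                return STATUS_NEIGH_OVERFLOW, step
            ref[:] = pos
        bad = _forces(pos, bond_style, bond_k, bond_len,
                      loops, loop_k, loop_r0, loop_cap,
                      eps_mat, types, use_core, cutoff, pi, pj, peps, npairs, force)
        if bad >= 0:
            return STATUS_OVERSTRETCH, step
        for i in range(n):
            vel[i, 0] += 0.5 * dt * force[i, 0]
            vel[i, 1] += 0.5 * dt * force[i, 1]
            vel[i, 2] += 0.5 * dt * force[i, 2]
        if (step + 1) % save_every == 0:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            frames[isave] = pos
            kin_out[isave] = ke
            isave += 1
    return STATUS_OK, n_steps
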