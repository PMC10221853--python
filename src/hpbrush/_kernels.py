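"""Numba-compiled inner loops: neighbour lists, forces, MD integration.

Everything here operates on plain arrays; the object layer in
:mod:`hpbrush.dynamics` owns validation and unit bookkeeping.  Positions are
unwrapped — minimum-image convention is applied inside the distance
computations, and cell assignment wraps coordinates on the fly.

Status codes returned by the kernels:
  0  normal completion
  1  FENE bond reached its maximum extension (integration blow-up)
  2  wall-feeling bead at z <= 0 or z >= H (escaped the slab)
  3  velocity blow-up (|v|^2 above threshold)
  4  neighbour-list capacity overflow (caller enlarges and retries)
"""

from __future__ import annotations

import numpy as np
from numba import njit

# half stencil: self + 13 neighbour cell offsets (no pair double-counting)
_STENCIL = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (1, 1, 0), (-1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (-1, 0, 1), (0, 1, 1), (0, -1, 1),
        (1, 1, 1), (-1, 1, 1), (1, -1, 1), (-1, -1, 1),
    ],
    dtype=np.int64,
)

_VSQ_MAX = 1.0e6  # blow-up threshold on |v|^2


@njit(cache=True)
def _min_image(dx, dy, dz, lx, ly, lz, periodic_z):
    dx -= lx * np.rint(dx / lx)
    dy -= ly * np.rint(dy / ly)
    if periodic_z:
        dz -= lz * np.rint(dz / lz)
    return dx, dy, dz


@njit(cache=True)
def build_neighbors(pos, lx, ly, lz, periodic_z, rlist, pi, pj):
    """Half neighbour list within rlist via a linked-cell sweep.

    Returns the number of pairs written, or -1 on capacity overflow.
    """
    n = pos.shape[0]
    ncx = int(lx / rlist)
    ncy = int(ly / rlist)
    ncz = int(lz / rlist)
    if ncx < 3:
        ncx = 1
    if ncy < 3:
        ncy = 1
    if periodic_z:
        if ncz < 3:
            ncz = 1
    elif ncz < 1:
        ncz = 1

    head = np.full(ncx * ncy * ncz, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cellof = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] % lx
        y = pos[i, 1] % ly
        cx = int(x / lx * ncx)
        cy = int(y / ly * ncy)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if periodic_z:
            z = pos[i, 2] % lz
            cz = int(z / lz * ncz)
        else:
            cz = int(pos[i, 2] / lz * ncz)
        if cz >= ncz:
            cz = ncz - 1
        if cz < 0:
            cz = 0
        cellof[i, 0] = cx
        cellof[i, 1] = cy
        cellof[i, 2] = cz
        cell = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[cell]
        head[cell] = i

    cap = pi.shape[0]
    r2max = rlist * rlist
    count = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                cell = (cx * ncy + cy) * ncz + cz
                for s in range(_STENCIL.shape[0]):
                    ox, oy, oz = _STENCIL[s, 0], _STENCIL[s, 1], _STENCIL[s, 2]
                    if ncx == 1 and ox != 0:
                        continue
                    if ncy == 1 and oy != 0:
                        continue
                    nx2, ny2, nz2 = cx + ox, cy + oy, cz + oz
                    if ncx > 1:
                        nx2 %= ncx
                    if ncy > 1:
                        ny2 %= ncy
                    if periodic_z:
                        if ncz == 1 and oz != 0:
                            continue
                        if ncz > 1:
                            nz2 %= ncz
                    else:
                        if nz2 < 0 or nz2 >= ncz:
                            continue
                        if ncz == 1 and oz != 0:
                            continue
                    other = (nx2 * ncy + ny2) * ncz + nz2
                    same = other == cell
                    i = head[cell]
                    while i >= 0:
                        j = nxt[i] if same else head[other]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, periodic_z)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if count >= cap:
                                    return -1
                                pi[count] = i
                                pj[count] = j
                                count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@njit(cache=True)
def compute_forces_kernel(
    pos, types, bonds, excl, n_excl,
    lx, ly, lz, periodic_z,
    pair_eps, pair_rc2, pair_shift,
    kfene, rfene2, wca_eps, wca_rc2, wca_shift,
    wl_eps, wl_zc, wl_style, wh_eps, wh_zc, wh_style,
    pi, pj, npairs,
    bias_idx, bias_k, bias_l,
    forces,
):
    """Fill ``forces`` and return (potential energy, status, bias COM z)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    status = 0

    # non-bonded pairs
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        skip = False
        for k in range(n_excl[i]):
            if excl[i, k] == j:
                skip = True
                break
        if skip:
            continue
        ti = types[i]
        tj = types[j]
        rc2 = pair_rc2[ti, tj]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, periodic_z)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            eps = pair_eps[ti, tj]
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            pe += 4.0 * eps * (inv6 * inv6 - inv6) - pair_shift[ti, tj]
            fr = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) * inv2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz

    # FENE + WCA bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, periodic_z)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rfene2:
            return pe, 1, 0.0
        x2 = r2 / rfene2
        pe += -0.5 * kfene * rfene2 * np.log(1.0 - x2)
        fr = -kfene / (1.0 - x2)
        if r2 < wca_rc2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            pe += 4.0 * wca_eps * (inv6 * inv6 - inv6) - wca_shift
            fr += 24.0 * wca_eps * (2.0 * inv6 * inv6 - inv6) * inv2
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    # implicit walls (z <= 0 encodes "exempt")
    if not periodic_z:
        for i in range(n):
            t = types[i]
            zc = wl_zc[t]
            if zc > 0.0:
                z = pos[i, 2]
                if z <= 0.0:
                    return pe, 2, 0.0
                if z < zc:
                    if wl_style[t] == 0:
                        inv3 = 1.0 / (z * z * z)
                        shift = wl_eps[t] * ((2.0 / 15.0) / (zc ** 9) - 1.0 / (zc ** 3))
                        pe += wl_eps[t] * ((2.0 / 15.0) * inv3 ** 3 - inv3) - shift
                        forces[i, 2] += wl_eps[t] * (
                            (6.0 / 5.0) / z ** 10 - 3.0 / z ** 4
                        )
                    else:
                        inv6 = 1.0 / (z ** 6)
                        shift = 4.0 * wl_eps[t] * (1.0 / zc ** 12 - 1.0 / zc ** 6)
                        pe += 4.0 * wl_eps[t] * (inv6 * inv6 - inv6) - shift
                        forces[i, 2] += 24.0 * wl_eps[t] * (
                            2.0 * inv6 * inv6 - inv6
                        ) / z
            zc = wh_zc[t]
            if zc > 0.0:
                a = lz - pos[i, 2]
                if a <= 0.0:
                    return pe, 2, 0.0
                if a < zc:
                    if wh_style[t] == 0:
                        inv3 = 1.0 / (a * a * a)
                        shift = wh_eps[t] * ((2.0 / 15.0) / (zc ** 9) - 1.0 / (zc ** 3))
                        pe += wh_eps[t] * ((2.0 / 15.0) * inv3 ** 3 - inv3) - shift
                        forces[i, 2] -= wh_eps[t] * (
                            (6.0 / 5.0) / a ** 10 - 3.0 / a ** 4
                        )
                    else:
                        inv6 = 1.0 / (a ** 6)
                        shift = 4.0 * wh_eps[t] * (1.0 / zc ** 12 - 1.0 / zc ** 6)
                        pe += 4.0 * wh_eps[t] * (inv6 * inv6 - inv6) - shift
                        forces[i, 2] -= 24.0 * wh_eps[t] * (
                            2.0 * inv6 * inv6 - inv6
                        ) / a

    # harmonic COM bias along z (steered-MD spring)
    bias_z = 0.0
    ng = bias_idx.shape[0]
    if ng > 0:
        zcom = 0.0
        for m in range(ng):
            zcom += pos[bias_idx[m], 2]
        zcom /= ng
        pe += 0.5 * bias_k * (zcom - bias_l) ** 2
        fz = -bias_k * (zcom - bias_l) / ng
        for m in range(ng):
            forces[bias_idx[m], 2] += fz
        bias_z = zcom
    return pe, status, bias_z


@njit(cache=True)
def _kinetic(vel, mobile):
    k2 = 0.0
    for i in range(vel.shape[0]):
        if mobile[i]:
            k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return k2  # = 2 * kinetic energy for unit masses


@njit(cache=True)
def _nh_half(vel, mobile, vxi, dt, g_temp, q):
    k2 = _kinetic(vel, mobile)
    vxi += 0.25 * dt * (k2 - g_temp) / q
    s = np.exp(-0.5 * dt * vxi)
    for i in range(vel.shape[0]):
        if mobile[i]:
            vel[i, 0] *= s
            vel[i, 1] *= s
            vel[i, 2] *= s
    k2 *= s * s
    vxi += 0.25 * dt * (k2 - g_temp) / q
    return vxi


@njit(cache=True)
def run_md_kernel(
    pos, vel, types, mobile, bonds, excl, n_excl,
    lx, ly, lz, periodic_z,
    pair_eps, pair_rc2, pair_shift,
    kfene, rfene2, wca_eps, wca_rc2, wca_shift,
    wl_eps, wl_zc, wl_style, wh_eps, wh_zc, wh_style,
    bias_idx, bias_k, bias_l,
    dt, nsteps, thermostat, temp, damping, seed, vxi0,
    log_stride, traj_stride, traj_sel,
    skin, rlist, pi, pj,
    traj_pos, traj_time,
    log_time, log_temp, log_pe, log_ke, log_z,
    t0,
):
    """Velocity-Verlet MD loop; thermostat 0=NVE, 1=Nose-Hoover, 2=Langevin.

    Returns (status, steps completed, final thermostat velocity).
    """
    n = pos.shape[0]
    n_mobile = 0
    for i in range(n):
        if mobile[i]:
            n_mobile += 1
    g = 3.0 * n_mobile
    q = g * temp * damping * damping if temp > 0.0 else 1.0
    vxi = vxi0
    if thermostat == 2:
        np.random.seed(seed)
        c1 = np.exp(-dt / damping)
        c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * temp))

    forces = np.zeros((n, 3))
    ref = pos.copy()
    npairs = build_neighbors(pos, lx, ly, lz, periodic_z, rlist, pi, pj)
    if npairs < 0:
        return 4, 0, vxi
    pe, status, bias_z = compute_forces_kernel(
        pos, types, bonds, excl, n_excl, lx, ly, lz, periodic_z,
        pair_eps, pair_rc2, pair_shift,
        kfene, rfene2, wca_eps, wca_rc2, wca_shift,
        wl_eps, wl_zc, wl_style, wh_eps, wh_zc, wh_style,
        pi, pj, npairs, bias_idx, bias_k, bias_l, forces,
    )
    if status != 0:
        return status, 0, vxi

    half_skin2 = 0.25 * skin * skin
    for step in range(nsteps):
        if thermostat == 1:
            vxi = _nh_half(vel, mobile, vxi, dt, g * temp, q)
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if thermostat == 2:
            # BAOAB splitting: drift half, Ornstein-Uhlenbeck, drift half
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] += 0.5 * dt * vel[i, 0]
                    pos[i, 1] += 0.5 * dt * vel[i, 1]
                    pos[i, 2] += 0.5 * dt * vel[i, 2]
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                if mobile[i]:
                    vel[i, 0] = c1 * vel[i, 0] + c2 * noise[i, 0]
                    vel[i, 1] = c1 * vel[i, 1] + c2 * noise[i, 1]
                    vel[i, 2] = c1 * vel[i, 2] + c2 * noise[i, 2]
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] += 0.5 * dt * vel[i, 0]
                    pos[i, 1] += 0.5 * dt * vel[i, 1]
                    pos[i, 2] += 0.5 * dt * vel[i, 2]
        else:
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] += dt * vel[i, 0]
                    pos[i, 1] += dt * vel[i, 1]
                    pos[i, 2] += dt * vel[i, 2]

        # half-skin displacement criterion for list rebuild
        maxd2 = 0.0
        for i in range(n):
            if mobile[i]:
                ddx = pos[i, 0] - ref[i, 0]
                ddy = pos[i, 1] - ref[i, 1]
                ddz = pos[i, 2] - ref[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > maxd2:
                    maxd2 = d2
        if maxd2 > half_skin2:
            npairs = build_neighbors(pos, lx, ly, lz, periodic_z, rlist, pi, pj)
            if npairs < 0:
                return 4, step, vxi
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]

        pe, status, bias_z = compute_forces_kernel(
            pos, types, bonds, excl, n_excl, lx, ly, lz, periodic_z,
            pair_eps, pair_rc2, pair_shift,
            kfene, rfene2, wca_eps, wca_rc2, wca_shift,
            wl_eps, wl_zc, wl_style, wh_eps, wh_zc, wh_style,
            pi, pj, npairs, bias_idx, bias_k, bias_l, forces,
        )
        if status != 0:
            return status, step, vxi

        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if thermostat == 1:
            vxi = _nh_half(vel, mobile, vxi, dt, g * temp, q)

        done = step + 1
        if done % log_stride == 0:
            li = done // log_stride - 1
            if li < log_time.shape[0]:
                k2 = _kinetic(vel, mobile)
                if k2 > _VSQ_MAX * n_mobile:
                    return 3, done, vxi
                log_time[li] = t0 + done * dt
                log_temp[li] = k2 / g if g > 0 else 0.0
                log_pe[li] = pe
                log_ke[li] = 0.5 * k2
                log_z[li] = bias_z
        if done % traj_stride == 0:
            fi = done // traj_stride - 1
            if fi < traj_pos.shape[0]:
                for m in range(traj_sel.shape[0]):
                    s = traj_sel[m]
                    traj_pos[fi, m, 0] = pos[s, 0]
                    traj_pos[fi, m, 1] = pos[s, 1]
                    traj_pos[fi, m, 2] = pos[s, 2]
                traj_time[fi] = t0 + done * dt
    return 0, nsteps, vxi
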