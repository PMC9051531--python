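"""Numba kernels for the DPD force loop and integrator.

Everything here operates on plain numpy arrays so it can be jit-compiled;
the object-level API lives in :mod:`brushdpd.sim_core`.

Conventions baked into the kernels:

* reduced units: m = r_c = kT = 1;
* x and y are periodic, z is bounded by two soft walls at z = 0 and z = h;
* pair weight w(r) = 1 - r/r_c for conservative and random forces, w^2 for
  the dissipative force (fluctuation-dissipation then requires
  sigma^2 = 2 gamma kT);
* the random force uses a counter-based generator keyed on
  (seed, step, i, j) so a run is bitwise reproducible and restartable;
* exactly overlapping beads (r = 0) repel along +x, a measure-zero
  deterministic tie-break for a finite soft potential.

Error codes returned by the step loop: 0 ok, 1 non-finite coordinate,
2 bond at or beyond maximum extension (FENE).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_SQRT12 = 3.4641016151377544  # sqrt(12): variance-1 uniform scale

BOND_HARMONIC = 0
BOND_FENE = 1

ERR_OK = 0
ERR_NONFINITE = 1
ERR_BOND_OVEREXTENDED = 2


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + U64(0x9E3779B97F4A7C15)) & U64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> U64(30))) * U64(0xBF58476D1CE4E5B9)) & U64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> U64(27))) * U64(0x94D049BB133111EB)) & U64(0xFFFFFFFFFFFFFFFF)
    return x ^ (x >> U64(31))


@njit(cache=True, inline="always")
def _pair_theta(seed, step, i, j):
    """Unit-variance symmetric uniform deviate keyed on (seed, step, pair)."""
    lo = i if i < j else j
    hi = j if i < j else i
    k = _splitmix64(U64(seed) ^ (U64(step) * U64(0x9E3779B97F4A7C15)))
    k = _splitmix64(k ^ ((U64(lo) << U64(32)) | U64(hi)))
    u = (k >> U64(11)) * (1.0 / 9007199254740992.0)  # 53-bit uniform in [0,1)
    return _SQRT12 * (u - 0.5)


@njit(cache=True)
def _cell_index(x, y, z, Lx, Ly, ncx, ncy, ncz, h):
    ix = int(x / Lx * ncx)
    iy = int(y / Ly * ncy)
    iz = int(z / h * ncz)
    if ix >= ncx:
        ix = ncx - 1
    if ix < 0:
        ix = 0
    if iy >= ncy:
        iy = ncy - 1
    if iy < 0:
        iy = 0
    if iz >= ncz:
        iz = ncz - 1
    if iz < 0:
        iz = 0
    return (iz * ncy + iy) * ncx + ix


@njit(cache=True)
def compute_forces(
    pos,
    vel,
    species,
    bonds,
    bond_model,
    bond_k,
    bond_len,
    a_mat,
    gamma,
    sigma,
    inv_sqrt_dt,
    Lx,
    Ly,
    h,
    aw_bot,
    zc_bot,
    aw_top,
    zc_top,
    seed,
    step,
    include_random,
):
    """Total force on every bead plus the bookkeeping used by observables.

    Returns
    -------
    forces : (N, 3) array
    pair_virial_z : float
        Sum of f_z * z_ij over conservative pair and bond forces (the
        dissipative/random channels are excluded; they average to zero).
    wall_f_bot, wall_f_top : float
        Total |force| the fluid receives from each wall (equal and opposite
        to the force the fluid exerts on that wall).
    wall_virial_z : float
        Sum of wall force times distance-from-own-plane, the boundary term
        that closes the mechanical-balance identity for the virial P_zz.
    err : int, err_idx : int
        Error code and offending bond index (FENE overextension).
    """
    N = pos.shape[0]
    forces = np.zeros((N, 3))
    pair_virial_z = 0.0
    wall_f_bot = 0.0
    wall_f_top = 0.0
    wall_virial_z = 0.0
    err = ERR_OK
    err_idx = -1

    # --- cell list (cells no smaller than r_c = 1) ---
    ncx = max(1, int(Lx))
    ncy = max(1, int(Ly))
    ncz = max(1, int(h))
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    for i in range(N):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], Lx, Ly, ncx, ncy, ncz, h)
        nxt[i] = head[c]
        head[c] = i

    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                for dz in range(-1, 2):
                    z2 = cz + dz
                    if z2 < 0 or z2 >= ncz:
                        continue
                    for dy in range(-1, 2):
                        y2 = (cy + dy) % ncy
                        for dx in range(-1, 2):
                            x2 = (cx + dx) % ncx
                            c2 = (z2 * ncy + y2) * ncx + x2
                            if c2 < c:
                                continue
                            i = head[c]
                            while i >= 0:
                                if c2 == c:
                                    j = nxt[i]
                                else:
                                    j = head[c2]
                                while j >= 0:
                                    rx = pos[i, 0] - pos[j, 0]
                                    ry = pos[i, 1] - pos[j, 1]
                                    rz = pos[i, 2] - pos[j, 2]
                                    # lateral minimum image
                                    if rx > 0.5 * Lx:
                                        rx -= Lx
                                    elif rx < -0.5 * Lx:
                                        rx += Lx
                                    if ry > 0.5 * Ly:
                                        ry -= Ly
                                    elif ry < -0.5 * Ly:
                                        ry += Ly
                                    r2 = rx * rx + ry * ry + rz * rz
                                    if r2 < 1.0:
                                        r = np.sqrt(r2)
                                        if r < 1e-12:
                                            # overlap tie-break: repel along +x
                                            ex, ey, ez = 1.0, 0.0, 0.0
                                            r = 0.0
                                        else:
                                            inv_r = 1.0 / r
                                            ex = rx * inv_r
                                            ey = ry * inv_r
                                            ez = rz * inv_r
                                        w = 1.0 - r
                                        a = a_mat[species[i], species[j]]
                                        fc = a * w
                                        vx = vel[i, 0] - vel[j, 0]
                                        vy = vel[i, 1] - vel[j, 1]
                                        vz = vel[i, 2] - vel[j, 2]
                                        vdote = vx * ex + vy * ey + vz * ez
                                        f = fc - gamma * w * w * vdote
                                        if include_random:
                                            f += (
                                                sigma
                                                * w
                                                * _pair_theta(seed, step, i, j)
                                                * inv_sqrt_dt
                                            )
                                        forces[i, 0] += f * ex
                                        forces[i, 1] += f * ey
                                        forces[i, 2] += f * ez
                                        forces[j, 0] -= f * ex
                                        forces[j, 1] -= f * ey
                                        forces[j, 2] -= f * ez
                                        pair_virial_z += fc * ez * rz
                                    j = nxt[j]
                                i = nxt[i]

    # --- bonds ---
    nb = bonds.shape[0]
    for b in range(nb):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        if rx > 0.5 * Lx:
            rx -= Lx
        elif rx < -0.5 * Lx:
            rx += Lx
        if ry > 0.5 * Ly:
            ry -= Ly
        elif ry < -0.5 * Ly:
            ry += Ly
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        if r < 1e-12:
            ex, ey, ez = 1.0, 0.0, 0.0
        else:
            ex, ey, ez = rx / r, ry / r, rz / r
        if bond_model == BOND_FENE:
            if r >= bond_len:
                err = ERR_BOND_OVEREXTENDED
                err_idx = b
                continue
            x = r / bond_len
            fmag = -bond_k * r / (1.0 - x * x)
        else:  # harmonic about rest length bond_len
            fmag = -bond_k * (r - bond_len)
        forces[i, 0] += fmag * ex
        forces[i, 1] += fmag * ey
        forces[i, 2] += fmag * ez
        forces[j, 0] -= fmag * ex
        forces[j, 1] -= fmag * ey
        forces[j, 2] -= fmag * ez
        pair_virial_z += fmag * ez * rz

    # --- walls: F_w(d) = a_w (1 - d/z_C) for d < z_C, 0 beyond ---
    for i in range(N):
        d = pos[i, 2]
        if d < 0.0:
            d = 0.0  # bead behind wall: clamped contact force
        if d < zc_bot:
            f = aw_bot * (1.0 - d / zc_bot)
            forces[i, 2] += f
            wall_f_bot += f
            wall_virial_z += f * d
        d = h - pos[i, 2]
        if d < 0.0:
            d = 0.0
        if d < zc_top:
            f = aw_top * (1.0 - d / zc_top)
            forces[i, 2] -= f
            wall_f_top += f
            wall_virial_z += f * d

    return forces, pair_virial_z, wall_f_bot, wall_f_top, wall_virial_z, err, err_idx


@njit(cache=True)
def run_steps(
    pos,
    vel,
    species,
    mobile,
    bonds,
    bond_model,
    bond_k,
    bond_len,
    a_mat,
    gamma,
    sigma,
    dt,
    lam,
    Lx,
    Ly,
    h,
    aw_bot,
    zc_bot,
    aw_top,
    zc_top,
    seed,
    step0,
    n_steps,
    sample_every,
    include_random,
    store_frames,
):
    """Advance the system ``n_steps`` with the modified velocity-Verlet scheme.

    Positions/velocities are updated in place.  Every ``sample_every`` steps
    the kernel records the instantaneous kinetic temperature, the wall-force
    P_zz on both walls and the virial P_zz, and (optionally) a position
    snapshot.  Returns the sample arrays plus (err, err_idx, n_reflected).
    """
    N = pos.shape[0]
    n_mobile = 0
    for i in range(N):
        if mobile[i]:
            n_mobile += 1
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    area = Lx * Ly
    vol = area * h

    n_samples = n_steps // sample_every if sample_every > 0 else 0
    temps = np.zeros(n_samples)
    p_top = np.zeros(n_samples)
    p_bot = np.zeros(n_samples)
    p_vir = np.zeros(n_samples)
    if store_frames and n_samples > 0:
        frames = np.zeros((n_samples, N, 3))
    else:
        frames = np.zeros((1, 1, 3))

    f, pv, wb, wt, wv, err, err_idx = compute_forces(
        pos, vel, species, bonds, bond_model, bond_k, bond_len,
        a_mat, gamma, sigma, inv_sqrt_dt, Lx, Ly, h,
        aw_bot, zc_bot, aw_top, zc_top, seed, step0, include_random,
    )
    if err != ERR_OK:
        return temps, p_top, p_bot, p_vir, frames, 0, err, err_idx, 0

    vtilde = np.zeros((N, 3))
    n_reflected = 0
    isample = 0
    for s in range(n_steps):
        step = step0 + s + 1
        for i in range(N):
            if not mobile[i]:
                continue
            for k in range(3):
                pos[i, k] += dt * vel[i, k] + 0.5 * dt * dt * f[i, k]
                vtilde[i, k] = vel[i, k] + lam * dt * f[i, k]
            # lateral periodic wrap
            pos[i, 0] -= Lx * np.floor(pos[i, 0] / Lx)
            pos[i, 1] -= Ly * np.floor(pos[i, 1] / Ly)
            # z safety: soft walls normally confine; a runaway bead is
            # reflected elastically and counted
            if pos[i, 2] < 0.0:
                pos[i, 2] = -pos[i, 2]
                vtilde[i, 2] = -vtilde[i, 2]
                vel[i, 2] = -vel[i, 2]
                n_reflected += 1
            elif pos[i, 2] > h:
                pos[i, 2] = 2.0 * h - pos[i, 2]
                vtilde[i, 2] = -vtilde[i, 2]
                vel[i, 2] = -vel[i, 2]
                n_reflected += 1
            if not (
                np.isfinite(pos[i, 0])
                and np.isfinite(pos[i, 1])
                and np.isfinite(pos[i, 2])
            ):
                return temps, p_top, p_bot, p_vir, frames, isample, ERR_NONFINITE, i, n_reflected

        fn, pv, wb, wt, wv, err, err_idx = compute_forces(
            pos, vtilde, species, bonds, bond_model, bond_k, bond_len,
            a_mat, gamma, sigma, inv_sqrt_dt, Lx, Ly, h,
            aw_bot, zc_bot, aw_top, zc_top, seed, step, include_random,
        )
        if err != ERR_OK:
            return temps, p_top, p_bot, p_vir, frames, isample, err, err_idx, n_reflected

        ke2 = 0.0  # sum m v^2 over mobile beads
        kz = 0.0  # sum m v_z^2 over all beads (anchored have v = 0)
        for i in range(N):
            if mobile[i]:
                for k in range(3):
                    vel[i, k] += 0.5 * dt * (f[i, k] + fn[i, k])
                ke2 += (
                    vel[i, 0] * vel[i, 0]
                    + vel[i, 1] * vel[i, 1]
                    + vel[i, 2] * vel[i, 2]
                )
                kz += vel[i, 2] * vel[i, 2]
        f = fn

        if sample_every > 0 and (s + 1) % sample_every == 0:
            temps[isample] = ke2 / (3.0 * n_mobile) if n_mobile > 0 else 0.0
            p_top[isample] = wt / area
            p_bot[isample] = wb / area
            p_vir[isample] = (kz + pv + wv) / vol
            if store_frames:
                for i in range(N):
                    frames[isample, i, 0] = pos[i, 0]
                    frames[isample, i, 1] = pos[i, 1]
                    frames[isample, i, 2] = pos[i, 2]
            isample += 1

    return temps, p_top, p_bot, p_vir, frames, isample, ERR_OK, -1, n_reflected
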