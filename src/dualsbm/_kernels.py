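"""Numba-compiled force kernel and BAOAB chunk integrator.

These kernels implement exactly the same potential as
:mod:`dualsbm.topology` (cross-checked by tests); they exist because the
per-step Python overhead of the vectorised path dominates for the small
systems the Langevin protocol integrates for millions of steps.  When numba
is unavailable the engine falls back to the vectorised path and produces
the same trajectories (the noise stream is generated outside the kernel).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in target env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def energy_forces(coords,
                  bond_idx, bond_r0, k_bond,
                  angle_idx, angle_t0, k_angle,
                  dih_idx, dih_p0, dih_p0b, k_dih,
                  con_idx, con_r0, con_r0b, eps, sigma, r_ex,
                  nn_pairs, eps_nn, r_nn, nn_cutoff,
                  f):
    """Accumulate forces into ``f`` (zeroed here); return per-class energies."""
    n = coords.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    for t in range(bond_idx.shape[0]):
        i, j = bond_idx[t, 0], bond_idx[t, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[t]
        e_bond += 0.5 * k_bond * dr * dr
        g = -k_bond * dr / r
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz

    e_angle = 0.0
    for t in range(angle_idx.shape[0]):
        ia, ja, ka = angle_idx[t, 0], angle_idx[t, 1], angle_idx[t, 2]
        ux = coords[ia, 0] - coords[ja, 0]
        uy = coords[ia, 1] - coords[ja, 1]
        uz = coords[ia, 2] - coords[ja, 2]
        vx = coords[ka, 0] - coords[ja, 0]
        vy = coords[ka, 1] - coords[ja, 1]
        vz = coords[ka, 2] - coords[ja, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dt_ = theta - angle_t0[t]
        e_angle += 0.5 * k_angle * dt_ * dt_
        st = np.sqrt(max(1.0 - ct * ct, 1e-12))
        g = k_angle * dt_
        # d theta / d r_i = (ct*u_hat - v_hat) / (nu * st)
        cix = (ct * ux / nu - vx / nv) / (nu * st)
        ciy = (ct * uy / nu - vy / nv) / (nu * st)
        ciz = (ct * uz / nu - vz / nv) / (nu * st)
        ckx = (ct * vx / nv - ux / nu) / (nv * st)
        cky = (ct * vy / nv - uy / nu) / (nv * st)
        ckz = (ct * vz / nv - uz / nu) / (nv * st)
        f[ia, 0] -= g * cix
        f[ia, 1] -= g * ciy
        f[ia, 2] -= g * ciz
        f[ka, 0] -= g * ckx
        f[ka, 1] -= g * cky
        f[ka, 2] -= g * ckz
        f[ja, 0] += g * (cix + ckx)
        f[ja, 1] += g * (ciy + cky)
        f[ja, 2] += g * (ciz + ckz)

    e_dih = 0.0
    for t in range(dih_idx.shape[0]):
        i0, i1, i2, i3 = (dih_idx[t, 0], dih_idx[t, 1], dih_idx[t, 2],
                          dih_idx[t, 3])
        b1x = coords[i1, 0] - coords[i0, 0]
        b1y = coords[i1, 1] - coords[i0, 1]
        b1z = coords[i1, 2] - coords[i0, 2]
        b2x = coords[i2, 0] - coords[i1, 0]
        b2y = coords[i2, 1] - coords[i1, 1]
        b2z = coords[i2, 2] - coords[i1, 2]
        b3x = coords[i3, 0] - coords[i2, 0]
        b3y = coords[i3, 1] - coords[i2, 1]
        b3z = coords[i3, 2] - coords[i2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phi = np.arctan2(y, x)

        # wrap(phi - p0) into (-pi, pi]
        d_a = phi - dih_p0[t]
        d_a = (d_a + np.pi) % (2.0 * np.pi) - np.pi
        if d_a == -np.pi:
            d_a = np.pi
        v = k_dih * ((1.0 - np.cos(d_a)) + 0.5 * (1.0 - np.cos(3.0 * d_a)))
        dv = k_dih * (np.sin(d_a) + 1.5 * np.sin(3.0 * d_a))
        if not np.isnan(dih_p0b[t]):
            d_b = phi - dih_p0b[t]
            d_b = (d_b + np.pi) % (2.0 * np.pi) - np.pi
            if d_b == -np.pi:
                d_b = np.pi
            vb = k_dih * ((1.0 - np.cos(d_b))
                          + 0.5 * (1.0 - np.cos(3.0 * d_b)))
            dvb = k_dih * (np.sin(d_b) + 1.5 * np.sin(3.0 * d_b))
            v = 0.5 * (v + vb)
            dv = 0.5 * (dv + dvb)
        e_dih += v
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        gi = dv * nb2 / n1sq
        gl = -dv * nb2 / n2sq
        fix = gi * n1x
        fiy = gi * n1y
        fiz = gi * n1z
        flx = gl * n2x
        fly = gl * n2y
        flz = gl * n2z
        s = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tt = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        fjx = (-1.0 - s) * fix + tt * flx
        fjy = (-1.0 - s) * fiy + tt * fly
        fjz = (-1.0 - s) * fiz + tt * flz
        fkx = s * fix - (1.0 + tt) * flx
        fky = s * fiy - (1.0 + tt) * fly
        fkz = s * fiz - (1.0 + tt) * flz
        f[i0, 0] += fix
        f[i0, 1] += fiy
        f[i0, 2] += fiz
        f[i1, 0] += fjx
        f[i1, 1] += fjy
        f[i1, 2] += fjz
        f[i2, 0] += fkx
        f[i2, 1] += fky
        f[i2, 2] += fkz
        f[i3, 0] += flx
        f[i3, 1] += fly
        f[i3, 2] += flz

    e_con = 0.0
    two_sig2 = 2.0 * sigma * sigma
    for t in range(con_idx.shape[0]):
        i, j = con_idx[t, 0], con_idx[t, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ex = (r_ex / r) ** 12
        dex = -12.0 * ex / r
        ga = np.exp(-((r - con_r0[t]) ** 2) / two_sig2)
        dga = ga * (-(r - con_r0[t]) / (sigma * sigma))
        prod = 1.0 - ga
        dprod = -dga
        if not np.isnan(con_r0b[t]):
            gb = np.exp(-((r - con_r0b[t]) ** 2) / two_sig2)
            dgb = gb * (-(r - con_r0b[t]) / (sigma * sigma))
            dprod = -dga * (1.0 - gb) + (1.0 - ga) * (-dgb)
            prod = (1.0 - ga) * (1.0 - gb)
        e_con += eps * ((1.0 + ex) * prod - 1.0)
        dv = eps * (dex * prod + (1.0 + ex) * dprod)
        g = -dv / r
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz

    e_nn = 0.0
    rc2 = nn_cutoff * nn_cutoff
    vshift = eps_nn * (r_nn / nn_cutoff) ** 12
    for t in range(nn_pairs.shape[0]):
        i, j = nn_pairs[t, 0], nn_pairs[t, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        vr = eps_nn * (r_nn / r) ** 12
        e_nn += vr - vshift
        dv = -12.0 * vr / r
        g = -dv / r
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz

    return e_bond, e_angle, e_dih, e_con, e_nn


@njit(cache=True)
def baoab_chunk(coords, vel, forces, noise, dt, c1, c2,
                bond_idx, bond_r0, k_bond,
                angle_idx, angle_t0, k_angle,
                dih_idx, dih_p0, dih_p0b, k_dih,
                con_idx, con_r0, con_r0b, eps, sigma, r_ex,
                nn_pairs, eps_nn, r_nn, nn_cutoff):
    """Advance ``noise.shape[0]`` BAOAB steps in place; returns total E_pot
    of the final configuration."""
    n_steps = noise.shape[0]
    n = coords.shape[0]
    eb = ea = ed = ec = en = 0.0
    for step in range(n_steps):
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            coords[i, 0] += 0.5 * dt * vel[i, 0]
            coords[i, 1] += 0.5 * dt * vel[i, 1]
            coords[i, 2] += 0.5 * dt * vel[i, 2]
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
            coords[i, 0] += 0.5 * dt * vel[i, 0]
            coords[i, 1] += 0.5 * dt * vel[i, 1]
            coords[i, 2] += 0.5 * dt * vel[i, 2]
        eb, ea, ed, ec, en = energy_forces(
            coords, bond_idx, bond_r0, k_bond, angle_idx, angle_t0, k_angle,
            dih_idx, dih_p0, dih_p0b, k_dih, con_idx, con_r0, con_r0b,
            eps, sigma, r_ex, nn_pairs, eps_nn, r_nn, nn_cutoff, forces)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
    return eb + ea + ed + ec + en
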