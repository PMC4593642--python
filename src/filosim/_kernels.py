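"""Numba kernels: force assembly, energy, FIRE relaxation and the adaptive
overdamped integrator.

All kernels operate on flat float64/int32 arrays in the package unit system
(μm, pN, s).  The force model mirrors the module-level numpy implementations;
a consistency test cross-checks the two.

Bend angles use θ = atan2(|û×v̂|, û·v̂) between consecutive tangent vectors,
which is numerically stable near collinearity; the near-singular factor
(θ − θ0)/sin θ is series-guarded so straight rest states (θ0 = 0), the
generator's common case, produce finite restoring forces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_SIN = 1e-8


@njit(cache=True, fastmath=True)
def _bend_accumulate(pos, F, a, b, c, kb, th0):
    ux = pos[b, 0] - pos[a, 0]
    uy = pos[b, 1] - pos[a, 1]
    uz = pos[b, 2] - pos[a, 2]
    vx = pos[c, 0] - pos[b, 0]
    vy = pos[c, 1] - pos[b, 1]
    vz = pos[c, 2] - pos[b, 2]
    lu = np.sqrt(ux * ux + uy * uy + uz * uz)
    lv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if lu < 1e-12 or lv < 1e-12:
        return
    ux /= lu
    uy /= lu
    uz /= lu
    vx /= lv
    vy /= lv
    vz /= lv
    cth = ux * vx + uy * vy + uz * vz
    if cth > 1.0:
        cth = 1.0
    elif cth < -1.0:
        cth = -1.0
    # |u x v|
    wx = uy * vz - uz * vy
    wy = uz * vx - ux * vz
    wz = ux * vy - uy * vx
    sth = np.sqrt(wx * wx + wy * wy + wz * wz)
    th = np.arctan2(sth, cth)
    dth = th - th0
    if sth < _EPS_SIN:
        if abs(th0) < 1e-12:
            g = 1.0  # lim (θ-0)/sinθ as θ→0
        else:
            g = dth / _EPS_SIN
    else:
        g = dth / sth
    coef = kb * g
    # F_a = -coef * (v̂ - cθ û)/lu ; F_c = -coef * (cθ v̂ - û)/lv
    fax = -coef * (vx - cth * ux) / lu
    fay = -coef * (vy - cth * uy) / lu
    faz = -coef * (vz - cth * uz) / lu
    fcx = -coef * (cth * vx - ux) / lv
    fcy = -coef * (cth * vy - uy) / lv
    fcz = -coef * (cth * vz - uz) / lv
    F[a, 0] += fax
    F[a, 1] += fay
    F[a, 2] += faz
    F[c, 0] += fcx
    F[c, 1] += fcy
    F[c, 2] += fcz
    F[b, 0] -= fax + fcx
    F[b, 1] -= fay + fcy
    F[b, 2] -= faz + fcz


@njit(cache=True, fastmath=True)
def network_forces(pos, F, seg_i, seg_j, seg_klin, seg_L0, seg_active,
                   tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active):
    """Stretch + bend forces of the fiber network, accumulated into F."""
    for m in range(seg_i.shape[0]):
        if not seg_active[m]:
            continue
        i = seg_i[m]
        j = seg_j[m]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-12:
            continue
        f = seg_klin[m] * (L - seg_L0[m]) / L
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
    for m in range(tri_a.shape[0]):
        if not tri_active[m]:
            continue
        _bend_accumulate(pos, F, tri_a[m], tri_b[m], tri_c[m], tri_kb[m], tri_th0[m])


@njit(cache=True)
def network_energy(pos, seg_i, seg_j, seg_ks, seg_L0, seg_active,
                   tri_a, tri_b, tri_c, tri_kb2, tri_th0, tri_active):
    """Σ κ_s/2 (L−L0)²/L0 + Σ κ_b/2 (θ−θ0)²/L0.

    ``seg_ks`` is the stretching modulus κ_s (pN) per segment and ``tri_kb2``
    is κ_b/L0 (pN·μm) per bend triple.
    """
    E = 0.0
    for m in range(seg_i.shape[0]):
        if not seg_active[m]:
            continue
        i = seg_i[m]
        j = seg_j[m]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        dL = L - seg_L0[m]
        E += 0.5 * seg_ks[m] * dL * dL / seg_L0[m]
    for m in range(tri_a.shape[0]):
        if not tri_active[m]:
            continue
        a = tri_a[m]
        b = tri_b[m]
        c = tri_c[m]
        ux = pos[b, 0] - pos[a, 0]
        uy = pos[b, 1] - pos[a, 1]
        uz = pos[b, 2] - pos[a, 2]
        vx = pos[c, 0] - pos[b, 0]
        vy = pos[c, 1] - pos[b, 1]
        vz = pos[c, 2] - pos[b, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        cth = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        wx = (uy * vz - uz * vy) / (lu * lv)
        wy = (uz * vx - ux * vz) / (lu * lv)
        wz = (ux * vy - uy * vx) / (lu * lv)
        sth = np.sqrt(wx * wx + wy * wy + wz * wz)
        th = np.arctan2(sth, cth)
        dth = th - tri_th0[m]
        E += 0.5 * tri_kb2[m] * dth * dth
    return E


@njit(cache=True, fastmath=True)
def assemble_forces(pos, F,
                    seg_i, seg_j, seg_klin, seg_L0, seg_active,
                    tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active,
                    spr_a, spr_b, spr_k, spr_L0,
                    psp_node, psp_na, psp_nb, psp_s, psp_k, psp_rest,
                    ext_node, ext_F,
                    con_node, con_na, con_nb, con_range, con_k):
    """Full force assembly: network + generic springs + point-on-segment bond
    clusters (FC/FA) + constant external forces + contact repulsion."""
    F[:, :] = 0.0
    network_forces(pos, F, seg_i, seg_j, seg_klin, seg_L0, seg_active,
                   tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active)
    for m in range(spr_a.shape[0]):
        i = spr_a[m]
        j = spr_b[m]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-12:
            continue
        f = spr_k[m] * (L - spr_L0[m]) / L
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
    for m in range(psp_node.shape[0]):
        n = psp_node[m]
        ia = psp_na[m]
        ib = psp_nb[m]
        s = psp_s[m]
        ax = pos[ia, 0] * (1.0 - s) + pos[ib, 0] * s
        ay = pos[ia, 1] * (1.0 - s) + pos[ib, 1] * s
        az = pos[ia, 2] * (1.0 - s) + pos[ib, 2] * s
        dx = ax - pos[n, 0]
        dy = ay - pos[n, 1]
        dz = az - pos[n, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-12:
            continue
        f = psp_k[m] * (L - psp_rest[m]) / L
        fx = f * dx
        fy = f * dy
        fz = f * dz
        F[n, 0] += fx
        F[n, 1] += fy
        F[n, 2] += fz
        F[ia, 0] -= fx * (1.0 - s)
        F[ia, 1] -= fy * (1.0 - s)
        F[ia, 2] -= fz * (1.0 - s)
        F[ib, 0] -= fx * s
        F[ib, 1] -= fy * s
        F[ib, 2] -= fz * s
    for m in range(ext_node.shape[0]):
        n = ext_node[m]
        F[n, 0] += ext_F[m, 0]
        F[n, 1] += ext_F[m, 1]
        F[n, 2] += ext_F[m, 2]
    for m in range(con_node.shape[0]):
        n = con_node[m]
        ia = con_na[m]
        ib = con_nb[m]
        ex = pos[ib, 0] - pos[ia, 0]
        ey = pos[ib, 1] - pos[ia, 1]
        ez = pos[ib, 2] - pos[ia, 2]
        ee = ex * ex + ey * ey + ez * ez
        px = pos[n, 0] - pos[ia, 0]
        py = pos[n, 1] - pos[ia, 1]
        pz = pos[n, 2] - pos[ia, 2]
        if ee < 1e-18:
            t = 0.0
        else:
            t = (px * ex + py * ey + pz * ez) / ee
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
        dx = px - t * ex
        dy = py - t * ey
        dz = pz - t * ez
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        r = con_range[m]
        if dist >= r or dist < 1e-12:
            continue
        f = con_k[m] * (r - dist) / dist
        fx = f * dx
        fy = f * dy
        fz = f * dz
        F[n, 0] += fx
        F[n, 1] += fy
        F[n, 2] += fz
        F[ia, 0] -= fx * (1.0 - t)
        F[ia, 1] -= fy * (1.0 - t)
        F[ia, 2] -= fz * (1.0 - t)
        F[ib, 0] -= fx * t
        F[ib, 1] -= fy * t
        F[ib, 2] -= fz * t


@njit(cache=True, fastmath=True)
def _velocities(F, V, drag, immobile, stiff, dt, pair_a, pair_b, c_c, c_t, c_x):
    """Overdamped rates with per-node linearized implicit damping.

    v = F / max(C, dt·k_local), where k_local is the summed stiffness of the
    interactions touching the node.  Below the overdamped stability limit
    (dt·k < C) this is the exact mobility, so the embedded pair keeps its
    second-order accuracy; beyond it the node relaxes dead-beat toward its
    local equilibrium instead of oscillating (the spring-limited step
    dt·v = F/k).  Equilibria and forces are untouched.  Kelvin–Voigt coupled
    membrane/transduce pairs solve their per-node 2×2 system with the same
    limited drags; ``immobile`` nodes do not move.
    """
    for i in range(F.shape[0]):
        if immobile[i]:
            V[i, 0] = 0.0
            V[i, 1] = 0.0
            V[i, 2] = 0.0
        else:
            d_eff = dt * stiff[i]
            if d_eff < drag[i]:
                d_eff = drag[i]
            inv = 1.0 / d_eff
            V[i, 0] = F[i, 0] * inv
            V[i, 1] = F[i, 1] * inv
            V[i, 2] = F[i, 2] * inv
    for p in range(pair_a.shape[0]):
        a = pair_a[p]
        b = pair_b[p]
        if immobile[a] or immobile[b]:
            continue
        da = dt * stiff[a]
        if da < c_c:
            da = c_c
        db = dt * stiff[b]
        if db < c_t:
            db = c_t
        aa = da + c_x
        bb = db + c_x
        det = aa * bb - c_x * c_x
        m11 = bb / det
        m12 = c_x / det
        m22 = aa / det
        for d in range(3):
            fa = F[a, d]
            fb = F[b, d]
            V[a, d] = m11 * fa + m12 * fb
            V[b, d] = m12 * fa + m22 * fb


@njit(cache=True, fastmath=True)
def integrate_batch(pos, t_batch, dt_start, tol, dt_min, dt_max,
                    drag, immobile, stiff, pair_a, pair_b, c_c, c_t, c_x,
                    seg_i, seg_j, seg_klin, seg_L0, seg_active,
                    tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active,
                    spr_a, spr_b, spr_k, spr_L0,
                    psp_node, psp_na, psp_nb, psp_s, psp_k, psp_rest,
                    ext_node, ext_F,
                    con_node, con_na, con_nb, con_range, con_k):
    """Advance the overdamped system by ``t_batch`` with an adaptive embedded
    Euler/Heun pair (local error = ‖y_Heun − y_Euler‖_∞ per step).

    Steps are clamped to [dt_min, dt_max]; a step at dt_min is accepted even
    above tolerance (counted in the returned diagnostics) so the simulation
    cannot stall.  Returns (dt_next, n_accepted, n_rejected, n_forced).
    """
    n = pos.shape[0]
    F1 = np.empty((n, 3))
    F2 = np.empty((n, 3))
    V1 = np.empty((n, 3))
    V2 = np.empty((n, 3))
    ye = np.empty((n, 3))
    t = 0.0
    dt = min(max(dt_start, dt_min), dt_max)
    n_acc = 0
    n_rej = 0
    n_forced = 0
    while t < t_batch - 1e-12:
        if dt > t_batch - t:
            dt = t_batch - t
        assemble_forces(pos, F1,
                        seg_i, seg_j, seg_klin, seg_L0, seg_active,
                        tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active,
                        spr_a, spr_b, spr_k, spr_L0,
                        psp_node, psp_na, psp_nb, psp_s, psp_k, psp_rest,
                        ext_node, ext_F,
                        con_node, con_na, con_nb, con_range, con_k)
        _velocities(F1, V1, drag, immobile, stiff, dt, pair_a, pair_b, c_c, c_t, c_x)
        for i in range(n):
            ye[i, 0] = pos[i, 0] + dt * V1[i, 0]
            ye[i, 1] = pos[i, 1] + dt * V1[i, 1]
            ye[i, 2] = pos[i, 2] + dt * V1[i, 2]
        assemble_forces(ye, F2,
                        seg_i, seg_j, seg_klin, seg_L0, seg_active,
                        tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active,
                        spr_a, spr_b, spr_k, spr_L0,
                        psp_node, psp_na, psp_nb, psp_s, psp_k, psp_rest,
                        ext_node, ext_F,
                        con_node, con_na, con_nb, con_range, con_k)
        _velocities(F2, V2, drag, immobile, stiff, dt, pair_a, pair_b, c_c, c_t, c_x)
        # RMS local-error norm over mobile nodes: a handful of stiff,
        # implicitly-damped nodes must not throttle the global step
        err2 = 0.0
        n_mob = 0
        for i in range(n):
            if immobile[i]:
                continue
            n_mob += 1
            for d in range(3):
                e = 0.5 * dt * (V2[i, d] - V1[i, d])
                err2 += e * e
        err = np.sqrt(err2 / (3.0 * n_mob)) if n_mob > 0 else 0.0
        at_floor = dt <= dt_min * 1.000001
        if err <= tol or at_floor:
            if err > tol:
                n_forced += 1
            for i in range(n):
                pos[i, 0] += 0.5 * dt * (V1[i, 0] + V2[i, 0])
                pos[i, 1] += 0.5 * dt * (V1[i, 1] + V2[i, 1])
                pos[i, 2] += 0.5 * dt * (V1[i, 2] + V2[i, 2])
            t += dt
            n_acc += 1
            if err > 1e-300:
                fac = 0.8 * np.sqrt(tol / err)
            else:
                fac = 1.5
            if fac > 1.5:
                fac = 1.5
            elif fac < 0.2:
                fac = 0.2
            dt *= fac
        else:
            n_rej += 1
            fac = 0.8 * np.sqrt(tol / err)
            if fac < 0.1:
                fac = 0.1
            dt *= fac
        if dt < dt_min:
            dt = dt_min
        elif dt > dt_max:
            dt = dt_max
    return dt, n_acc, n_rej, n_forced


@njit(cache=True)
def fire_relax(pos, free, f_tol, dt_start, dt_cap, max_steps,
               seg_i, seg_j, seg_klin, seg_L0, seg_active,
               tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active):
    """FIRE energy minimization of the network with frozen boundary nodes.

    Returns (residual max |F| over free nodes, number of steps taken).
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    v = np.zeros((n, 3))
    dt = dt_start
    alpha = 0.1
    n_pos = 0
    for step in range(max_steps):
        F[:, :] = 0.0
        network_forces(pos, F, seg_i, seg_j, seg_klin, seg_L0, seg_active,
                       tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active)
        fmax = 0.0
        P = 0.0
        vnorm = 0.0
        fnorm = 0.0
        for i in range(n):
            if not free[i]:
                continue
            fm = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2)
            if fm > fmax:
                fmax = fm
            P += F[i, 0] * v[i, 0] + F[i, 1] * v[i, 1] + F[i, 2] * v[i, 2]
            vnorm += v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            fnorm += fm * fm
        if fmax < f_tol:
            return fmax, step
        if P > 0.0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_cap)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            for i in range(n):
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                v[i, 2] = 0.0
        vnorm = np.sqrt(vnorm)
        fnorm = np.sqrt(fnorm)
        for i in range(n):
            if not free[i]:
                continue
            v[i, 0] += dt * F[i, 0]
            v[i, 1] += dt * F[i, 1]
            v[i, 2] += dt * F[i, 2]
        if fnorm > 1e-300:
            mix = alpha * vnorm / fnorm
            for i in range(n):
                if not free[i]:
                    continue
                v[i, 0] = (1.0 - alpha) * v[i, 0] + mix * F[i, 0]
                v[i, 1] = (1.0 - alpha) * v[i, 1] + mix * F[i, 1]
                v[i, 2] = (1.0 - alpha) * v[i, 2] + mix * F[i, 2]
        for i in range(n):
            if not free[i]:
                continue
            pos[i, 0] += dt * v[i, 0]
            pos[i, 1] += dt * v[i, 1]
            pos[i, 2] += dt * v[i, 2]
    # residual after exhausting the step budget
    F[:, :] = 0.0
    network_forces(pos, F, seg_i, seg_j, seg_klin, seg_L0, seg_active,
                   tri_a, tri_b, tri_c, tri_kb, tri_th0, tri_active)
    fmax = 0.0
    for i in range(n):
        if not free[i]:
            continue
        fm = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2)
        if fm > fmax:
            fmax = fm
    return fmax, max_steps
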