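"""Numba force and Langevin-integration kernels.

All bonded terms beyond the harmonic bonds are tabulated (cubic Hermite on
uniform grids, degrees); the XGG penalty is analytic.  Nonbonded terms act
on midpoint virtual sites whose forces are redistributed half-and-half to
the two parent beads.  The integrator is BAOAB Langevin splitting; what the
model relies on is equilibrium configurational sampling, for which BAOAB
has small and well-characterized timestep bias.
"""

import numpy as np
from numba import njit

DEG = 180.0 / np.pi


@njit(cache=False)
def _tab_eval(x, t, tx0, tdx, tn, toff, tE, tS, tper):
    """Energy and dV/dx of table t at coordinate x (grid units, degrees)."""
    x0 = tx0[t]
    dx = tdx[t]
    n = tn[t]
    off = toff[t]
    span = (n - 1) * dx
    if tper[t] == 1:
        x = x - span * np.floor((x - x0) / span)
        x = x0 + (x - x0) % span
    u = (x - x0) / dx
    i = int(np.floor(u))
    if i < 0:
        s = tS[off]
        return tE[off] + s * (x - x0), s
    if i >= n - 1:
        s = tS[off + n - 1]
        return tE[off + n - 1] + s * (x - (x0 + span)), s
    tt = u - i
    y0 = tE[off + i]
    y1 = tE[off + i + 1]
    m0 = tS[off + i] * dx
    m1 = tS[off + i + 1] * dx
    h00 = (1.0 + 2.0 * tt) * (1.0 - tt) ** 2
    h10 = tt * (1.0 - tt) ** 2
    h01 = tt * tt * (3.0 - 2.0 * tt)
    h11 = tt * tt * (tt - 1.0)
    e = h00 * y0 + h10 * m0 + h01 * y1 + h11 * m1
    de = (6.0 * tt * (tt - 1.0) * (y0 - y1) / dx
          + (3.0 * tt * tt - 4.0 * tt + 1.0) * tS[off + i]
          + (3.0 * tt * tt - 2.0 * tt) * tS[off + i + 1])
    return e, de


@njit(cache=False)
def _forces(pos, f,
            bond_ij, bond_r0, bond_k,
            ang_ijk, ang_t,
            dih_ijkl, dih_t,
            pen_ijk, pen_a, pen_b,
            tx0, tdx, tn, toff, tE, tS, tper,
            vs_ab, vs_q, vs_sig,
            nb_on, excl_adj, dh_pref, kappa, r_dh_cut, wca_eps):
    """Accumulate forces into f (zeroed here); returns total energy (kJ/mol)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0

    # harmonic bonds
    for m in range(bond_ij.shape[0]):
        i = bond_ij[m, 0]
        j = bond_ij[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[m]
        energy += 0.5 * bond_k[m] * dr * dr
        if r > 1e-12:
            fac = -bond_k[m] * dr / r
            f[i, 0] -= fac * dx
            f[i, 1] -= fac * dy
            f[i, 2] -= fac * dz
            f[j, 0] += fac * dx
            f[j, 1] += fac * dy
            f[j, 2] += fac * dz

    # tabulated bending angles
    for m in range(ang_ijk.shape[0]):
        i = ang_ijk[m, 0]
        j = ang_ijk[m, 1]
        k = ang_ijk[m, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        e, dedx = _tab_eval(theta * DEG, ang_t[m], tx0, tdx, tn, toff, tE, tS, tper)
        energy += e
        dvdth = dedx * DEG  # kJ/mol per radian
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        coef = dvdth / st
        # grad_i theta = -(v/(nu*nv) - ct*u/nu^2)/st
        gix = coef * (vx / (nu * nv) - ct * ux / (nu * nu))
        giy = coef * (vy / (nu * nv) - ct * uy / (nu * nu))
        giz = coef * (vz / (nu * nv) - ct * uz / (nu * nu))
        gkx = coef * (ux / (nu * nv) - ct * vx / (nv * nv))
        gky = coef * (uy / (nu * nv) - ct * vy / (nv * nv))
        gkz = coef * (uz / (nu * nv) - ct * vz / (nv * nv))
        f[i, 0] += gix
        f[i, 1] += giy
        f[i, 2] += giz
        f[k, 0] += gkx
        f[k, 1] += gky
        f[k, 2] += gkz
        f[j, 0] -= gix + gkx
        f[j, 1] -= giy + gky
        f[j, 2] -= giz + gkz

    # XGG penalty angles: V = a b^2 / ((pi-theta)^2 - b^2), theta < pi - b
    for m in range(pen_ijk.shape[0]):
        i = pen_ijk[m, 0]
        j = pen_ijk[m, 1]
        k = pen_ijk[m, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        s = np.pi - theta
        s_min = pen_b * 1.02  # C1 linear continuation behind the pole
        if s > s_min:
            g = s * s - pen_b * pen_b
            e = pen_a * pen_b * pen_b / g
            dvdth = 2.0 * pen_a * pen_b * pen_b * s / (g * g)
        else:
            g0 = s_min * s_min - pen_b * pen_b
            e0 = pen_a * pen_b * pen_b / g0
            slope = 2.0 * pen_a * pen_b * pen_b * s_min / (g0 * g0)
            e = e0 + slope * (s_min - s)
            dvdth = slope
        energy += e
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        coef = dvdth / st
        gix = coef * (vx / (nu * nv) - ct * ux / (nu * nu))
        giy = coef * (vy / (nu * nv) - ct * uy / (nu * nu))
        giz = coef * (vz / (nu * nv) - ct * uz / (nu * nu))
        gkx = coef * (ux / (nu * nv) - ct * vx / (nv * nv))
        gky = coef * (uy / (nu * nv) - ct * vy / (nv * nv))
        gkz = coef * (uz / (nu * nv) - ct * vz / (nv * nv))
        f[i, 0] += gix
        f[i, 1] += giy
        f[i, 2] += giz
        f[k, 0] += gkx
        f[k, 1] += gky
        f[k, 2] += gkz
        f[j, 0] -= gix + gkx
        f[j, 1] -= giy + gky
        f[j, 2] -= giz + gkz

    # tabulated dihedrals (including the non-consecutive GXGG coupling term)
    for m in range(dih_ijkl.shape[0]):
        i = dih_ijkl[m, 0]
        j = dih_ijkl[m, 1]
        k = dih_ijkl[m, 2]
        l = dih_ijkl[m, 3]
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
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12:
            n1sq = 1e-12
        if n2sq < 1e-12:
            n2sq = 1e-12
        # phi = atan2((n1 x b2hat).n2, n1.n2)
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        xv = n1x * n2x + n1y * n2y + n1z * n2z
        yv = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(yv, xv)
        e, dedx = _tab_eval(phi * DEG, dih_t[m], tx0, tdx, tn, toff, tE, tS, tper)
        energy += e
        dvdphi = dedx * DEG
        # dihedral gradient dphi/dr (validated against finite differences)
        gix = nb2 / n1sq * n1x
        giy = nb2 / n1sq * n1y
        giz = nb2 / n1sq * n1z
        glx = -nb2 / n2sq * n2x
        gly = -nb2 / n2sq * n2y
        glz = -nb2 / n2sq * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gjx = -(1.0 + d12) * gix + d32 * glx
        gjy = -(1.0 + d12) * giy + d32 * gly
        gjz = -(1.0 + d12) * giz + d32 * glz
        gkx = d12 * gix - (1.0 + d32) * glx
        gky = d12 * giy - (1.0 + d32) * gly
        gkz = d12 * giz - (1.0 + d32) * glz
        f[i, 0] -= dvdphi * gix
        f[i, 1] -= dvdphi * giy
        f[i, 2] -= dvdphi * giz
        f[j, 0] -= dvdphi * gjx
        f[j, 1] -= dvdphi * gjy
        f[j, 2] -= dvdphi * gjz
        f[k, 0] -= dvdphi * gkx
        f[k, 1] -= dvdphi * gky
        f[k, 2] -= dvdphi * gkz
        f[l, 0] -= dvdphi * glx
        f[l, 1] -= dvdphi * gly
        f[l, 2] -= dvdphi * glz

    # nonbonded on virtual sites (Debye-Hueckel + WCA), half/half to parents
    if nb_on:
        nv_ = vs_ab.shape[0]
        for a in range(nv_):
            ia = vs_ab[a, 0]
            ja = vs_ab[a, 1]
            sax = 0.5 * (pos[ia, 0] + pos[ja, 0])
            say = 0.5 * (pos[ia, 1] + pos[ja, 1])
            saz = 0.5 * (pos[ia, 2] + pos[ja, 2])
            for b in range(a + 1, nv_):
                if excl_adj and b == a + 1:
                    continue
                ib = vs_ab[b, 0]
                jb = vs_ab[b, 1]
                sbx = 0.5 * (pos[ib, 0] + pos[jb, 0])
                sby = 0.5 * (pos[ib, 1] + pos[jb, 1])
                sbz = 0.5 * (pos[ib, 2] + pos[jb, 2])
                dx = sbx - sax
                dy = sby - say
                dz = sbz - saz
                r2 = dx * dx + dy * dy + dz * dz
                sig = 0.5 * (vs_sig[a] + vs_sig[b])
                rc_wca = 1.122462048309373 * sig
                qq = vs_q[a] * vs_q[b]
                rc = rc_wca
                if qq != 0.0 and r_dh_cut > rc:
                    rc = r_dh_cut
                if r2 >= rc * rc or r2 < 1e-16:
                    continue
                r = np.sqrt(r2)
                fmag = 0.0  # dV/dr
                if qq != 0.0 and r < r_dh_cut:
                    vdh = dh_pref * qq / r * np.exp(-kappa * r)
                    energy += vdh
                    fmag += -vdh * (1.0 / r + kappa)
                if r < rc_wca:
                    sr6 = (sig / r) ** 6
                    energy += 4.0 * wca_eps * (sr6 * sr6 - sr6) + wca_eps
                    fmag += -24.0 * wca_eps * (2.0 * sr6 * sr6 - sr6) / r
                # force on site b along +d is -dV/dr * dhat
                fbx = -fmag * dx / r
                fby = -fmag * dy / r
                fbz = -fmag * dz / r
                f[ib, 0] += 0.5 * fbx
                f[ib, 1] += 0.5 * fby
                f[ib, 2] += 0.5 * fbz
                f[jb, 0] += 0.5 * fbx
                f[jb, 1] += 0.5 * fby
                f[jb, 2] += 0.5 * fbz
                f[ia, 0] -= 0.5 * fbx
                f[ia, 1] -= 0.5 * fby
                f[ia, 2] -= 0.5 * fbz
                f[ja, 0] -= 0.5 * fbx
                f[ja, 1] -= 0.5 * fby
                f[ja, 2] -= 0.5 * fbz
    return energy


@njit(cache=False)
def _integrate(pos, masses, dt, friction, kt, n_steps, record_every, seed,
               bond_ij, bond_r0, bond_k,
               ang_ijk, ang_t,
               dih_ijkl, dih_t,
               pen_ijk, pen_a, pen_b,
               tx0, tdx, tn, toff, tE, tS, tper,
               vs_ab, vs_q, vs_sig,
               nb_on, excl_adj, dh_pref, kappa, r_dh_cut, wca_eps,
               frames, kin_out):
    """BAOAB Langevin dynamics.  dt in ps, friction in ps^-1, kt in kJ/mol.

    Fills ``frames`` (preallocated (n_frames, n, 3)) every ``record_every``
    steps, recording frame 0 as the initial state.  Returns (status,
    max_pen_theta, max_disp): status is -1 on success or the step index at
    which coordinates became non-finite; max_pen_theta is the largest
    penalty-angle value encountered at any integration step (radians).
    """
    n = pos.shape[0]
    np.random.seed(seed)
    x = pos.copy()
    v = np.zeros((n, 3))
    # Maxwell-Boltzmann start
    for i in range(n):
        sd = np.sqrt(kt / masses[i])
        for d in range(3):
            v[i, d] = sd * np.random.normal(0.0, 1.0)
    f = np.zeros((n, 3))
    _forces(x, f, bond_ij, bond_r0, bond_k, ang_ijk, ang_t, dih_ijkl, dih_t,
            pen_ijk, pen_a, pen_b, tx0, tdx, tn, toff, tE, tS, tper,
            vs_ab, vs_q, vs_sig, nb_on, excl_adj, dh_pref, kappa, r_dh_cut, wca_eps)
    a_o = np.exp(-friction * dt)
    frames[0] = x
    frame = 1
    max_pen = 0.0
    max_disp = 0.0
    kin_sum = 0.0
    kin_n = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            hdtm = 0.5 * dt / masses[i]
            for d in range(3):
                v[i, d] += hdtm * f[i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        for i in range(n):
            sd = np.sqrt(kt / masses[i] * (1.0 - a_o * a_o))
            for d in range(3):
                v[i, d] = a_o * v[i, d] + sd * np.random.normal(0.0, 1.0)
                x[i, d] += 0.5 * dt * v[i, d]
        _forces(x, f, bond_ij, bond_r0, bond_k, ang_ijk, ang_t, dih_ijkl, dih_t,
                pen_ijk, pen_a, pen_b, tx0, tdx, tn, toff, tE, tS, tper,
                vs_ab, vs_q, vs_sig, nb_on, excl_adj, dh_pref, kappa, r_dh_cut, wca_eps)
        md = 0.0
        for i in range(n):
            hdtm = 0.5 * dt / masses[i]
            for d in range(3):
                v[i, d] += hdtm * f[i, d]
                dd = np.abs(dt * v[i, d])
                if dd > md:
                    md = dd
        if md > max_disp:
            max_disp = md
        # track the largest penalty angle ever visited
        for m in range(pen_ijk.shape[0]):
            i = pen_ijk[m, 0]
            j = pen_ijk[m, 1]
            k = pen_ijk[m, 2]
            ux = x[i, 0] - x[j, 0]
            uy = x[i, 1] - x[j, 1]
            uz = x[i, 2] - x[j, 2]
            vx = x[k, 0] - x[j, 0]
            vy = x[k, 1] - x[j, 1]
            vz = x[k, 2] - x[j, 2]
            ct = ((ux * vx + uy * vy + uz * vz)
                  / (np.sqrt(ux * ux + uy * uy + uz * uz)
                     * np.sqrt(vx * vx + vy * vy + vz * vz)))
            if ct > 1.0:
                ct = 1.0
            if ct < -1.0:
                ct = -1.0
            th = np.arccos(ct)
            if th > max_pen:
                max_pen = th
        if step % record_every == 0:
            ok = True
            for i in range(n):
                for d in range(3):
                    if not np.isfinite(x[i, d]) or np.abs(x[i, d]) > 1e6:
                        ok = False
            if not ok:
                return step, max_pen, max_disp, frame
            if frame < frames.shape[0]:
                frames[frame] = x
                frame += 1
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
            kin_sum += ke
            kin_n += 1
    kin_out[0] = kin_sum / max(kin_n, 1)
    return -1, max_pen, max_disp, frame
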