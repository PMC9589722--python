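"""Numba-compiled energy/force kernels.

All kernels accumulate forces in-place and return energies.  The main entry
point :func:`ff_energy_forces` evaluates the complete coarse-grained force
field for one configuration, including the per-interface double-basin mixing
(eigenvalue form of the two-state secular problem).

Energy component layout returned by :func:`ff_energy_forces`::

    0  bonded (bonds + angles + dihedrals, protein and rigid-ligand)
    1  shared single-basin contacts (intra-domain protein)
    2  mixed LID-CORE interface
    3  mixed NMP-CORE interface
    4  mixed LID-NMP interface
    5  protein-ligand native contacts (12-10)
    6  protein-ligand non-native Gaussian wells
    7  excluded volume
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _bonds(coords, bi, bj, br0, bk, F):
    e = 0.0
    for n in range(bi.shape[0]):
        i, j = bi[n], bj[n]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[n]
        e += 0.5 * bk[n] * dr * dr
        if r > 1e-12:
            c = bk[n] * dr / r
            F[i, 0] -= c * dx
            F[i, 1] -= c * dy
            F[i, 2] -= c * dz
            F[j, 0] += c * dx
            F[j, 1] += c * dy
            F[j, 2] += c * dz
    return e


@njit(cache=True, fastmath=True)
def _angles(coords, ai, aj, ak, at0, akk, agrp, F, Fg, egrp):
    e = 0.0
    for n in range(ai.shape[0]):
        i, j, k = ai[n], aj[n], ak[n]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        dth = theta - at0[n]
        ev = 0.5 * akk[n] * dth * dth
        g = akk[n] * dth  # dE/dtheta
        # dtheta/dri = (ct*u_hat - v_hat) / (nu*st), analogous for rk
        cix = (ct * ux / nu - vx / nv) / (nu * st)
        ciy = (ct * uy / nu - vy / nv) / (nu * st)
        ciz = (ct * uz / nu - vz / nv) / (nu * st)
        ckx = (ct * vx / nv - ux / nu) / (nv * st)
        cky = (ct * vy / nv - uy / nu) / (nv * st)
        ckz = (ct * vz / nv - uz / nu) / (nv * st)
        grp = agrp[n]
        if grp == 0:
            e += ev
            F[i, 0] -= g * cix
            F[i, 1] -= g * ciy
            F[i, 2] -= g * ciz
            F[k, 0] -= g * ckx
            F[k, 1] -= g * cky
            F[k, 2] -= g * ckz
            F[j, 0] += g * (cix + ckx)
            F[j, 1] += g * (ciy + cky)
            F[j, 2] += g * (ciz + ckz)
        else:
            egrp[grp - 1] += ev
            Fg[grp - 1, i, 0] -= g * cix
            Fg[grp - 1, i, 1] -= g * ciy
            Fg[grp - 1, i, 2] -= g * ciz
            Fg[grp - 1, k, 0] -= g * ckx
            Fg[grp - 1, k, 1] -= g * cky
            Fg[grp - 1, k, 2] -= g * ckz
            Fg[grp - 1, j, 0] += g * (cix + ckx)
            Fg[grp - 1, j, 1] += g * (ciy + cky)
            Fg[grp - 1, j, 2] += g * (ciz + ckz)
    return e


@njit(cache=True, fastmath=True)
def _dihedrals(coords, di, dj, dk, dl, dp0, dkk, dgrp, F, Fg, egrp):
    e = 0.0
    for n in range(di.shape[0]):
        i, j, k, l = di[n], dj[n], dk[n], dl[n]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # m1 = n1 x b2_hat
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(y, x)
        ev = dkk[n] * (1.0 - np.cos(phi - dp0[n]))
        g = dkk[n] * np.sin(phi - dp0[n])  # dE/dphi
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # dphi/dri = (|b2|/|n1|^2) n1 ; dphi/drl = -(|b2|/|n2|^2) n2
        pix = (nb2 / n1sq) * n1x
        piy = (nb2 / n1sq) * n1y
        piz = (nb2 / n1sq) * n1z
        qlx = -(nb2 / n2sq) * n2x
        qly = -(nb2 / n2sq) * n2y
        qlz = -(nb2 / n2sq) * n2z
        sv = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        sw = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        # interior beads: dphi/drj = -(1+sv) p + sw q ; dphi/drk = sv p - (1+sw) q
        pjx = -(1.0 + sv) * pix + sw * qlx
        pjy = -(1.0 + sv) * piy + sw * qly
        pjz = -(1.0 + sv) * piz + sw * qlz
        pkx = sv * pix - (1.0 + sw) * qlx
        pky = sv * piy - (1.0 + sw) * qly
        pkz = sv * piz - (1.0 + sw) * qlz
        grp = dgrp[n]
        if grp == 0:
            e += ev
            F[i, 0] -= g * pix
            F[i, 1] -= g * piy
            F[i, 2] -= g * piz
            F[j, 0] -= g * pjx
            F[j, 1] -= g * pjy
            F[j, 2] -= g * pjz
            F[k, 0] -= g * pkx
            F[k, 1] -= g * pky
            F[k, 2] -= g * pkz
            F[l, 0] -= g * qlx
            F[l, 1] -= g * qly
            F[l, 2] -= g * qlz
        else:
            egrp[grp - 1] += ev
            Fg[grp - 1, i, 0] -= g * pix
            Fg[grp - 1, i, 1] -= g * piy
            Fg[grp - 1, i, 2] -= g * piz
            Fg[grp - 1, j, 0] -= g * pjx
            Fg[grp - 1, j, 1] -= g * pjy
            Fg[grp - 1, j, 2] -= g * pjz
            Fg[grp - 1, k, 0] -= g * pkx
            Fg[grp - 1, k, 1] -= g * pky
            Fg[grp - 1, k, 2] -= g * pkz
            Fg[grp - 1, l, 0] -= g * qlx
            Fg[grp - 1, l, 1] -= g * qly
            Fg[grp - 1, l, 2] -= g * qlz
    return e


@njit(cache=True, fastmath=True)
def _tethers(coords, ti, tj, tr0, tk, tgrp, F, Fg, egrp):
    """Harmonic basin-defining springs, routed into interface groups."""
    e = 0.0
    for n in range(ti.shape[0]):
        i, j = ti[n], tj[n]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - tr0[n]
        ev = 0.5 * tk[n] * dr * dr
        if r < 1e-12:
            continue
        c = -tk[n] * dr / r
        g = tgrp[n]
        if g == 0:
            e += ev
            F[i, 0] += c * dx
            F[i, 1] += c * dy
            F[i, 2] += c * dz
            F[j, 0] -= c * dx
            F[j, 1] -= c * dy
            F[j, 2] -= c * dz
        else:
            egrp[g - 1] += ev
            Fg[g - 1, i, 0] += c * dx
            Fg[g - 1, i, 1] += c * dy
            Fg[g - 1, i, 2] += c * dz
            Fg[g - 1, j, 0] -= c * dx
            Fg[g - 1, j, 1] -= c * dy
            Fg[g - 1, j, 2] -= c * dz
    return e


@njit(cache=True, fastmath=True)
def _contacts_1210(coords, ci, cj, cr0, ceps, cgrp, F, Fg, egrp):
    """12-10 native contacts; groups 1..6 accumulate into Fg[g-1]."""
    e_shared = 0.0
    e_lig = 0.0
    for n in range(ci.shape[0]):
        i, j = ci[n], cj[n]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        q = cr0[n] / r
        q2 = q * q
        q10 = q2 * q2 * q2 * q2 * q2
        q12 = q10 * q2
        ev = ceps[n] * (5.0 * q12 - 6.0 * q10)
        # dE/dr = (60*eps/r) * (q10 - q12); force prefactor on (ri - rj)
        c = -(60.0 * ceps[n] / (r * r)) * (q10 - q12)
        g = cgrp[n]
        if g == 0 or g == 7:
            if g == 0:
                e_shared += ev
            else:
                e_lig += ev
            F[i, 0] += c * dx
            F[i, 1] += c * dy
            F[i, 2] += c * dz
            F[j, 0] -= c * dx
            F[j, 1] -= c * dy
            F[j, 2] -= c * dz
        else:
            egrp[g - 1] += ev
            Fg[g - 1, i, 0] += c * dx
            Fg[g - 1, i, 1] += c * dy
            Fg[g - 1, i, 2] += c * dz
            Fg[g - 1, j, 0] -= c * dx
            Fg[g - 1, j, 1] -= c * dy
            Fg[g - 1, j, 2] -= c * dz
    return e_shared, e_lig


@njit(cache=True, fastmath=True)
def _gaussian_wells(coords, gi, gj, eps, sigma, F):
    e = 0.0
    if eps == 0.0:
        return e
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for n in range(gi.shape[0]):
        i, j = gi[n], gj[n]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        ev = -eps * np.exp(-r2 * inv2s2)
        e += ev
        # F_i = -dE/dri = ev * (ri - rj) / sigma^2
        c = ev / (sigma * sigma)
        F[i, 0] += c * dx
        F[i, 1] += c * dy
        F[i, 2] += c * dz
        F[j, 0] -= c * dx
        F[j, 1] -= c * dy
        F[j, 2] -= c * dz
    return e


@njit(cache=True, fastmath=True)
def _excluded_volume(coords, xi_, xj_, sig, eps, F):
    e = 0.0
    for n in range(xi_.shape[0]):
        i, j = xi_[n], xj_[n]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = sig[n] * sig[n] / r2
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        ev = eps * s12
        e += ev
        c = 12.0 * ev / r2
        F[i, 0] += c * dx
        F[i, 1] += c * dy
        F[i, 2] += c * dz
        F[j, 0] -= c * dx
        F[j, 1] -= c * dy
        F[j, 2] -= c * dz
    return e


@njit(cache=True, fastmath=True)
def mix_two_basins(v1, v2, coupling):
    """Lower eigenvalue of the 2x2 secular problem; returns (V_mb, w1).

    V_mb = ((v1+v2) - sqrt((v1-v2)^2 + 4*coupling^2)) / 2 and w1 is the
    chain-rule weight dV_mb/dv1 (w2 = 1 - w1).  At the fully degenerate point
    (v1 = v2, coupling = 0) both weights are 1/2.
    """
    d = v1 - v2
    s = np.sqrt(d * d + 4.0 * coupling * coupling)
    vmb = 0.5 * (v1 + v2 - s)
    if s > 1e-14:
        w1 = 0.5 * (1.0 - d / s)
    else:
        w1 = 0.5
    return vmb, w1


@njit(cache=True, fastmath=True)
def ff_energy_forces(coords,
                     bond_i, bond_j, bond_r0, bond_k,
                     ang_i, ang_j, ang_k, ang_t0, ang_kk, ang_grp,
                     dih_i, dih_j, dih_k, dih_l, dih_p0, dih_kk, dih_grp,
                     con_i, con_j, con_r0, con_eps, con_grp,
                     teth_i, teth_j, teth_r0, teth_k, teth_grp,
                     nn_i, nn_j,
                     exv_i, exv_j, exv_sig,
                     eps_nnat, sigma_nnat, eps_exv,
                     dV, coupling,
                     F, Fg, comps):
    """Total energy and forces of the double-basin coarse-grained model.

    ``F`` (n, 3), ``Fg`` (6, n, 3) and ``comps`` (8,) are caller-provided
    scratch buffers, overwritten on every call.  Returns the total energy;
    the component breakdown is left in ``comps``.
    """
    nb = coords.shape[0]
    F[:] = 0.0
    Fg[:] = 0.0
    comps[:] = 0.0
    egrp = np.zeros(6)

    comps[0] += _bonds(coords, bond_i, bond_j, bond_r0, bond_k, F)
    comps[0] += _angles(coords, ang_i, ang_j, ang_k, ang_t0, ang_kk, ang_grp,
                        F, Fg, egrp)
    comps[0] += _dihedrals(coords, dih_i, dih_j, dih_k, dih_l, dih_p0, dih_kk,
                           dih_grp, F, Fg, egrp)
    e_shared, e_lig = _contacts_1210(coords, con_i, con_j, con_r0, con_eps,
                                     con_grp, F, Fg, egrp)
    e_shared += _tethers(coords, teth_i, teth_j, teth_r0, teth_k, teth_grp,
                         F, Fg, egrp)
    comps[1] = e_shared
    comps[5] = e_lig
    comps[6] = _gaussian_wells(coords, nn_i, nn_j, eps_nnat, sigma_nnat, F)
    comps[7] = _excluded_volume(coords, exv_i, exv_j, exv_sig, eps_exv, F)

    for c in range(3):
        v1 = egrp[c]
        v2 = egrp[c + 3] + dV[c]
        vmb, w1 = mix_two_basins(v1, v2, coupling[c])
        comps[2 + c] = vmb
        w2 = 1.0 - w1
        for i in range(nb):
            F[i, 0] += w1 * Fg[c, i, 0] + w2 * Fg[c + 3, i, 0]
            F[i, 1] += w1 * Fg[c, i, 1] + w2 * Fg[c + 3, i, 1]
            F[i, 2] += w1 * Fg[c, i, 2] + w2 * Fg[c + 3, i, 2]

    etot = 0.0
    for k in range(8):
        etot += comps[k]
    return etot
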