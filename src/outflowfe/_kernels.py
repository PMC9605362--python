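"""Numba kernels for the explicit quasi-static solver.

Everything here operates on plain float64/int64 arrays in the mm-MPa-s unit
system.  The hot path is one fused time loop: move nodes, update stresses
(solids via fully integrated hexahedra with mean-dilatation volumetric
treatment, beams via the degenerated 2-noded formulation), apply follower
pressure and penalty coupling, then advance damped central-difference
velocities.  Strain/spin increments are evaluated in the mid-step
configuration, which makes rigid rotations strain-free to round-off.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small dense helpers
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy", inline="always")
def _inv3(a, out):
    d = (
        a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
        - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
        + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0])
    )
    inv_d = 1.0 / d
    out[0, 0] = (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]) * inv_d
    out[0, 1] = (a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]) * inv_d
    out[0, 2] = (a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]) * inv_d
    out[1, 0] = (a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]) * inv_d
    out[1, 1] = (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]) * inv_d
    out[1, 2] = (a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]) * inv_d
    out[2, 0] = (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]) * inv_d
    out[2, 1] = (a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]) * inv_d
    out[2, 2] = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) * inv_d
    return d


@njit(cache=True, error_model="numpy", inline="always")
def _rot_cayley(w1, w2, w3, r):
    """Orthogonal rotation operator from a spin vector (Hughes-Winget form)."""
    denom = 1.0 + 0.25 * (w1 * w1 + w2 * w2 + w3 * w3)
    # S + S^2/2
    r[0, 0] = 1.0 + (-0.5 * (w3 * w3 + w2 * w2)) / denom
    r[0, 1] = (-w3 + 0.5 * w1 * w2) / denom
    r[0, 2] = (w2 + 0.5 * w1 * w3) / denom
    r[1, 0] = (w3 + 0.5 * w1 * w2) / denom
    r[1, 1] = 1.0 + (-0.5 * (w3 * w3 + w1 * w1)) / denom
    r[1, 2] = (-w1 + 0.5 * w2 * w3) / denom
    r[2, 0] = (-w2 + 0.5 * w1 * w3) / denom
    r[2, 1] = (w1 + 0.5 * w2 * w3) / denom
    r[2, 2] = 1.0 + (-0.5 * (w1 * w1 + w2 * w2)) / denom


@njit(cache=True, error_model="numpy", inline="always")
def _voigt_to_mat(v, m):
    m[0, 0] = v[0]
    m[1, 1] = v[1]
    m[2, 2] = v[2]
    m[0, 1] = v[3]
    m[1, 0] = v[3]
    m[1, 2] = v[4]
    m[2, 1] = v[4]
    m[0, 2] = v[5]
    m[2, 0] = v[5]


@njit(cache=True, error_model="numpy", inline="always")
def _mat_to_voigt(m, v):
    v[0] = m[0, 0]
    v[1] = m[1, 1]
    v[2] = m[2, 2]
    v[3] = 0.5 * (m[0, 1] + m[1, 0])
    v[4] = 0.5 * (m[1, 2] + m[2, 1])
    v[5] = 0.5 * (m[0, 2] + m[2, 0])


@njit(cache=True, error_model="numpy", inline="always")
def _rotate_voigt(v, r, tmp1, tmp2):
    """v <- R M(v) R^T in Voigt storage."""
    _voigt_to_mat(v, tmp1)
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += r[i, k] * tmp1[k, j]
            tmp2[i, j] = s
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += tmp2[i, k] * r[j, k]
            tmp1[i, j] = s
    _mat_to_voigt(tmp1, v)


# ---------------------------------------------------------------------------
# solid hexahedra
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def hex_step(x_mid, x_new, du, elems, mat_id, mat_coef, dn_gauss, sigma, hmem, f_int):
    """Stress update + internal force for all hexahedra (one time step).

    mat_coef rows: [decay, c_h, two_ginf, k_bulk, g_eff] per material.
    Gradients use the mid-step configuration; forces use the updated stress
    and mid-step geometry.  Returns the internal energy increment.
    """
    ne = elems.shape[0]
    e_int = 0.0
    jac = np.empty((3, 3))
    jinv = np.empty((3, 3))
    rot = np.empty((3, 3))
    t1 = np.empty((3, 3))
    t2 = np.empty((3, 3))
    gy = np.empty((8, 8, 3))     # per gp, per node
    detj = np.empty(8)
    grad = np.empty((8, 3, 3))   # per gp displacement gradient
    xe = np.empty((8, 3))
    de = np.empty((8, 3))
    tr_g = np.empty(8)
    dev = np.empty(6)

    for e in range(ne):
        m = mat_id[e]
        decay = mat_coef[m, 0]
        c_h = mat_coef[m, 1]
        two_ginf = mat_coef[m, 2]
        k_bulk = mat_coef[m, 3]

        for a in range(8):
            na = elems[e, a]
            for i in range(3):
                xe[a, i] = x_mid[na, i]
                de[a, i] = du[na, i]

        vol = 0.0
        tr_bar = 0.0
        for g in range(8):
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for a in range(8):
                        s += dn_gauss[g, a, j] * xe[a, i]
                    jac[i, j] = s
            dj = _inv3(jac, jinv)
            detj[g] = dj
            for a in range(8):
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += dn_gauss[g, a, j] * jinv[j, i]
                    gy[g, a, i] = s
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for a in range(8):
                        s += de[a, i] * gy[g, a, j]
                    grad[g, i, j] = s
            tr = grad[g, 0, 0] + grad[g, 1, 1] + grad[g, 2, 2]
            tr_g[g] = tr
            vol += dj
            tr_bar += tr * dj
        tr_bar /= vol

        for g in range(8):
            gg = grad[g]
            # spin vector from the skew part
            w1 = 0.5 * (gg[2, 1] - gg[1, 2])
            w2 = 0.5 * (gg[0, 2] - gg[2, 0])
            w3 = 0.5 * (gg[1, 0] - gg[0, 1])
            _rot_cayley(w1, w2, w3, rot)
            _rotate_voigt(sigma[e, g], rot, t1, t2)
            _rotate_voigt(hmem[e, g], rot, t1, t2)

            corr = (tr_bar - tr_g[g]) / 3.0
            e11 = gg[0, 0] + corr
            e22 = gg[1, 1] + corr
            e33 = gg[2, 2] + corr
            e12 = 0.5 * (gg[0, 1] + gg[1, 0])
            e23 = 0.5 * (gg[1, 2] + gg[2, 1])
            e31 = 0.5 * (gg[0, 2] + gg[2, 0])
            tr = e11 + e22 + e33
            third = tr / 3.0
            dev[0] = e11 - third
            dev[1] = e22 - third
            dev[2] = e33 - third
            dev[3] = e12
            dev[4] = e23
            dev[5] = e31

            for c in range(6):
                h_old = hmem[e, g, c]
                h_new = decay * h_old + c_h * 2.0 * dev[c]
                hmem[e, g, c] = h_new
                sigma[e, g, c] += two_ginf * dev[c] + (h_new - h_old)
            for c in range(3):
                sigma[e, g, c] += k_bulk * tr

            dj = detj[g]
            e_int += (
                sigma[e, g, 0] * e11
                + sigma[e, g, 1] * e22
                + sigma[e, g, 2] * e33
                + 2.0 * (sigma[e, g, 3] * e12 + sigma[e, g, 4] * e23 + sigma[e, g, 5] * e31)
            ) * dj

            _voigt_to_mat(sigma[e, g], t1)
            for a in range(8):
                na = elems[e, a]
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += t1[i, j] * gy[g, a, j]
                    f_int[na, i] += s * dj
    return e_int


# ---------------------------------------------------------------------------
# beams
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def beam_step(
    xb_old, dub, dth, ye, yz, d_ye, d_yz,
    segs, seg_mat, mat_coef, offsets, wts,
    sig_b, h_b, f_b, m_b,
):
    """Fiber-vector update + stress update + internal forces for all beams.

    ``ye``/``yz`` are updated in place; ``d_ye``/``d_yz`` receive the tip
    increments.  Forces accumulate into ``f_b`` (translations) and ``m_b``
    (moments).  Returns the internal energy increment.
    """
    nb = xb_old.shape[0]
    ns = segs.shape[0]
    nip = offsets.shape[0]
    rot = np.empty((3, 3))
    t1 = np.empty((3, 3))
    t2 = np.empty((3, 3))
    jac = np.empty((3, 3))
    jinv = np.empty((3, 3))
    q = np.empty((3, 3))
    grads = np.empty((2, 3, 3))
    gg = np.empty((3, 3))
    sl = np.empty((3, 3))
    hl = np.empty((3, 3))
    dl = np.empty((3, 3))
    e_int = 0.0

    for n in range(nb):
        w1, w2, w3 = dth[n, 0], dth[n, 1], dth[n, 2]
        _rot_cayley(w1, w2, w3, rot)
        for vec_id in range(2):
            if vec_id == 0:
                v = ye[n]
                dv = d_ye[n]
            else:
                v = yz[n]
                dv = d_yz[n]
            a0 = rot[0, 0] * v[0] + rot[0, 1] * v[1] + rot[0, 2] * v[2]
            a1 = rot[1, 0] * v[0] + rot[1, 1] * v[1] + rot[1, 2] * v[2]
            a2 = rot[2, 0] * v[0] + rot[2, 1] * v[1] + rot[2, 2] * v[2]
            nrm = np.sqrt(a0 * a0 + a1 * a1 + a2 * a2)
            a0 /= nrm
            a1 /= nrm
            a2 /= nrm
            dv[0] = a0 - v[0]
            dv[1] = a1 - v[1]
            dv[2] = a2 - v[2]
            v[0] = a0
            v[1] = a1
            v[2] = a2

    for s in range(ns):
        n1 = segs[s, 0]
        n2 = segs[s, 1]
        m = seg_mat[s]
        decay = mat_coef[m, 0]
        c_h = mat_coef[m, 1]
        ginf2 = mat_coef[m, 2]
        k_bulk = mat_coef[m, 3]
        g_eff = mat_coef[m, 4]
        g0_minus_ginf_ramp = c_h
        alpha = k_bulk - 2.0 * g_eff / 3.0

        # new configuration
        x1n = np.empty(3)
        x2n = np.empty(3)
        for i in range(3):
            x1n[i] = xb_old[n1, i] + dub[n1, i]
            x2n[i] = xb_old[n2, i] + dub[n2, i]

        # local co-rotational triad from the new configuration
        ax0 = x2n[0] - x1n[0]
        ax1 = x2n[1] - x1n[1]
        ax2 = x2n[2] - x1n[2]
        ln = np.sqrt(ax0 * ax0 + ax1 * ax1 + ax2 * ax2)
        e10 = ax0 / ln
        e11_ = ax1 / ln
        e12_ = ax2 / ln
        s20 = ye[n1, 0] + ye[n2, 0]
        s21 = ye[n1, 1] + ye[n2, 1]
        s22 = ye[n1, 2] + ye[n2, 2]
        sn = np.sqrt(s20 * s20 + s21 * s21 + s22 * s22)
        s20 /= sn
        s21 /= sn
        s22 /= sn
        e30 = e11_ * s22 - e12_ * s21
        e31 = e12_ * s20 - e10 * s22
        e32 = e10 * s21 - e11_ * s20
        n3 = np.sqrt(e30 * e30 + e31 * e31 + e32 * e32)
        e30 /= n3
        e31 /= n3
        e32 /= n3
        e20 = e31 * e12_ - e32 * e11_
        e21 = e32 * e10 - e30 * e12_
        e22_ = e30 * e11_ - e31 * e10
        q[0, 0] = e10
        q[0, 1] = e11_
        q[0, 2] = e12_
        q[1, 0] = e20
        q[1, 1] = e21
        q[1, 2] = e22_
        q[2, 0] = e30
        q[2, 1] = e31
        q[2, 2] = e32

        for ip in range(nip):
            z_e = offsets[ip, 0]
            z_z = offsets[ip, 1]

            # midpoint geometry rows of the Jacobian
            for i in range(3):
                ye1m = ye[n1, i] - 0.5 * d_ye[n1, i]
                ye2m = ye[n2, i] - 0.5 * d_ye[n2, i]
                yz1m = yz[n1, i] - 0.5 * d_yz[n1, i]
                yz2m = yz[n2, i] - 0.5 * d_yz[n2, i]
                x1m = xb_old[n1, i] + 0.5 * dub[n1, i]
                x2m = xb_old[n2, i] + 0.5 * dub[n2, i]
                jac[0, i] = 0.5 * (
                    (x2m + z_e * ye2m + z_z * yz2m) - (x1m + z_e * ye1m + z_z * yz1m)
                )
                jac[1, i] = 0.5 * (ye1m + ye2m)
                jac[2, i] = 0.5 * (yz1m + yz2m)
            _inv3(jac, jinv)

            # jac rows are d y / d (xi, eta~, zeta~): grad_y = J^-1 @ grad_xi
            for a in range(2):
                dna = -0.5 if a == 0 else 0.5
                na = 0.5
                for i in range(3):
                    grads[a, 0, i] = jinv[i, 0] * dna
                    grads[a, 1, i] = jinv[i, 0] * dna * z_e + jinv[i, 1] * na
                    grads[a, 2, i] = jinv[i, 0] * dna * z_z + jinv[i, 2] * na

            for i in range(3):
                for j in range(3):
                    gg[i, j] = (
                        dub[n1, i] * grads[0, 0, j]
                        + dub[n2, i] * grads[1, 0, j]
                        + d_ye[n1, i] * grads[0, 1, j]
                        + d_ye[n2, i] * grads[1, 1, j]
                        + d_yz[n1, i] * grads[0, 2, j]
                        + d_yz[n2, i] * grads[1, 2, j]
                    )

            w1 = 0.5 * (gg[2, 1] - gg[1, 2])
            w2 = 0.5 * (gg[0, 2] - gg[2, 0])
            w3 = 0.5 * (gg[1, 0] - gg[0, 1])
            _rot_cayley(w1, w2, w3, rot)
            _rotate_voigt(sig_b[s, ip], rot, t1, t2)
            _rotate_voigt(h_b[s, ip], rot, t1, t2)

            # to local frame
            _voigt_to_mat(sig_b[s, ip], t1)
            for i in range(3):
                for j in range(3):
                    t2[i, j] = q[i, 0] * t1[0, j] + q[i, 1] * t1[1, j] + q[i, 2] * t1[2, j]
            for i in range(3):
                for j in range(3):
                    sl[i, j] = t2[i, 0] * q[j, 0] + t2[i, 1] * q[j, 1] + t2[i, 2] * q[j, 2]
            _voigt_to_mat(h_b[s, ip], t1)
            for i in range(3):
                for j in range(3):
                    t2[i, j] = q[i, 0] * t1[0, j] + q[i, 1] * t1[1, j] + q[i, 2] * t1[2, j]
            for i in range(3):
                for j in range(3):
                    hl[i, j] = t2[i, 0] * q[j, 0] + t2[i, 1] * q[j, 1] + t2[i, 2] * q[j, 2]
            # strain increment to local
            for i in range(3):
                for j in range(3):
                    t1[i, j] = 0.5 * (gg[i, j] + gg[j, i])
            for i in range(3):
                for j in range(3):
                    t2[i, j] = q[i, 0] * t1[0, j] + q[i, 1] * t1[1, j] + q[i, 2] * t1[2, j]
            for i in range(3):
                for j in range(3):
                    dl[i, j] = t2[i, 0] * q[j, 0] + t2[i, 1] * q[j, 1] + t2[i, 2] * q[j, 2]

            # condense transverse normal strains: sigma_22 = sigma_33 = 0
            a11 = 2.0 * g_eff + alpha
            a22k = sl[1, 1] + (decay - 1.0) * hl[1, 1]
            a33k = sl[2, 2] + (decay - 1.0) * hl[2, 2]
            r1 = -(a22k + alpha * dl[0, 0])
            r2 = -(a33k + alpha * dl[0, 0])
            det2 = a11 * a11 - alpha * alpha
            de22 = (a11 * r1 - alpha * r2) / det2
            de33 = (a11 * r2 - alpha * r1) / det2
            dl[1, 1] = de22
            dl[2, 2] = de33

            tr = dl[0, 0] + dl[1, 1] + dl[2, 2]
            third = tr / 3.0
            for i in range(3):
                for j in range(3):
                    dev_ij = dl[i, j] - (third if i == j else 0.0)
                    h_new = decay * hl[i, j] + g0_minus_ginf_ramp * 2.0 * dev_ij
                    sl[i, j] += ginf2 * dev_ij + (h_new - hl[i, j])
                    hl[i, j] = h_new
                sl[i, i] += k_bulk * tr
            sl[1, 1] = 0.0
            sl[2, 2] = 0.0

            # back to global
            for i in range(3):
                for j in range(3):
                    t2[i, j] = q[0, i] * sl[0, j] + q[1, i] * sl[1, j] + q[2, i] * sl[2, j]
            for i in range(3):
                for j in range(3):
                    t1[i, j] = t2[i, 0] * q[0, j] + t2[i, 1] * q[1, j] + t2[i, 2] * q[2, j]
            _mat_to_voigt(t1, sig_b[s, ip])
            sig_glob = t1.copy()
            for i in range(3):
                for j in range(3):
                    t2[i, j] = q[0, i] * hl[0, j] + q[1, i] * hl[1, j] + q[2, i] * hl[2, j]
            for i in range(3):
                for j in range(3):
                    t1[i, j] = t2[i, 0] * q[0, j] + t2[i, 1] * q[1, j] + t2[i, 2] * q[2, j]
            _mat_to_voigt(t1, h_b[s, ip])

            # energy (global strain increment against updated stress)
            for i in range(3):
                for j in range(3):
                    e_int += sig_glob[i, j] * 0.5 * (gg[i, j] + gg[j, i]) * ln * wts[ip]

            # internal force contributions (end-of-step geometry ~ midpoint ok)
            dv = ln * wts[ip]
            for a in range(2):
                node = n1 if a == 0 else n2
                fu0 = (sig_glob[0, 0] * grads[a, 0, 0] + sig_glob[0, 1] * grads[a, 0, 1] + sig_glob[0, 2] * grads[a, 0, 2]) * dv
                fu1 = (sig_glob[1, 0] * grads[a, 0, 0] + sig_glob[1, 1] * grads[a, 0, 1] + sig_glob[1, 2] * grads[a, 0, 2]) * dv
                fu2 = (sig_glob[2, 0] * grads[a, 0, 0] + sig_glob[2, 1] * grads[a, 0, 1] + sig_glob[2, 2] * grads[a, 0, 2]) * dv
                fe0 = (sig_glob[0, 0] * grads[a, 1, 0] + sig_glob[0, 1] * grads[a, 1, 1] + sig_glob[0, 2] * grads[a, 1, 2]) * dv
                fe1 = (sig_glob[1, 0] * grads[a, 1, 0] + sig_glob[1, 1] * grads[a, 1, 1] + sig_glob[1, 2] * grads[a, 1, 2]) * dv
                fe2 = (sig_glob[2, 0] * grads[a, 1, 0] + sig_glob[2, 1] * grads[a, 1, 1] + sig_glob[2, 2] * grads[a, 1, 2]) * dv
                fz0 = (sig_glob[0, 0] * grads[a, 2, 0] + sig_glob[0, 1] * grads[a, 2, 1] + sig_glob[0, 2] * grads[a, 2, 2]) * dv
                fz1 = (sig_glob[1, 0] * grads[a, 2, 0] + sig_glob[1, 1] * grads[a, 2, 1] + sig_glob[1, 2] * grads[a, 2, 2]) * dv
                fz2 = (sig_glob[2, 0] * grads[a, 2, 0] + sig_glob[2, 1] * grads[a, 2, 1] + sig_glob[2, 2] * grads[a, 2, 2]) * dv
                f_b[node, 0] += fu0
                f_b[node, 1] += fu1
                f_b[node, 2] += fu2
                # moment = Y_eta x f_eta + Y_zeta x f_zeta
                m_b[node, 0] += ye[node, 1] * fe2 - ye[node, 2] * fe1 + yz[node, 1] * fz2 - yz[node, 2] * fz1
                m_b[node, 1] += ye[node, 2] * fe0 - ye[node, 0] * fe2 + yz[node, 2] * fz0 - yz[node, 0] * fz2
                m_b[node, 2] += ye[node, 0] * fe1 - ye[node, 1] * fe0 + yz[node, 0] * fz1 - yz[node, 1] * fz0
    return e_int


# ---------------------------------------------------------------------------
# coupling + pressure
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def coupling_step(x_s, x_b, c_conn, c_w, c_k, f_s, f_b):
    nb = x_b.shape[0]
    for n in range(nb):
        k = c_k[n]
        for i in range(3):
            xh = 0.0
            for a in range(8):
                xh += c_w[n, a] * x_s[c_conn[n, a], i]
            fi = k * (xh - x_b[n, i])
            f_b[n, i] += fi
            for a in range(8):
                f_s[c_conn[n, a], i] -= c_w[n, a] * fi
    return 0


@njit(cache=True, error_model="numpy")
def pressure_step(x, du, faces, p, f):
    """Follower pressure on quad faces; returns external work increment."""
    nf = faces.shape[0]
    w_ext = 0.0
    for fc in range(nf):
        a = faces[fc, 0]
        b = faces[fc, 1]
        c = faces[fc, 2]
        d = faces[fc, 3]
        d10 = x[c, 0] - x[a, 0]
        d11 = x[c, 1] - x[a, 1]
        d12 = x[c, 2] - x[a, 2]
        d20 = x[d, 0] - x[b, 0]
        d21 = x[d, 1] - x[b, 1]
        d22 = x[d, 2] - x[b, 2]
        av0 = 0.5 * (d11 * d22 - d12 * d21)
        av1 = 0.5 * (d12 * d20 - d10 * d22)
        av2 = 0.5 * (d10 * d21 - d11 * d20)
        f0 = -p * av0 * 0.25
        f1 = -p * av1 * 0.25
        f2 = -p * av2 * 0.25
        for nd in (a, b, c, d):
            f[nd, 0] += f0
            f[nd, 1] += f1
            f[nd, 2] += f2
            w_ext += f0 * du[nd, 0] + f1 * du[nd, 1] + f2 * du[nd, 2]
    return w_ext


@njit(cache=True, error_model="numpy", inline="always")
def _interp_table(t, tt, vv):
    n = tt.shape[0]
    if t <= tt[0]:
        return vv[0]
    if t >= tt[n - 1]:
        return vv[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tt[mid] <= t:
            lo = mid
        else:
            hi = mid
    w = (t - tt[lo]) / (tt[hi] - tt[lo])
    return vv[lo] * (1.0 - w) + vv[hi] * w


# ---------------------------------------------------------------------------
# master loop
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def run_loop(
    x, v, mass, fixed_mask,
    elems, mat_id, mat_coef, dn_gauss, sigma, hmem,
    xb, vb, wb, mb, ib, ye, yz,
    segs, seg_mat, sig_b, h_b, offsets, wts,
    c_conn, c_w, c_k,
    faces, p_times, p_vals,
    presc_ids, presc_t, presc_x, presc_dof,
    dt, n_steps, alpha, out_stride,
    frames_x, frames_xb, frames_t, frames_sig, frames_sigb, energies,
):
    nn = x.shape[0]
    nb = xb.shape[0]
    ne = elems.shape[0]
    f_s = np.zeros((nn, 3))
    f_b = np.zeros((nb, 3))
    m_bm = np.zeros((nb, 3))
    du = np.zeros((nn, 3))
    dub = np.zeros((nb, 3))
    dth = np.zeros((nb, 3))
    d_ye = np.zeros((nb, 3))
    d_yz = np.zeros((nb, 3))
    x_mid = np.zeros((nn, 3))
    e_int = 0.0
    e_ext = 0.0
    out_i = 0
    damp1 = 1.0 - 0.5 * alpha * dt
    damp2 = 1.0 / (1.0 + 0.5 * alpha * dt)

    for step in range(n_steps):
        t_new = (step + 1) * dt

        # prescribed trajectories override velocities (masked per dof)
        for pi in range(presc_ids.shape[0]):
            node = presc_ids[pi]
            for i in range(3):
                if presc_dof[i]:
                    target = _interp_table(t_new, presc_t, presc_x[:, pi, i])
                    v[node, i] = (target - x[node, i]) / dt

        for n in range(nn):
            for i in range(3):
                if fixed_mask[n, i]:
                    v[n, i] = 0.0
                du[n, i] = v[n, i] * dt
                x_mid[n, i] = x[n, i] + 0.5 * du[n, i]

        for n in range(nb):
            for i in range(3):
                dub[n, i] = vb[n, i] * dt
                dth[n, i] = wb[n, i] * dt

        f_s[:] = 0.0
        f_b[:] = 0.0
        m_bm[:] = 0.0

        # solids: stress update + internal forces (negated below)
        e_int += hex_step(x_mid, x, du, elems, mat_id, mat_coef, dn_gauss, sigma, hmem, f_s)
        for n in range(nn):
            for i in range(3):
                f_s[n, i] = -f_s[n, i]

        # advance solid positions
        for n in range(nn):
            for i in range(3):
                x[n, i] += du[n, i]

        # beams: internal forces accumulate positively, negate after
        if nb > 0:
            e_int += beam_step(
                xb, dub, dth, ye, yz, d_ye, d_yz,
                segs, seg_mat, mat_coef, offsets, wts,
                sig_b, h_b, f_b, m_bm,
            )
            for n in range(nb):
                for i in range(3):
                    f_b[n, i] = -f_b[n, i]
                    m_bm[n, i] = -m_bm[n, i]
                    xb[n, i] += dub[n, i]
            coupling_step(x, xb, c_conn, c_w, c_k, f_s, f_b)

        # follower pressure at the new configuration
        p_now = _interp_table(t_new, p_times, p_vals)
        if faces.shape[0] > 0:
            e_ext += pressure_step(x, du, faces, p_now, f_s)

        # velocity updates (damped central difference)
        for n in range(nn):
            for i in range(3):
                if fixed_mask[n, i]:
                    v[n, i] = 0.0
                else:
                    v[n, i] = (damp1 * v[n, i] + dt * f_s[n, i] / mass[n]) * damp2
        for pi in range(presc_ids.shape[0]):
            node = presc_ids[pi]
            for i in range(3):
                if presc_dof[i]:
                    v[node, i] = 0.0   # reset; next step recomputes from trajectory
        for n in range(nb):
            for i in range(3):
                vb[n, i] = (damp1 * vb[n, i] + dt * f_b[n, i] / mb[n]) * damp2
                wb[n, i] = (damp1 * wb[n, i] + dt * m_bm[n, i] / ib[n]) * damp2

        if (step + 1) % out_stride == 0 or step == n_steps - 1:
            if out_i < frames_t.shape[0]:
                frames_t[out_i] = t_new
                for n in range(nn):
                    for i in range(3):
                        frames_x[out_i, n, i] = x[n, i]
                for n in range(nb):
                    for i in range(3):
                        frames_xb[out_i, n, i] = xb[n, i]
                for e in range(ne):
                    for c in range(6):
                        s = 0.0
                        for g in range(8):
                            s += sigma[e, g, c]
                        frames_sig[out_i, e, c] = s / 8.0
                nip = sig_b.shape[1]
                if nip > 0:
                    for sg in range(segs.shape[0]):
                        for c in range(6):
                            s = 0.0
                            for ip in range(nip):
                                s += sig_b[sg, ip, c]
                            frames_sigb[out_i, sg, c] = s / nip
                ke = 0.0
                for n in range(nn):
                    ke += 0.5 * mass[n] * (v[n, 0] ** 2 + v[n, 1] ** 2 + v[n, 2] ** 2)
                for n in range(nb):
                    ke += 0.5 * mb[n] * (vb[n, 0] ** 2 + vb[n, 1] ** 2 + vb[n, 2] ** 2)
                energies[out_i, 0] = ke
                energies[out_i, 1] = e_int
                energies[out_i, 2] = e_ext
                # instability guard: relative, after a warmup window
                if not np.isfinite(ke):
                    return 1, out_i + 1
                if step > n_steps // 3 and ke > 50.0 * (abs(e_int) + abs(e_ext)) and ke > 0.0:
                    return 1, out_i + 1
                out_i += 1
    return 0, out_i
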