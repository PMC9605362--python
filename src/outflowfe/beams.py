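"""Degenerated-solid (Hughes-Liu) 2-noded beam element.

The beam is derived from the trilinear 8-noded hexahedron by collapsing the
four nodes at each end into a single node carrying three translations and
three rotations.  Cross-section orientation is tracked by two unit section
("fiber") vectors per node, updated with a second-order accurate (Cayley)
rotation operator, which makes the formulation incrementally objective:
rigid rotations generate no strain.

Constitutive evaluation happens in a co-rotational local frame where the
transverse normal stresses are condensed to zero each step.  Finite
transverse shear is retained.  Integration is one-point along the axis and
four points on the tubular cross-section (one per quadrant at the area
centroidal radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .material import (
    ViscoelasticParams,
    stress_update_coefficients,
)
from .meshing import HexMesh, BeamNetwork, locate_point, shape_gradients, _XI_A

__all__ = [
    "BeamNode",
    "BeamSection",
    "BeamElementState",
    "CouplingSet",
    "shape_functions",
    "rotation_update",
    "update_fiber_vectors",
    "local_basis",
    "strain_spin_increment",
    "b_matrix",
    "beam_internal_force",
    "couple_beams_to_solid",
    "coupling_forces",
]


def shape_functions(xi: float, eta: float, zeta: float):
    """Trilinear shape functions of the parent hexahedron and their
    parametric derivatives: ``N_a = (1 + xi_a xi)(1 + eta_a eta)(1 + zeta_a zeta)/8``.

    Returns ``(n, dn)`` with shapes (8,) and (8, 3).
    """
    p = np.array([xi, eta, zeta], dtype=float)
    if np.any(np.abs(p) > 1.0 + 1e-12):
        raise ValueError("parametric coordinates must lie in the biunit cube")
    n = np.prod(1.0 + _XI_A * p[None, :], axis=1) / 8.0
    dn = shape_gradients(p)
    return n, dn


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def rotation_update(d_theta) -> np.ndarray:
    """Second-order accurate (Hughes-Winget / Cayley) rotation operator.

    ``R = I + (S + S^2/2) / (1 + |dtheta|^2 / 4)`` with ``S = skew(dtheta)``.
    Exactly orthogonal for any increment magnitude; matches the Rodrigues
    rotation to second order.
    """
    th = np.asarray(d_theta, dtype=float)
    s = _skew(th)
    denom = 1.0 + 0.25 * float(th @ th)
    return np.eye(3) + (s + 0.5 * (s @ s)) / denom


@dataclass
class BeamNode:
    """Beam node: positions, translation, section vectors, rotation increment."""

    x_ref: np.ndarray
    x_cur: np.ndarray
    y_eta: np.ndarray
    y_zeta: np.ndarray
    u: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta_inc: np.ndarray = field(default_factory=lambda: np.zeros(3))


def update_fiber_vectors(node: BeamNode, d_theta) -> tuple:
    """Rotate both section vectors by ``rotation_update(d_theta)``.

    Returns ``(d_u_eta, d_u_zeta)``, the fiber-tip displacement increments
    (new minus old unit vectors).  Norms are renormalised to guard against
    drift over long increment sequences.
    """
    r = rotation_update(d_theta)
    y_eta_new = r @ node.y_eta
    y_zeta_new = r @ node.y_zeta
    y_eta_new /= np.linalg.norm(y_eta_new)
    y_zeta_new /= np.linalg.norm(y_zeta_new)
    d_eta = y_eta_new - node.y_eta
    d_zeta = y_zeta_new - node.y_zeta
    node.y_eta = y_eta_new
    node.y_zeta = y_zeta_new
    node.theta_inc = np.asarray(d_theta, dtype=float)
    return d_eta, d_zeta


def local_basis(node1: BeamNode, node2: BeamNode) -> np.ndarray:
    """Co-rotational orthonormal triad (rows e1, e2, e3).

    e1 follows the axis, e2/e3 are normal to it; e2' is seeded by the mean
    eta-section vector of the two nodes.
    """
    return _local_basis_vectors(node1.x_cur, node2.x_cur, node1.y_eta, node2.y_eta)


def _local_basis_vectors(y1, y2, y_eta1, y_eta2) -> np.ndarray:
    axis = np.asarray(y2, dtype=float) - np.asarray(y1, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1.0e-14:
        raise ValueError("beam nodes are coincident")
    e1 = axis / norm
    seed = np.asarray(y_eta1, dtype=float) + np.asarray(y_eta2, dtype=float)
    sn = np.linalg.norm(seed)
    if sn < 1.0e-14:
        raise ValueError("mean section vector vanishes")
    e2p = seed / sn
    e3 = np.cross(e1, e2p)
    n3 = np.linalg.norm(e3)
    if n3 < 1.0e-10:
        raise ValueError("section vector parallel to the beam axis")
    e3 /= n3
    e2 = np.cross(e3, e1)
    return np.vstack([e1, e2, e3])


def strain_spin_increment(du_gradient):
    """Split an incremental displacement gradient into strain and spin."""
    g = np.asarray(du_gradient, dtype=float)
    if g.shape != (3, 3):
        raise ValueError("gradient must be 3x3")
    d_eps = 0.5 * (g + g.T)
    d_omega = 0.5 * (g - g.T)
    return d_eps, d_omega


@dataclass
class BeamSection:
    """Tubular cross-section with its integration rule.

    ``eta_bar``/``zeta_bar`` place the reference surface (0 = mid-axis).
    Integration points carry physical offsets (along the two section vectors)
    and area weights that sum to the section area.
    """

    r_outer: float
    r_inner: float = 0.0
    eta_bar: float = 0.0
    zeta_bar: float = 0.0
    offsets: np.ndarray = None    # (nip, 2): (z_eta, z_zeta), physical length
    weights: np.ndarray = None    # (nip,) area weights

    def __post_init__(self):
        if self.r_outer <= 0 or self.r_inner < 0 or self.r_inner >= self.r_outer:
            raise ValueError("invalid tubular section radii")
        if self.offsets is None:
            ro, ri = self.r_outer, self.r_inner
            area = np.pi * (ro**2 - ri**2)
            # centroid coordinate of one quadrant of the annulus
            c = (4.0 / (3.0 * np.pi)) * (ro**3 - ri**3) / (ro**2 - ri**2)
            self.offsets = np.array(
                [[c, c], [-c, c], [-c, -c], [c, -c]], dtype=float
            )
            self.weights = np.full(4, area / 4.0)
        if abs(self.weights.sum() - self.area) > 1e-12 * max(self.area, 1.0):
            raise ValueError("integration weights must sum to the section area")

    @property
    def area(self) -> float:
        return np.pi * (self.r_outer**2 - self.r_inner**2)


@dataclass
class BeamElementState:
    """Per-element kinematic snapshot and per-integration-point stress."""

    node1: BeamNode
    node2: BeamNode
    section: BeamSection
    sigma: np.ndarray = None   # (nip, 6) local-frame-free global storage
    h: np.ndarray = None
    t: float = 0.0

    def __post_init__(self):
        nip = self.section.offsets.shape[0]
        if self.sigma is None:
            self.sigma = np.zeros((nip, 6))
        if self.h is None:
            self.h = np.zeros((nip, 6))


def _beam_gradients(y1, y2, ye1, ye2, yz1, yz2, z_eta, z_zeta):
    """Global gradients of N_a, N_a*z_eta, N_a*z_zeta at (xi=0, section point).

    Returns ``(grads, det_j)`` where grads has shape (2, 3, 3): node a ->
    rows [grad N_a, grad(N_a z_eta_a), grad(N_a z_zeta_a)].
    """
    n = np.array([0.5, 0.5])
    dn_dxi = np.array([-0.5, 0.5])
    # Jacobian rows: d y / d xi, d y / d eta~, d y / d zeta~ (physical offsets)
    dy_dxi = dn_dxi[0] * (y1 + z_eta * ye1 + z_zeta * yz1) + dn_dxi[1] * (
        y2 + z_eta * ye2 + z_zeta * yz2
    )
    dy_deta = n[0] * ye1 + n[1] * ye2
    dy_dzeta = n[0] * yz1 + n[1] * yz2
    jac = np.vstack([dy_dxi, dy_deta, dy_dzeta])
    det_j = np.linalg.det(jac)
    if abs(det_j) < 1.0e-18:
        raise ValueError("singular beam Jacobian (distorted element)")
    # jac rows are d y / d (xi, eta~, zeta~), so grad_y f = jac^-1 @ grad_xi f
    jinv = np.linalg.inv(jac)
    grads = np.empty((2, 3, 3))
    for a, (na, dna) in enumerate(zip(n, dn_dxi)):
        grads[a, 0] = jinv @ np.array([dna, 0.0, 0.0])
        grads[a, 1] = jinv @ np.array([dna * z_eta, na, 0.0])
        grads[a, 2] = jinv @ np.array([dna * z_zeta, 0.0, na])
    return grads, det_j


def b_matrix(y1, y2, y_eta1, y_eta2, y_zeta1, y_zeta2,
             section: BeamSection, ip: int) -> np.ndarray:
    """6x18 strain-displacement matrix at one cross-section integration point.

    Column order: [u1 (3), U_eta1-tip (3), U_zeta1-tip (3), u2, U_eta2-tip,
    U_zeta2-tip]; row order [exx, eyy, ezz, gxy, gyz, gzx] with engineering
    shear.  Evaluated at the mid-point of the axis (xi = 0).
    """
    z_eta, z_zeta = section.offsets[ip]
    grads, _ = _beam_gradients(
        np.asarray(y1, float), np.asarray(y2, float),
        np.asarray(y_eta1, float), np.asarray(y_eta2, float),
        np.asarray(y_zeta1, float), np.asarray(y_zeta2, float),
        z_eta, z_zeta,
    )
    b = np.zeros((6, 18))
    for a in range(2):
        col0 = 9 * a
        for blk in range(3):   # u, U_eta, U_zeta blocks
            g = grads[a, blk]  # (3,) gradient of the scalar interpolant
            c = col0 + 3 * blk
            b[0, c + 0] = g[0]
            b[1, c + 1] = g[1]
            b[2, c + 2] = g[2]
            b[3, c + 0] = g[1]
            b[3, c + 1] = g[0]
            b[4, c + 1] = g[2]
            b[4, c + 2] = g[1]
            b[5, c + 0] = g[2]
            b[5, c + 2] = g[0]
    return b


def _rotate_sigma_orthogonal(sig6, d_omega):
    """Rotate a Voigt stress by the orthogonal operator built from the spin."""
    w = np.array([d_omega[2, 1], d_omega[0, 2], d_omega[1, 0]])
    r = rotation_update(w)
    from .material import voigt_to_tensor, tensor_to_voigt

    return tensor_to_voigt(r @ voigt_to_tensor(sig6) @ r.T)


def _condensed_local_update(sig_l, h_l, de_l, params, dt):
    """Viscoelastic update in the local frame with sigma_22 = sigma_33 = 0.

    The transverse normal strain increments are condensed so that the
    updated transverse normal stresses vanish (iteration-free for this
    isotropic law).  Returns updated (sigma, h, de_modified), all 3x3.
    """
    decay, ramp, g_eff, k = stress_update_coefficients(params, dt)
    alpha = k - 2.0 * g_eff / 3.0
    a_known = sig_l + (decay - 1.0) * h_l
    c11 = de_l[0, 0]
    m = np.array([[2 * g_eff + alpha, alpha], [alpha, 2 * g_eff + alpha]])
    rhs = -np.array([a_known[1, 1] + alpha * c11, a_known[2, 2] + alpha * c11])
    de22, de33 = np.linalg.solve(m, rhs)
    de = de_l.copy()
    de[1, 1] = de22
    de[2, 2] = de33
    tr = np.trace(de)
    de_dev = de - tr / 3.0 * np.eye(3)
    h_new = decay * h_l + (params.g0 - params.ginf) * ramp * 2.0 * de_dev
    sig_new = sig_l + (h_new - h_l) + 2.0 * params.ginf * de_dev + k * tr * np.eye(3)
    sig_new[1, 1] = 0.0
    sig_new[2, 2] = 0.0
    return sig_new, h_new, de


def beam_internal_force(state: BeamElementState, du1, du2, d_theta1, d_theta2,
                        material: ViscoelasticParams, dt: float) -> np.ndarray:
    """Advance a beam element by one increment and return nodal forces.

    Applies the rotational update to the section vectors, computes midpoint
    strain/spin increments, performs the condensed viscoelastic update at
    every section integration point and integrates ``B^T sigma`` over the
    element.  Fiber-tip forces are transformed to moments.

    Returns the 12-vector ``[f1, m1, f2, m2]`` of internal forces/moments.
    """
    from .material import voigt_to_tensor, tensor_to_voigt

    if dt <= 0:
        raise ValueError("dt must be positive")
    n1, n2 = state.node1, state.node2
    du1 = np.asarray(du1, float)
    du2 = np.asarray(du2, float)

    ye1_old, yz1_old = n1.y_eta.copy(), n1.y_zeta.copy()
    ye2_old, yz2_old = n2.y_eta.copy(), n2.y_zeta.copy()
    d_eta1, d_zeta1 = update_fiber_vectors(n1, d_theta1)
    d_eta2, d_zeta2 = update_fiber_vectors(n2, d_theta2)

    y1_old, y2_old = n1.x_cur.copy(), n2.x_cur.copy()
    n1.x_cur = y1_old + du1
    n2.x_cur = y2_old + du2
    n1.u += du1
    n2.u += du2

    # midpoint geometry (incremental objectivity)
    y1m, y2m = y1_old + 0.5 * du1, y2_old + 0.5 * du2
    ye1m, ye2m = ye1_old + 0.5 * d_eta1, ye2_old + 0.5 * d_eta2
    yz1m, yz2m = yz1_old + 0.5 * d_zeta1, yz2_old + 0.5 * d_zeta2

    q = _local_basis_vectors(n1.x_cur, n2.x_cur, n1.y_eta, n2.y_eta)

    sec = state.section
    cur_len = np.linalg.norm(n2.x_cur - n1.x_cur)
    f9 = np.zeros((2, 3, 3))   # node, block (u, U_eta, U_zeta), component
    dus = (du1, du2)
    detas = (d_eta1, d_eta2)
    dzetas = (d_zeta1, d_zeta2)
    for ip in range(sec.offsets.shape[0]):
        z_eta, z_zeta = sec.offsets[ip]
        grads_m, _ = _beam_gradients(y1m, y2m, ye1m, ye2m, yz1m, yz2m, z_eta, z_zeta)
        # displacement field: N_a du_a + (N_a z_eta) dU_eta_a + (N_a z_zeta) dU_zeta_a
        g = np.zeros((3, 3))
        for a in range(2):
            g += np.outer(dus[a], grads_m[a, 0])
            g += np.outer(detas[a], grads_m[a, 1])
            g += np.outer(dzetas[a], grads_m[a, 2])
        d_eps, d_omega = strain_spin_increment(g)

        sig = _rotate_sigma_orthogonal(state.sigma[ip], d_omega)
        hh = _rotate_sigma_orthogonal(state.h[ip], d_omega)
        sig_l = q @ voigt_to_tensor(sig) @ q.T
        h_l = q @ voigt_to_tensor(hh) @ q.T
        de_l = q @ d_eps @ q.T
        sig_l, h_l, _ = _condensed_local_update(sig_l, h_l, de_l, material, dt)
        sig_g = q.T @ sig_l @ q
        h_g = q.T @ h_l @ q
        state.sigma[ip] = tensor_to_voigt(sig_g)
        state.h[ip] = tensor_to_voigt(h_g)

        grads_n, _ = _beam_gradients(
            n1.x_cur, n2.x_cur, n1.y_eta, n2.y_eta, n1.y_zeta, n2.y_zeta,
            z_eta, z_zeta,
        )
        dv = cur_len * sec.weights[ip]
        for a in range(2):
            for blk in range(3):
                f9[a, blk] += (sig_g @ grads_n[a, blk]) * dv

    state.t += dt
    out = np.empty(12)
    for a, node in enumerate((n1, n2)):
        f_u = f9[a, 0]
        m = np.cross(node.y_eta, f9[a, 1]) + np.cross(node.y_zeta, f9[a, 2])
        out[6 * a: 6 * a + 3] = f_u
        out[6 * a + 3: 6 * a + 6] = m
    return out


# ---------------------------------------------------------------------------
# beam-in-solid coupling
# ---------------------------------------------------------------------------

@dataclass
class CouplingSet:
    """Penalty ties between beam control points and host-element material points."""

    host_elem: np.ndarray       # (nb,)
    host_xi: np.ndarray         # (nb, 3)
    weights: np.ndarray         # (nb, 8) trilinear shape values
    stiffness: np.ndarray       # (nb,) N/mm


def couple_beams_to_solid(beams: BeamNetwork, mesh: HexMesh,
                          penalty_scale: float = 100.0,
                          shear_modulus_by_tag: Optional[dict] = None) -> CouplingSet:
    """Bind every beam control point to its host hexahedron.

    The penalty stiffness is ``penalty_scale`` times a host-element elastic
    stiffness estimate ``G * l`` (shear modulus times characteristic edge).
    Raises if any control point falls outside the mesh, listing orphans.
    """
    nb = beams.n_points
    host = np.empty(nb, dtype=np.int64)
    xi_arr = np.empty((nb, 3))
    weights = np.empty((nb, 8))
    stiff = np.empty(nb)
    orphans = []
    hosts_hint = beams.meta.get("host_elements")
    edge_mm = mesh.meta.get("edge_um", 4.0) * 1.0e-3
    for k in range(nb):
        p = beams.control_points[k]
        e = None
        if hosts_hint is not None:
            xi = _invert_trilinear(mesh.nodes[mesh.elements[hosts_hint[k]]], p)
            if xi is not None:
                e = int(hosts_hint[k])
        if e is None:
            e, xi = locate_point(mesh, p)
        if e is None:
            orphans.append(k)
            continue
        host[k] = e
        xi_arr[k] = xi
        n, _ = shape_functions(*xi)
        weights[k] = n
        g_host = 1.0
        if shear_modulus_by_tag is not None:
            g_host = shear_modulus_by_tag.get(int(mesh.tissue_tag[e]), 1.0)
        stiff[k] = penalty_scale * g_host * edge_mm
    if orphans:
        raise ValueError(
            f"{len(orphans)} beam control points lie outside the mesh: "
            f"{orphans[:10]}{'...' if len(orphans) > 10 else ''}"
        )
    return CouplingSet(host_elem=host, host_xi=xi_arr, weights=weights, stiffness=stiff)


def coupling_forces(coupling: CouplingSet, mesh: HexMesh, solid_coords: np.ndarray,
                    beam_coords: np.ndarray):
    """Penalty force pairs for the current configurations.

    Returns ``(f_beam, f_solid)``: the force on each beam point and the
    equal-and-opposite reaction distributed to the host nodes by shape
    weights.  Momentum is conserved exactly.
    """
    f_beam = np.zeros_like(beam_coords)
    f_solid = np.zeros_like(solid_coords)
    for k in range(coupling.host_elem.size):
        conn = mesh.elements[coupling.host_elem[k]]
        x_host = coupling.weights[k] @ solid_coords[conn]
        f = coupling.stiffness[k] * (x_host - beam_coords[k])
        f_beam[k] += f
        for a in range(8):
            f_solid[conn[a]] -= coupling.weights[k][a] * f
    return f_beam, f_solid


from .meshing import _invert_trilinear  # noqa: E402  (shared helper)
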