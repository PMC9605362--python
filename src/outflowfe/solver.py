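"""Explicit quasi-static solver.

Central-difference integration with mass-proportional damping (dynamic
relaxation) drives the model to a quasi-static response under pressure
and/or floating-displacement boundary conditions.  Because the physical
tissue inertia is irrelevant at these scales, nodal masses are scaled from
element stiffness so that every element oscillates at the same frequency
``gamma / dt`` — the standard mass-scaling device for explicit quasi-static
analysis.  The kinetic/internal energy ratio is monitored and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import _kernels
from .material import ViscoelasticParams, StressState, stress_update_coefficients, update_stress, voigt_to_tensor, tensor_to_voigt
from .meshing import HexMesh, TissueTag, _GAUSS_DN, shape_gradients, _XI_A
from .beams import CouplingSet
from .units import MMHG_TO_MPA

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "LoadCase",
    "BoundaryTrajectory",
    "SolverError",
    "run",
    "hex_internal_force",
    "apply_pressure",
    "apply_floating_displacement",
    "probe_average_displacement",
]


class SolverError(RuntimeError):
    pass


@dataclass
class BoundaryTrajectory:
    """Time-stamped coordinates of tracked boundary nodes (mm)."""

    times: np.ndarray          # (nf,)
    node_ids: np.ndarray       # (k,)
    coords: np.ndarray         # (nf, k, 3)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.times.size, self.node_ids.size, 3):
            raise ValueError("trajectory coords must have shape (n_frames, n_nodes, 3)")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class SimulationConfig:
    """Explicit-solver controls.

    ``dt_scale`` is the fraction of the (mass-scaled) per-element critical
    step actually used; with stiffness-proportional mass scaling the element
    frequency is ``dt_scale/dt`` by construction, so stability is guaranteed
    for ``dt_scale < 2``.  A conservative default well below the audit value
    is used.  ``damping=None`` selects mass-proportional damping at roughly
    critical for the lowest structural mode.
    """

    termination: float = 1.0       # s
    n_steps: int = 2000
    dt_scale: float = 0.25
    damping: Optional[float] = None   # 1/s
    out_stride: Optional[int] = None
    seed: int = 0

    @property
    def dt(self) -> float:
        return self.termination / self.n_steps


@dataclass
class LoadCase:
    """Pressure table (mmHg), prescribed trajectories and fixed node sets."""

    pressure_times: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    pressure_mmhg: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    pressure_faces: Optional[np.ndarray] = None    # (nf, 4) node ids
    trajectory: Optional[BoundaryTrajectory] = None
    #: which coordinates the trajectory prescribes (others stay free)
    trajectory_dofs: Sequence[bool] = (True, True, True)
    fixed_sets: Sequence[str] = ("lateral_left", "lateral_right")
    fixed_node_ids: Optional[np.ndarray] = None
    #: plane-strain constraint through the extrusion: the 10-um slab stands
    #: in for a slice of a much wider structure, so out-of-plane motion is
    #: suppressed (otherwise the near-incompressible tissue escapes in z)
    plane_strain_z: bool = False


@dataclass
class SimulationResult:
    times: np.ndarray                # (nf,)
    x_frames: np.ndarray             # (nf, nn, 3) mm
    xb_frames: np.ndarray            # (nf, nb, 3)
    sig_frames: np.ndarray           # (nf, ne, 6) element-mean stress, MPa
    sigb_frames: np.ndarray          # (nf, ns, 6) beam segment-mean stress
    energies: np.ndarray             # (nf, 3): kinetic, internal, external
    x0: np.ndarray                   # (nn, 3) reference coordinates
    xb0: np.ndarray
    quasi_static: bool = True
    log: dict = field(default_factory=dict)

    def displacements(self) -> np.ndarray:
        return self.x_frames - self.x0[None, :, :]

    def node_trajectory(self, node_ids) -> BoundaryTrajectory:
        ids = np.asarray(node_ids, dtype=np.int64)
        return BoundaryTrajectory(self.times, ids, self.x_frames[:, ids, :])


def _material_table(materials: Dict[int, ViscoelasticParams], dt: float):
    """Stack materials into the kernel coefficient table."""
    tags = sorted(materials)
    index = {t: i for i, t in enumerate(tags)}
    coef = np.zeros((len(tags), 5))
    for t, i in index.items():
        p = materials[t]
        decay, ramp, g_eff, k = stress_update_coefficients(p, dt)
        coef[i] = [decay, (p.g0 - p.ginf) * ramp, 2.0 * p.ginf, k, g_eff]
    return index, coef


def _beam_stiffness_probe(xb, ye, yz, segs, seg_mat, coef, offsets, wts,
                          delta: float = 1.0e-7):
    """Nodal stiffness bounds for beam translations/rotations (N/mm, N*mm).

    Applies sign-alternating unit-axis perturbations through the element
    kernel and reads back |force|/delta and |moment|/delta.  Alternating
    signs between neighbouring nodes excite the stiffest local deformation
    modes, giving a Gershgorin-style bound for the mass scaling.
    """
    nb = xb.shape[0]
    k_trans = np.zeros(nb)
    k_rot = np.zeros(nb)
    alternating = np.where(np.arange(nb) % 2 == 0, 1.0, -1.0)
    uniform = np.ones(nb)
    # (rotational?, sign field); the uniform rotation field excites the
    # fiber-tilt (transverse shear) mode that alternating signs cancel
    probes = [(False, alternating), (True, alternating), (True, uniform)]
    for ax in range(3):
        for rotational, signs in probes:
            dub = np.zeros((nb, 3))
            dth = np.zeros((nb, 3))
            if rotational:
                dth[:, ax] = signs * delta
            else:
                dub[:, ax] = signs * delta
            d_ye = np.zeros((nb, 3))
            d_yz = np.zeros((nb, 3))
            fb = np.zeros((nb, 3))
            mbm = np.zeros((nb, 3))
            sig_p = np.zeros((segs.shape[0], offsets.shape[0], 6))
            h_p = np.zeros_like(sig_p)
            _kernels.beam_step(
                xb.copy(), dub, dth, ye.copy(), yz.copy(), d_ye, d_yz,
                segs, seg_mat, coef, offsets, wts, sig_p, h_p, fb, mbm,
            )
            if rotational:
                k_rot = np.maximum(k_rot, np.abs(mbm).max(axis=1) / delta)
            else:
                k_trans = np.maximum(k_trans, np.abs(fb).max(axis=1) / delta)
    return k_trans, k_rot


def _stiffness_estimates(mesh: HexMesh, materials: Dict[int, ViscoelasticParams]):
    """Per-node translational stiffness bound (N/mm) for mass scaling."""
    xe = mesh.element_coords()
    vol = mesh.volumes()
    edge_min = np.full(mesh.n_elements, np.inf)
    from .meshing import _EDGES

    for a, b in _EDGES:
        edge_min = np.minimum(edge_min, np.linalg.norm(xe[:, b] - xe[:, a], axis=1))
    k_node = np.zeros(mesh.n_nodes)
    for e in range(mesh.n_elements):
        p = materials[int(mesh.tissue_tag[e])]
        m_mod = p.bulk_modulus + 4.0 * p.g0 / 3.0
        k_e = m_mod * vol[e] / edge_min[e] ** 2
        k_node[mesh.elements[e]] += k_e
    return k_node


def run(
    mesh: HexMesh,
    materials: Dict[int, ViscoelasticParams],
    load: LoadCase,
    config: SimulationConfig,
    beams=None,
    beam_materials: Optional[Dict[int, ViscoelasticParams]] = None,
    coupling: Optional[CouplingSet] = None,
) -> SimulationResult:
    """Run the explicit forward model to ``config.termination`` seconds."""
    dt = config.dt
    gamma = config.dt_scale
    nn = mesh.n_nodes

    all_mats = dict(materials)
    beam_tag_offset = 100   # beam groups live in a disjoint tag namespace
    if beams is not None:
        if beam_materials is None or coupling is None:
            raise ValueError("beams require beam_materials and a coupling set")
        for t, p in beam_materials.items():
            all_mats[beam_tag_offset + t] = p
    index, coef = _material_table(all_mats, dt)
    mat_id = np.array([index[int(t)] for t in mesh.tissue_tag], dtype=np.int64)

    # mass scaling: element frequency = gamma/dt everywhere
    k_node = _stiffness_estimates(mesh, materials)

    # beams
    if beams is not None:
        nb = beams.n_points
        xb = beams.control_points.copy()
        segs = beams.segments
        seg_mat = np.array(
            [index[beam_tag_offset + int(t)] for t in beams.group_tag], dtype=np.int64
        )
        from .beams import BeamSection

        section = BeamSection(r_outer=beams.r_outer, r_inner=beams.r_inner)
        offsets = section.offsets
        wts = section.weights
        sig_b = np.zeros((segs.shape[0], offsets.shape[0], 6))
        h_b = np.zeros_like(sig_b)
        ye = np.zeros((nb, 3))
        yz = np.zeros((nb, 3))
        # section vectors: eta ~ global y-ish, zeta ~ axis x eta
        seg_of_node = {}
        axis_dir = np.zeros((nb, 3))
        for s, (a, b) in enumerate(segs):
            d = xb[b] - xb[a]
            d /= np.linalg.norm(d)
            axis_dir[a] += d
            axis_dir[b] += d
        for n in range(nb):
            a = axis_dir[n]
            na = np.linalg.norm(a)
            a = a / na if na > 0 else np.array([1.0, 0.0, 0.0])
            ref = np.array([0.0, 0.0, 1.0])
            if abs(a @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e2 = np.cross(ref, a)
            e2 /= np.linalg.norm(e2)
            ye[n] = np.cross(a, e2)
            yz[n] = e2
        c_conn = mesh.elements[coupling.host_elem]
        c_w = coupling.weights
        c_k = coupling.stiffness
        # host nodes also see the penalty stiffness
        np.add.at(k_node, c_conn.ravel(), (c_w * c_k[:, None]).ravel())
        # beam nodal stiffness bounds measured numerically from the element
        # kernel (sign-alternating probes excite the stiffest local modes;
        # closed-form estimates miss the fiber-tilt coupling at curve kinks)
        k_trans, k_rot = _beam_stiffness_probe(
            xb, ye, yz, segs, seg_mat, coef, offsets, wts
        )
        safety = 6.0
        k_b = c_k + safety * k_trans
        # floor: isolated control points still carry the penalty spring
        mb = np.maximum(k_b, 1e-30) * (dt / gamma) ** 2
        ib = np.maximum(safety * k_rot, 1e-12 * np.max(k_rot) + 1e-300)
        ib = ib * (dt / gamma) ** 2 + 1e-300
        vb = np.zeros((nb, 3))
        wb = np.zeros((nb, 3))
    else:
        nb = 0
        xb = np.zeros((0, 3))
        segs = np.zeros((0, 2), dtype=np.int64)
        seg_mat = np.zeros(0, dtype=np.int64)
        offsets = np.zeros((0, 2))
        wts = np.zeros(0)
        sig_b = np.zeros((0, 0, 6))
        h_b = np.zeros((0, 0, 6))
        ye = np.zeros((0, 3))
        yz = np.zeros((0, 3))
        c_conn = np.zeros((0, 8), dtype=np.int64)
        c_w = np.zeros((0, 8))
        c_k = np.zeros(0)
        mb = np.zeros(0)
        ib = np.zeros(0)
        vb = np.zeros((0, 3))
        wb = np.zeros((0, 3))

    mass = np.maximum(k_node, 1e-30) * (dt / gamma) ** 2

    # boundary conditions
    fixed_mask = np.zeros((nn, 3), dtype=np.uint8)
    for name in load.fixed_sets:
        if name in mesh.node_sets:
            fixed_mask[mesh.node_sets[name]] = 1
    if load.fixed_node_ids is not None:
        fixed_mask[np.asarray(load.fixed_node_ids, dtype=np.int64)] = 1
    if load.plane_strain_z:
        fixed_mask[:, 2] = 1

    if load.trajectory is not None:
        presc_ids = load.trajectory.node_ids
        presc_t = load.trajectory.times
        presc_x = load.trajectory.coords
        presc_dof = np.asarray(load.trajectory_dofs, dtype=np.uint8)
    else:
        presc_ids = np.zeros(0, dtype=np.int64)
        presc_t = np.array([0.0, config.termination])
        presc_x = np.zeros((2, 0, 3))
        presc_dof = np.ones(3, dtype=np.uint8)

    faces = load.pressure_faces
    if faces is None:
        faces = np.zeros((0, 4), dtype=np.int64)
    p_times = np.asarray(load.pressure_times, dtype=float)
    p_vals = np.asarray(load.pressure_mmhg, dtype=float) * MMHG_TO_MPA

    # damping: roughly critical for the lowest structural mode
    if config.damping is None:
        meta = mesh.meta
        n_span = max(meta.get("nx", 0), meta.get("ny", 0)) or max(
            2, int(round(mesh.n_elements ** (1.0 / 2.0)))
        )
        omega1 = gamma / (dt * n_span)
        alpha = 2.0 * omega1
    else:
        alpha = config.damping

    out_stride = config.out_stride
    if out_stride is None:
        out_stride = max(1, config.n_steps // 50)
    n_out = config.n_steps // out_stride + (1 if config.n_steps % out_stride else 0)

    frames_x = np.zeros((n_out, nn, 3))
    frames_xb = np.zeros((n_out, nb, 3))
    frames_t = np.zeros(n_out)
    frames_sig = np.zeros((n_out, mesh.n_elements, 6))
    frames_sigb = np.zeros((n_out, segs.shape[0], 6))
    energies = np.zeros((n_out, 3))

    x = mesh.nodes.copy()
    v = np.zeros((nn, 3))
    sigma = np.zeros((mesh.n_elements, 8, 6))
    hmem = np.zeros_like(sigma)

    status, n_written = _kernels.run_loop(
        x, v, mass, fixed_mask,
        mesh.elements, mat_id, coef, _GAUSS_DN, sigma, hmem,
        xb, vb, wb, mb, ib, ye, yz,
        segs, seg_mat, sig_b, h_b, offsets, wts,
        c_conn, c_w, c_k,
        faces, p_times, p_vals,
        presc_ids, presc_t, presc_x, presc_dof,
        dt, config.n_steps, alpha, out_stride,
        frames_x, frames_xb, frames_t, frames_sig, frames_sigb, energies,
    )
    if status == 1:
        raise SolverError(
            "energy blow-up (kinetic > 10 x internal); reduce dt_scale or "
            "increase n_steps"
        )

    ke, ei = energies[-1, 0], energies[-1, 1]
    quasi_static = bool(ke < 0.01 * abs(ei) + 1e-15)
    return SimulationResult(
        times=frames_t,
        x_frames=frames_x,
        xb_frames=frames_xb,
        sig_frames=frames_sig,
        sigb_frames=frames_sigb,
        energies=energies,
        x0=mesh.nodes.copy(),
        xb0=xb if nb == 0 else beams.control_points.copy(),
        quasi_static=quasi_static,
        log={
            "dt": dt,
            "alpha_damping": alpha,
            "n_steps": config.n_steps,
            "mass_scaled": True,
            "element_frequency": gamma / dt,
        },
    )


# ---------------------------------------------------------------------------
# python reference operations (dual route for the kernels; used in tests)
# ---------------------------------------------------------------------------


def hex_internal_force(xe, du, states, material: ViscoelasticParams, dt: float):
    """Internal nodal forces of one hexahedron after a displacement increment.

    Full 2x2x2 integration; strain/spin from the mid-step configuration.
    ``states`` is a list of 8 :class:`StressState`, updated in place.
    Returns a (8, 3) force array.  Raises on non-positive Jacobians.
    """
    xe = np.asarray(xe, dtype=float)
    du = np.asarray(du, dtype=float)
    x_mid = xe + 0.5 * du
    f = np.zeros((8, 3))
    for g in range(8):
        dn = _GAUSS_DN[g]
        jac = np.einsum("ai,aj->ij", x_mid, dn)
        detj = np.linalg.det(jac)
        if detj <= 0:
            raise SolverError(f"inverted element at integration point {g}")
        gy = dn @ np.linalg.inv(jac)
        grad = np.einsum("ai,aj->ij", du, gy)
        d_eps = 0.5 * (grad + grad.T)
        d_omega = 0.5 * (grad - grad.T)
        states[g] = update_stress(states[g], d_eps, d_omega, dt, material)
        sig = voigt_to_tensor(states[g].sigma)
        f += np.einsum("ij,aj->ai", sig, gy) * detj
    return f


def apply_pressure(coords, faces, p_mpa: float):
    """Follower pressure nodal forces: -p * area * normal per quad face."""
    coords = np.asarray(coords, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    f = np.zeros_like(coords)
    for quad in faces:
        a, b, c, d = quad
        av = 0.5 * np.cross(coords[c] - coords[a], coords[d] - coords[b])
        if np.linalg.norm(av) == 0.0:
            raise ValueError(f"degenerate pressure face {quad}")
        for nd in quad:
            f[nd] += -p_mpa * av / 4.0
    return f


def apply_floating_displacement(trajectory: BoundaryTrajectory, t: float):
    """Prescribed nodal positions at time ``t`` by linear interpolation."""
    times = trajectory.times
    if t < times[0] - 1e-12 or t > times[-1] + 1e-12:
        raise ValueError(
            f"time {t} outside trajectory range [{times[0]}, {times[-1]}]"
        )
    out = np.empty((trajectory.node_ids.size, 3))
    for i in range(3):
        for k in range(trajectory.node_ids.size):
            out[k, i] = np.interp(t, times, trajectory.coords[:, k, i])
    return out


def probe_average_displacement(result: SimulationResult, node_sets):
    """Set-averaged displacement magnitude time series, plus the pooled mean.

    ``node_sets`` is a sequence of node-id arrays.  Returns ``(per_set,
    pooled)`` with shapes (n_sets, n_frames) and (n_frames,).
    """
    sets = [np.asarray(s, dtype=np.int64) for s in node_sets]
    if any(s.size == 0 for s in sets):
        raise ValueError("probe node sets must be non-empty")
    disp = result.displacements()
    per_set = np.empty((len(sets), result.times.size))
    for i, s in enumerate(sets):
        mag = np.linalg.norm(disp[:, s, :], axis=2)
        per_set[i] = mag.mean(axis=1)
    return per_set, per_set.mean(axis=0)
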