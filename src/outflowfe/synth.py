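"""Synthetic stand-ins for the unpublished experimental inputs.

Every input the calibration pipeline consumes but that was never published
is generated here with known ground truth: OCT-like cross-section
boundaries, boundary-motion trajectories from forward simulation, specimen
stress-strain curves, TM-displacement-vs-pressure curves and SC-lumen
cross-section point clouds.  Same seed, same bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .material import ViscoelasticParams
from .meshing import (
    BeamNetwork,
    GeometryError,
    HexMesh,
    TissueTag,
    extrude_and_mesh,
    make_probe_sets,
    partition_layers,
    distribute_beams,
)
from .beams import couple_beams_to_solid
from .solver import (
    BoundaryTrajectory,
    LoadCase,
    SimulationConfig,
    SimulationResult,
    run,
)
from .tables import ground_truth_set, GROUP_TO_TAG, ECM_GROUPS, BEAM_GROUPS
from .units import UM_TO_MM, MM_TO_UM

__all__ = [
    "SyntheticScene",
    "LoadProtocol",
    "generate_scene",
    "generate_specimen_curve",
    "generate_boundary_trajectory",
    "generate_sc_lumen_stack",
    "build_complex_model",
    "build_patch_model",
    "simulate_trajectory",
    "JCT_THICKNESS_UM",
    "SC_WALL_THICKNESS_UM",
]

JCT_THICKNESS_UM = 14.0
SC_WALL_THICKNESS_UM = 2.2
SC_LUMEN_UM = 30.0

BOUNDARY_LABELS = (
    "TM_anterior",
    "TM_posterior",
    "JCT_band",
    "SC_inner_wall",
    "SC_outer_wall",
)


@dataclass
class SyntheticScene:
    seed: int
    boundaries: Dict[str, np.ndarray]            # label -> (n, 2) um
    ground_truth: Dict[str, ViscoelasticParams]  # group name -> params
    noise_sd: float = 0.0                        # um

    def boundary(self, label: str) -> np.ndarray:
        return self.boundaries[label]


@dataclass
class LoadProtocol:
    """Pressure/strain protocol.  1 mmHg = 133.322 Pa = 1.33322e-4 MPa.

    ``hold`` appends a constant-load dwell after the ramp, which adds
    relaxation content to the response (useful for identifiability).
    """

    kind: str = "sc_pressure_ramp"               # sc_pressure_ramp | iop_ramp | uniaxial_strain
    p_start: float = 0.0
    p_end: float = 30.0                          # mmHg (or strain for uniaxial)
    duration: float = 1.0                        # s (ramp length)
    hold: float = 0.0                            # s

    def __post_init__(self):
        if self.kind not in ("sc_pressure_ramp", "iop_ramp", "uniaxial_strain"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("protocol duration must be positive")

    @property
    def total_time(self) -> float:
        return self.duration + self.hold

    def table(self):
        """(times, values) table for the solver (monotone within the ramp)."""
        if self.hold > 0:
            return (
                np.array([0.0, self.duration, self.total_time]),
                np.array([self.p_start, self.p_end, self.p_end]),
            )
        return np.array([0.0, self.duration]), np.array([self.p_start, self.p_end])


def generate_scene(
    seed: int,
    width_um: float = 400.0,
    waviness: float = 0.1,
    tm_depth_um: Optional[float] = None,
    ground_truth: Optional[Dict[str, ViscoelasticParams]] = None,
    noise_sd: float = 0.0,
) -> SyntheticScene:
    """OCT-like cross-section geometry with known ground truth.

    The TM band is 60-120 um deep and undulates with the given waviness
    (amplitude as a fraction of the depth).  Boundaries are ordered
    monotonically in depth; the JCT band is 14 um and the SC inner wall
    2.2 um thick by construction.  Ground truth defaults to the healthy
    115LF parameter set from the fixtures.
    """
    if width_um < 100:
        raise ValueError("width_um must be >= 100")
    if not (0.0 <= waviness <= 0.3):
        raise ValueError("waviness must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    if tm_depth_um is None:
        tm_depth_um = float(rng.uniform(70.0, 110.0))
    if not (60.0 <= tm_depth_um <= 120.0):
        raise ValueError("tm_depth_um must lie in [60, 120]")

    n_pts = max(24, int(width_um / 5.0))
    x = np.linspace(0.0, width_um, n_pts)

    def undulation():
        y = np.zeros_like(x)
        for k in range(1, 4):
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.3, 1.0) / k
            y += amp * np.sin(2 * np.pi * k * x / width_um + phase)
        m = np.abs(y).max()
        return y / m if m > 0 else y

    base = 40.0
    y_ant = base + waviness * 0.5 * tm_depth_um * undulation()
    depth = tm_depth_um * (1.0 + 0.3 * waviness * undulation())
    depth = np.clip(depth, 60.0, 120.0)
    if waviness == 0.0:
        y_ant = np.full_like(x, base)
        depth = np.full_like(x, tm_depth_um)

    y_post = y_ant + depth
    y_jct = y_post + JCT_THICKNESS_UM
    y_scw = y_jct + SC_WALL_THICKNESS_UM
    y_out = y_scw + SC_LUMEN_UM

    boundaries = {
        "TM_anterior": np.column_stack([x, y_ant]),
        "TM_posterior": np.column_stack([x, y_post]),
        "JCT_band": np.column_stack([x, y_jct]),
        "SC_inner_wall": np.column_stack([x, y_scw]),
        "SC_outer_wall": np.column_stack([x, y_out]),
    }
    if ground_truth is None:
        ground_truth = ground_truth_set("115LF")
    return SyntheticScene(
        seed=seed, boundaries=boundaries, ground_truth=ground_truth, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def build_complex_model(
    scene: SyntheticScene,
    edge_um: float = 4.0,
    beam_planar_spacing_um: float = 4.0,
    beam_thickness_spacing_um: float = 2.5,
    beam_r_outer_um: float = 0.5,
    penalty_scale: float = 100.0,
    probe_seed: int = 0,
):
    """Mesh + partition + beams + coupling for the TM/JCT/SC-wall complex.

    The mesh is graded so the SC inner wall band is exactly one element row
    (2.2 um) and the JCT band two rows.
    """
    mesh = extrude_and_mesh(
        scene.boundaries,
        target_edge_um=edge_um,
        bottom_row_heights_um=[SC_WALL_THICKNESS_UM, JCT_THICKNESS_UM / 2, JCT_THICKNESS_UM / 2],
    )
    partition_layers(mesh, JCT_THICKNESS_UM, SC_WALL_THICKNESS_UM)
    beams = distribute_beams(
        mesh,
        planar_spacing_um=beam_planar_spacing_um,
        thickness_spacing_um=beam_thickness_spacing_um,
        r_outer_um=beam_r_outer_um,
    )
    coupling = couple_beams_to_solid(beams, mesh, penalty_scale=penalty_scale)
    make_probe_sets(mesh, seed=probe_seed)
    return mesh, beams, coupling


def materials_from_groups(groups: Dict[str, ViscoelasticParams]):
    """Split a group-name parameter map into solid and beam material dicts."""
    solids = {GROUP_TO_TAG[g]: p for g, p in groups.items() if g in ECM_GROUPS}
    beams = {GROUP_TO_TAG[g]: p for g, p in groups.items() if g in BEAM_GROUPS}
    return solids, beams


def simulate_trajectory(
    mesh: HexMesh,
    beams: BeamNetwork,
    coupling,
    groups: Dict[str, ViscoelasticParams],
    protocol: LoadProtocol,
    n_frames: int,
    n_steps: int = 2000,
    tracked_sets=("sc_inner_wall_track", "tm_anterior"),
    drive_trajectory: Optional[BoundaryTrajectory] = None,
    damping: Optional[float] = None,
) -> BoundaryTrajectory:
    """Forward-run the complex model and sample tracked boundary nodes.

    ``drive_trajectory`` optionally prescribes measured boundary-node
    motion (floating displacement boundary condition) on a subset of nodes
    while the SC pressure acts; this is how the inverse stage replays the
    recorded anterior-boundary data.
    """
    if protocol.kind != "sc_pressure_ramp":
        raise ValueError("complex model is driven by the SC pressure ramp")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    solids, beam_mats = materials_from_groups(groups)
    if TissueTag.SCLERA in set(int(t) for t in mesh.tissue_tag):
        solids.setdefault(TissueTag.SCLERA, ViscoelasticParams.from_youngs(2.93, 0.495))
    times, values = protocol.table()
    load = LoadCase(
        pressure_times=times,
        pressure_mmhg=values,
        pressure_faces=mesh.pressure_faces,
        trajectory=drive_trajectory,
        trajectory_dofs=(True, True, False),
        fixed_sets=("lateral_left", "lateral_right"),
        plane_strain_z=True,
    )
    config = SimulationConfig(
        termination=protocol.total_time,
        n_steps=n_steps,
        damping=damping,
        out_stride=max(1, n_steps // max(2 * n_frames, 40)),
    )
    result = run(mesh, solids, load, config, beams=beams,
                 beam_materials=beam_mats, coupling=coupling)

    ids = np.concatenate([mesh.node_sets[name] for name in tracked_sets])
    frame_times = np.linspace(0.0, protocol.total_time, n_frames)
    coords = np.empty((n_frames, ids.size, 3))
    # include the t=0 reference frame explicitly
    rec_t = np.concatenate([[0.0], result.times])
    rec_x = np.concatenate([mesh.nodes[None, ids, :], result.x_frames[:, ids, :]])
    for i in range(3):
        for k in range(ids.size):
            coords[:, k, i] = np.interp(frame_times, rec_t, rec_x[:, k, i])
    return BoundaryTrajectory(times=frame_times, node_ids=ids, coords=coords)


def generate_boundary_trajectory(
    scene: SyntheticScene,
    protocol: LoadProtocol,
    n_frames: Optional[int] = None,
    edge_um: float = 4.0,
    n_steps: int = 2000,
    model=None,
) -> BoundaryTrajectory:
    """Ground-truth boundary motion plus optional i.i.d. Gaussian noise.

    The default frame rate is 30 frames/s.  ``model`` may carry a prebuilt
    ``(mesh, beams, coupling)`` triple to avoid re-meshing.
    """
    if n_frames is None:
        n_frames = max(2, int(round(30.0 * protocol.total_time)))
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if model is None:
        model = build_complex_model(scene, edge_um=edge_um)
    mesh, beams, coupling = model
    traj = simulate_trajectory(
        mesh, beams, coupling, scene.ground_truth, protocol, n_frames, n_steps=n_steps
    )
    if scene.noise_sd > 0.0:
        rng = np.random.default_rng(scene.seed + 7919)
        noise = rng.normal(0.0, scene.noise_sd * UM_TO_MM, size=traj.coords.shape)
        noise[..., 2] = 0.0          # planar (B-scan) noise only
        traj = BoundaryTrajectory(traj.times, traj.node_ids, traj.coords + noise)
    return traj


# ---------------------------------------------------------------------------
# specimen (uniaxial) model
# ---------------------------------------------------------------------------

SPECIMEN_L_MM = 10.0
SPECIMEN_W_MM = 0.24
SPECIMEN_T_MM = 0.136
#: fiber area fraction equivalent to the 4 x 2.5 um control-point lattice
#: with 0.5 um fiber radius
SPECIMEN_FIBER_FRACTION = np.pi * 0.5e-3**2 / (4e-3 * 2.5e-3)


def _specimen_model(nx: int = 12, ny: int = 2, n_fib_y: int = 3, n_fib_z: int = 2,
                    fiber_fraction: float = SPECIMEN_FIBER_FRACTION):
    """Coarse specimen bar with area-equivalent axial fibers.

    Desk-scale stand-in for the full-density fiber lattice: a handful of
    fibers whose total cross-section area preserves the lattice's fiber
    area fraction (rule-of-mixtures equivalent).
    """
    from .meshing import box_mesh

    mesh = box_mesh(SPECIMEN_L_MM, SPECIMEN_W_MM, SPECIMEN_T_MM, nx, ny, 1)
    n_fib = n_fib_y * n_fib_z
    r_eq = np.sqrt(fiber_fraction * SPECIMEN_W_MM * SPECIMEN_T_MM / (n_fib * np.pi))
    xs = np.linspace(0.05 * SPECIMEN_L_MM, 0.95 * SPECIMEN_L_MM, nx + 1)
    ys = np.linspace(0, SPECIMEN_W_MM, n_fib_y + 2)[1:-1]
    zs = np.linspace(0, SPECIMEN_T_MM, n_fib_z + 2)[1:-1]
    pts = []
    segs = []
    for y in ys:
        for z in zs:
            start = len(pts)
            for x in xs:
                pts.append([x, y, z])
            for i in range(len(xs) - 1):
                segs.append([start + i, start + i + 1])
    beams = BeamNetwork(
        control_points=np.asarray(pts),
        segments=np.asarray(segs, dtype=np.int64),
        group_tag=np.full(len(segs), TissueTag.TM, dtype=np.int64),
        r_outer=r_eq,
        meta={"fiber_fraction": fiber_fraction},
    )
    coupling = couple_beams_to_solid(beams, mesh, penalty_scale=100.0)
    return mesh, beams, coupling


def generate_specimen_curve(
    params_ecm: ViscoelasticParams,
    params_beam: ViscoelasticParams,
    strain_max: float = 0.02,
    n_points: int = 21,
    duration: float = 0.02,
    n_steps: int = 1200,
    model=None,
):
    """Gauge stress-strain curve of the uniaxial TM specimen model.

    The bar (10 x 0.24 x 0.136 mm) is stretched to ``strain_max`` over
    ``duration`` seconds; gauge stress is the mean axial stress in the
    central elements.  Returns an (n_points, 2) array of (strain, stress).
    """
    if not (0.0 < strain_max <= 0.02):
        raise ValueError("strain_max must lie in (0, 0.02]")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if model is None:
        model = _specimen_model()
    mesh, beams, coupling = model

    # affine axial stretch: the x coordinate of every node follows the
    # nominal strain ramp (transverse dofs stay free so the Poisson
    # contraction develops); this realises a homogeneous uniaxial state in
    # the gauge without end-grip artifacts
    all_ids = np.arange(mesh.n_nodes)
    t_table = np.array([0.0, duration])
    coords = np.stack([mesh.nodes, mesh.nodes.copy()])
    coords[1, :, 0] *= 1.0 + strain_max
    traj = BoundaryTrajectory(times=t_table, node_ids=all_ids, coords=coords)
    load = LoadCase(
        pressure_faces=None,
        trajectory=traj,
        trajectory_dofs=(True, False, False),
        fixed_sets=(),
    )
    config = SimulationConfig(
        termination=duration, n_steps=n_steps,
        out_stride=max(1, n_steps // 120),
    )
    result = run(
        mesh,
        {TissueTag.TM: params_ecm},
        load,
        config,
        beams=beams,
        beam_materials={TissueTag.TM: params_beam},
        coupling=coupling,
    )
    if not np.all(np.isfinite(result.energies)):
        raise RuntimeError("specimen simulation diverged (non-finite energies)")

    cen = mesh.centroids()
    gauge = np.flatnonzero(np.abs(cen[:, 0] - SPECIMEN_L_MM / 2) < SPECIMEN_L_MM / 6)
    seg_mid = 0.5 * (
        beams.control_points[beams.segments[:, 0]]
        + beams.control_points[beams.segments[:, 1]]
    )
    gauge_segs = np.flatnonzero(np.abs(seg_mid[:, 0] - SPECIMEN_L_MM / 2) < SPECIMEN_L_MM / 6)
    # composite gauge stress: rule of mixtures of ECM and fiber axial stress
    vf = beams.meta["fiber_fraction"]
    sig_ecm = result.sig_frames[:, gauge, 0].mean(axis=1)
    sig_fib = result.sigb_frames[:, gauge_segs, 0].mean(axis=1)
    rec_t = np.concatenate([[0.0], result.times])
    strain_t = np.interp(rec_t, t_table, [0.0, strain_max])
    stress_t = np.concatenate([[0.0], (1.0 - vf) * sig_ecm + vf * sig_fib])

    s_grid = np.linspace(0.0, strain_max, n_points)
    times_of_strain = np.interp(s_grid, strain_t, rec_t)
    sig_grid = np.interp(times_of_strain, rec_t, stress_t)
    curve = np.column_stack([s_grid, sig_grid])
    curve[0] = (0.0, 0.0)
    return curve


# ---------------------------------------------------------------------------
# IOP-ramp patch model (beta stage)
# ---------------------------------------------------------------------------


def build_patch_model(
    seed: int = 0,
    width_um: float = 120.0,
    tm_depth_um: float = 80.0,
    sclera_thickness_um: float = 12.0,
    edge_um: float = 8.0,
    beam_planar_spacing_um: float = 8.0,
    beam_thickness_spacing_um: float = 2.5,
):
    """TM patch anchored on a scleral band, pressurised on the anterior face.

    Returns ``(mesh, beams, coupling, probe_sets)``.  The scleral band sits
    on the posterior side and is tagged SCLERA (elastic, E = 2.93 MPa,
    nu = 0.495); pressure faces are the anterior surface.
    """
    scene = generate_scene(
        seed, width_um=width_um, waviness=0.0, tm_depth_um=tm_depth_um
    )
    boundaries = {
        "TM_anterior": scene.boundaries["TM_anterior"],
        # mesh only TM + sclera band: reuse the band mesher with a fake
        # SC-facing boundary at the bottom of the scleral band
        "SC_inner_wall": scene.boundaries["TM_posterior"].copy(),
    }
    boundaries["SC_inner_wall"][:, 1] += sclera_thickness_um
    mesh = extrude_and_mesh(
        boundaries,
        target_edge_um=edge_um,
        bottom_row_heights_um=[sclera_thickness_um / 2, sclera_thickness_um / 2],
    )
    # tag: scleral band = elements within the bottom band
    partition_layers(mesh, jct_thickness_um=0.0, sc_thickness_um=sclera_thickness_um)
    tag = mesh.tissue_tag
    tag[tag == TissueTag.SC_WALL] = TissueTag.SCLERA
    mesh.tissue_tag = tag
    mesh.meta["sc_thickness_um"] = sclera_thickness_um  # keep beams out of sclera
    beams = distribute_beams(
        mesh,
        planar_spacing_um=beam_planar_spacing_um,
        thickness_spacing_um=beam_thickness_spacing_um,
    )
    coupling = couple_beams_to_solid(beams, mesh, penalty_scale=100.0)
    probe_sets = make_probe_sets(mesh, seed=seed)
    mesh.pressure_faces = mesh.meta["anterior_faces"]
    return mesh, beams, coupling, probe_sets


def generate_iop_displacement_curve(
    groups: Dict[str, ViscoelasticParams],
    protocol: Optional[LoadProtocol] = None,
    model=None,
    n_steps: int = 1500,
    n_points: int = 26,
    seed: int = 0,
):
    """TM displacement vs IOP from the patch model (probe-set average).

    Returns an (n_points, 2) array of (IOP mmHg, mean displacement um).
    """
    from .solver import probe_average_displacement

    if protocol is None:
        protocol = LoadProtocol(kind="iop_ramp", p_start=0.0, p_end=50.0, duration=1.0)
    if model is None:
        model = build_patch_model(seed=seed)
    mesh, beams, coupling, probe_sets = model
    solids = {
        TissueTag.TM: groups["TM"],
        TissueTag.SCLERA: ViscoelasticParams.from_youngs(2.93, 0.495),
    }
    beam_mats = {TissueTag.TM: groups["TM_beam"]}
    times, values = protocol.table()
    load = LoadCase(
        pressure_times=times,
        pressure_mmhg=values,
        pressure_faces=mesh.pressure_faces,
        fixed_sets=("lateral_left", "lateral_right"),
    )
    config = SimulationConfig(
        termination=protocol.total_time, n_steps=n_steps,
        out_stride=max(1, n_steps // 100),
    )
    result = run(mesh, solids, load, config, beams=beams,
                 beam_materials=beam_mats, coupling=coupling)
    _, pooled = probe_average_displacement(result, probe_sets)
    rec_t = np.concatenate([[0.0], result.times])
    rec_d = np.concatenate([[0.0], pooled]) * MM_TO_UM
    p_of_t = np.interp(rec_t, times, values)
    p_grid = np.linspace(values[0], values.max(), n_points)
    # displacement sampled at the ramp times for each pressure level
    t_of_p = np.interp(p_grid, p_of_t[: len(rec_t)], rec_t)
    d_grid = np.interp(t_of_p, rec_t, rec_d)
    return np.column_stack([p_grid, d_grid])


# ---------------------------------------------------------------------------
# SC lumen sections
# ---------------------------------------------------------------------------


def generate_sc_lumen_stack(
    radius_um: float,
    n_sections: int = 4,
    jitter_sd: float = 0.0,
    n_points: int = 36,
    seed: int = 0,
) -> List[np.ndarray]:
    """Cross-section point clouds of a circular SC lumen with radial jitter."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    n_points = max(24, n_points)
    rng = np.random.default_rng(seed)
    sections = []
    for _ in range(n_sections):
        theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
        r = radius_um + (rng.normal(0.0, jitter_sd, n_points) if jitter_sd > 0 else 0.0)
        sections.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return sections


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def trajectory_to_csv(traj: BoundaryTrajectory, path):
    """One row per node per frame: frame, time_s, node_id, x_um, y_um."""
    import pandas as pd

    rows = []
    for f in range(traj.n_frames):
        for k, nid in enumerate(traj.node_ids):
            rows.append(
                (f, traj.times[f], int(nid),
                 traj.coords[f, k, 0] * MM_TO_UM, traj.coords[f, k, 1] * MM_TO_UM)
            )
    pd.DataFrame(rows, columns=["frame", "time_s", "node_id", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def trajectory_from_csv(path) -> BoundaryTrajectory:
    import pandas as pd

    df = pd.read_csv(path)
    frames = np.sort(df["frame"].unique())
    ids = df[df["frame"] == frames[0]]["node_id"].to_numpy(dtype=np.int64)
    times = np.empty(frames.size)
    coords = np.zeros((frames.size, ids.size, 3))
    for i, f in enumerate(frames):
        d = df[df["frame"] == f]
        times[i] = d["time_s"].iloc[0]
        coords[i, :, 0] = d["x_um"].to_numpy() * UM_TO_MM
        coords[i, :, 1] = d["y_um"].to_numpy() * UM_TO_MM
    return BoundaryTrajectory(times=times, node_ids=ids, coords=coords)


def scene_to_yaml(scene: SyntheticScene, path):
    import yaml

    doc = {
        "seed": scene.seed,
        "noise_sd_um": scene.noise_sd,
        "boundaries": {
            k: np.asarray(v).tolist() for k, v in scene.boundaries.items()
        },
        "ground_truth": {
            k: {"G0_MPa": p.g0, "Ginf_MPa": p.ginf, "beta_per_s": p.beta,
                "nu_vol": p.nu_vol}
            for k, p in scene.ground_truth.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def scene_from_yaml(path) -> SyntheticScene:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticScene(
        seed=int(doc["seed"]),
        boundaries={k: np.asarray(v, dtype=float) for k, v in doc["boundaries"].items()},
        ground_truth={
            k: ViscoelasticParams(v["G0_MPa"], v["Ginf_MPa"], v["beta_per_s"],
                                  v.get("nu_vol", 0.495))
            for k, v in doc["ground_truth"].items()
        },
        noise_sd=float(doc.get("noise_sd_um", 0.0)),
    )
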