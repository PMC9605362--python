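"""Boundary smoothing, hexahedral meshing, layer partition and quality audit.

The cross-section lives in the x-y plane (x along the tissue band, y the
depth coordinate running from the anterior TM surface toward the SC lumen)
and is extruded 10 um in z.  All mesh coordinates are stored in mm; public
entry points accept micrometres and convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .units import UM_TO_MM, MM_TO_UM

__all__ = [
    "TissueTag",
    "HexMesh",
    "BeamNetwork",
    "QualityReport",
    "GeometryError",
    "smooth_boundary",
    "extrude_and_mesh",
    "partition_layers",
    "distribute_beams",
    "element_quality",
    "critical_timestep",
    "fit_circle_diameter",
    "make_probe_sets",
    "EXTRUSION_THICKNESS_MM",
]

EXTRUSION_THICKNESS_MM = 0.010  # 10 um slab, exact by construction


class GeometryError(ValueError):
    pass


class TissueTag:
    TM = 0
    JCT = 1
    SC_WALL = 2
    SCLERA = 3

    NAMES = {TM: "TM", JCT: "JCT", SC_WALL: "SC_wall", SCLERA: "SCLERA"}


# Gauss 2x2x2 points/weights on the biunit cube and trilinear shape
# derivatives, shared by quality/volume integration.
_GP1 = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = np.array(
    [[sx * _GP1, sy * _GP1, sz * _GP1]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
# Node parametric signs in VTK hexahedron order.
_XI_A = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d(xi,eta,zeta) for the 8-noded hexahedron, shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        sa = _XI_A[a]
        g[a, 0] = sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 1] = sa[1] * (1 + sa[0] * xi[0]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 2] = sa[2] * (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1]) / 8.0
    return g


_GAUSS_DN = np.stack([shape_gradients(p) for p in _GAUSS_PTS])  # (8gp, 8a, 3)


@dataclass
class HexMesh:
    """8-noded hexahedral mesh with per-element tissue tags (mm units)."""

    nodes: np.ndarray                      # (nn, 3) mm
    elements: np.ndarray                   # (ne, 8) int
    tissue_tag: np.ndarray                 # (ne,) int, TissueTag values
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    pressure_faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]      # (ne, 8, 3)

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def corner_jacobians(self) -> np.ndarray:
        """det J at the 8 corners of every element, shape (ne, 8)."""
        xe = self.element_coords()
        dets = np.empty((self.n_elements, 8))
        for c in range(8):
            dn = shape_gradients(_XI_A[c])    # (8, 3)
            jac = np.einsum("eai,aj->eij", xe, dn)
            dets[:, c] = np.linalg.det(jac)
        return dets

    def volumes(self) -> np.ndarray:
        """Element volumes by 2x2x2 Gauss integration (mm^3)."""
        xe = self.element_coords()
        vol = np.zeros(self.n_elements)
        for g in range(8):
            jac = np.einsum("eai,aj->eij", xe, _GAUSS_DN[g])
            vol += np.linalg.det(jac)          # unit weights
        return vol


@dataclass
class BeamNetwork:
    """Fiber control points and 2-noded beam connectivity (mm units)."""

    control_points: np.ndarray             # (np, 3) mm
    segments: np.ndarray                   # (ns, 2) int
    group_tag: np.ndarray                  # (ns,) int, TissueTag of host
    r_outer: float = 0.5 * UM_TO_MM        # mm
    r_inner: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.control_points.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def section_area(self) -> float:
        return np.pi * (self.r_outer**2 - self.r_inner**2)


@dataclass
class QualityReport:
    min_angle: np.ndarray     # degrees, per element
    max_angle: np.ndarray
    aspect_ratio: np.ndarray
    volume_um3: np.ndarray

    def summary(self) -> dict:
        return {
            "min_angle_deg": (float(self.min_angle.min()), float(self.min_angle.mean())),
            "max_angle_deg": (float(self.max_angle.max()), float(self.max_angle.mean())),
            "aspect_ratio_max": float(self.aspect_ratio.max()),
            "volume_um3_range": (float(self.volume_um3.min()), float(self.volume_um3.max())),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "min_angle_deg": self.min_angle,
                "max_angle_deg": self.max_angle,
                "aspect_ratio": self.aspect_ratio,
                "volume_um3": self.volume_um3,
            }
        )


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------

def smooth_boundary(points, p: float, weights=None, n_out: Optional[int] = None):
    """Cubic smoothing spline through an ordered planar polyline.

    Minimises ``p * sum_i w_i (y_i - s(x_i))^2 + (1 - p) * int s''(x)^2 dx``
    (the MATLAB ``csaps`` parameterisation).  ``p = 1`` interpolates, ``p = 0``
    returns the weighted least-squares straight line.

    Returns ``(x_out, y_out, predict)`` where ``predict`` evaluates the
    smoothed curve at arbitrary abscissae.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need an (n, 2) array with n >= 4")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"smoothing parameter must lie in [0, 1], got {p}")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size != x.size:
        raise ValueError("duplicated abscissae in boundary points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)[order]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    if p == 0.0:
        coef = np.polyfit(x, y, 1, w=np.sqrt(w))
        predict = lambda xq: np.polyval(coef, np.asarray(xq, dtype=float))
    else:
        lam = (1.0 - p) / p
        spl = make_smoothing_spline(x, y, w=w, lam=lam)
        predict = lambda xq: spl(np.asarray(xq, dtype=float))

    if n_out is None:
        n_out = x.size
    x_out = np.linspace(x[0], x[-1], n_out)
    return x_out, predict(x_out), predict


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def extrude_and_mesh(boundaries: Dict[str, np.ndarray], target_edge_um: float = 4.0,
                     smooth_p: float = 0.999,
                     bottom_row_heights_um=None) -> HexMesh:
    """Transfinite hex mesh of the band between the anterior TM boundary and
    the SC-facing boundary, extruded 10 um out of plane (single layer).

    ``boundaries`` maps labels to (n, 2) polylines in micrometres; the labels
    ``TM_anterior`` and ``SC_inner_wall`` bound the meshed slab.

    ``bottom_row_heights_um`` optionally grades the mesh: explicit element
    row heights stacked upward from the SC-facing surface (e.g. ``[2.2, 7,
    7]`` puts one row in the SC inner wall band and two in the JCT); the
    remaining depth is filled with near-uniform rows of ``target_edge_um``.
    """
    if "TM_anterior" not in boundaries or "SC_inner_wall" not in boundaries:
        raise GeometryError("boundaries must include TM_anterior and SC_inner_wall")
    top = np.asarray(boundaries["TM_anterior"], dtype=float)
    bot = np.asarray(boundaries["SC_inner_wall"], dtype=float)

    _, _, f_top = smooth_boundary(top, smooth_p)
    _, _, f_bot = smooth_boundary(bot, smooth_p)

    x0 = max(top[:, 0].min(), bot[:, 0].min())
    x1 = min(top[:, 0].max(), bot[:, 0].max())
    width = x1 - x0
    if width <= 0:
        raise GeometryError("boundaries do not overlap in x")

    nx = max(2, int(round(width / target_edge_um)))
    xg = np.linspace(x0, x1, nx + 1)
    y_top = np.asarray(f_top(xg), dtype=float)
    y_bot = np.asarray(f_bot(xg), dtype=float)
    depth = y_bot - y_top
    if np.any(depth <= 0):
        raise GeometryError(
            "boundary pair (TM_anterior, SC_inner_wall) intersects: "
            "SC-facing boundary must lie below the anterior boundary everywhere"
        )
    if bottom_row_heights_um is None:
        ny = max(2, int(round(depth.mean() / target_edge_um)))
        s = np.linspace(0.0, 1.0, ny + 1)
        ygrid = y_top[None, :] * (1 - s[:, None]) + y_bot[None, :] * s[:, None]
    else:
        hb = np.asarray(bottom_row_heights_um, dtype=float)
        if np.any(hb <= 0):
            raise GeometryError("graded row heights must be positive")
        rem = depth - hb.sum()
        if np.any(rem <= 0):
            raise GeometryError("graded rows exceed the tissue depth")
        n_tm = max(1, int(round(rem.mean() / target_edge_um)))
        ny = n_tm + hb.size
        ygrid = np.empty((ny + 1, nx + 1))
        # uniform rows from the anterior surface down to the graded stack
        for j in range(n_tm + 1):
            ygrid[j] = y_top + rem * (j / n_tm)
        cum = np.cumsum(hb[::-1])
        for j in range(hb.size):
            ygrid[n_tm + 1 + j] = y_top + rem + cum[j]
    nn_plane = (nx + 1) * (ny + 1)
    nodes = np.empty((2 * nn_plane, 3))
    xs = np.broadcast_to(xg[None, :], ygrid.shape)
    plane = np.column_stack([xs.ravel(), ygrid.ravel(), np.zeros(nn_plane)])
    nodes[:nn_plane] = plane
    nodes[nn_plane:] = plane
    nodes[nn_plane:, 2] = EXTRUSION_THICKNESS_MM * MM_TO_UM  # still um here
    nodes *= UM_TO_MM

    def nid(i, j, k):
        return k * nn_plane + j * (nx + 1) + i

    elems = np.empty((nx * ny, 8), dtype=np.int64)
    e = 0
    for j in range(ny):
        for i in range(nx):
            elems[e] = [
                nid(i, j, 0), nid(i + 1, j, 0), nid(i + 1, j + 1, 0), nid(i, j + 1, 0),
                nid(i, j, 1), nid(i + 1, j, 1), nid(i + 1, j + 1, 1), nid(i, j + 1, 1),
            ]
            e += 1

    # y grows downward while z grows upward: check handedness once and fix
    mesh = HexMesh(
        nodes=nodes,
        elements=elems,
        tissue_tag=np.full(nx * ny, TissueTag.TM, dtype=np.int64),
    )
    if mesh.corner_jacobians().min() <= 0:
        elems = elems[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        mesh.elements = elems
    if mesh.corner_jacobians().min() <= 0:
        raise GeometryError("meshing produced inverted elements")

    i_idx = np.arange(nx + 1)
    bottom_nodes = np.concatenate([nid(i_idx, ny, 0), nid(i_idx, ny, 1)])
    top_nodes = np.concatenate([nid(i_idx, 0, 0), nid(i_idx, 0, 1)])
    j_idx = np.arange(ny + 1)
    left_nodes = np.concatenate([nid(0, j_idx, 0), nid(0, j_idx, 1)])
    right_nodes = np.concatenate([nid(nx, j_idx, 0), nid(nx, j_idx, 1)])

    # lumen-facing quad faces (row j = ny), outward normal pointing +y (into
    # the lumen) so follower pressure pushes the wall toward the TM
    faces = np.empty((nx, 4), dtype=np.int64)
    for i in range(nx):
        faces[i] = [nid(i, ny, 0), nid(i, ny, 1), nid(i + 1, ny, 1), nid(i + 1, ny, 0)]
    # anterior faces: outward normal -y (toward the anterior chamber)
    anterior_faces = np.empty((nx, 4), dtype=np.int64)
    for i in range(nx):
        anterior_faces[i] = [nid(i, 0, 0), nid(i + 1, 0, 0), nid(i + 1, 0, 1), nid(i, 0, 1)]

    mesh.node_sets = {
        "sc_inner_wall_track": np.sort(bottom_nodes),
        "tm_anterior": np.sort(top_nodes),
        "floating_boundary": np.sort(np.unique(np.concatenate([top_nodes, bottom_nodes]))),
        "lateral_left": np.sort(left_nodes),
        "lateral_right": np.sort(right_nodes),
    }
    mesh.pressure_faces = faces
    mesh.meta = {
        "nx": nx,
        "ny": ny,
        "x_grid_um": xg,
        "y_top_um": y_top,
        "y_bot_um": y_bot,
        "edge_um": target_edge_um,
        "anterior_faces": anterior_faces,
    }
    return mesh


def partition_layers(mesh: HexMesh, jct_thickness_um: float = 14.0,
                     sc_thickness_um: float = 2.2,
                     sclera_thickness_um: float = 0.0) -> HexMesh:
    """Tag elements by distance from the SC-facing boundary.

    Elements whose centroid lies within ``sc_thickness_um`` of the SC-facing
    surface become SC_wall, the next ``jct_thickness_um`` band JCT and the
    remainder TM.  Optionally, a band measured from the anterior surface is
    tagged SCLERA (used by the IOP-ramp patch model).
    """
    if "x_grid_um" not in mesh.meta:
        raise GeometryError("mesh lacks boundary metadata for partitioning")
    xg = mesh.meta["x_grid_um"]
    y_top = mesh.meta["y_top_um"]
    y_bot = mesh.meta["y_bot_um"]
    cen = mesh.centroids() * MM_TO_UM
    yb = np.interp(cen[:, 0], xg, y_bot)
    yt = np.interp(cen[:, 0], xg, y_top)
    depth = yb - yt
    if np.any(sc_thickness_um + jct_thickness_um + sclera_thickness_um >= depth):
        raise GeometryError("layer bands exceed the tissue depth")
    d_sc = yb - cen[:, 1]
    tag = np.full(mesh.n_elements, TissueTag.TM, dtype=np.int64)
    tag[d_sc < sc_thickness_um + jct_thickness_um] = TissueTag.JCT
    tag[d_sc < sc_thickness_um] = TissueTag.SC_WALL
    if sclera_thickness_um > 0.0:
        d_top = cen[:, 1] - yt
        tag[d_top < sclera_thickness_um] = TissueTag.SCLERA
    mesh.tissue_tag = tag
    mesh.meta["sc_thickness_um"] = sc_thickness_um
    mesh.meta["jct_thickness_um"] = jct_thickness_um
    mesh.meta["sclera_thickness_um"] = sclera_thickness_um
    return mesh


def locate_point(mesh: HexMesh, p_mm: np.ndarray):
    """Host element and parametric coordinates of a point, or (None, None).

    Structured lookup via the stored grid, then a trilinear Newton inversion.
    Ties on element faces resolve to the lowest element index by scan order.
    """
    xg = mesh.meta["x_grid_um"]
    nx, ny = mesh.meta["nx"], mesh.meta["ny"]
    p_um = np.asarray(p_mm) * MM_TO_UM
    i = int(np.clip(np.searchsorted(xg, p_um[0]) - 1, 0, nx - 1))
    # scan this column and neighbours
    for ii in (i, max(i - 1, 0), min(i + 1, nx - 1)):
        for j in range(ny):
            e = j * nx + ii
            xi = _invert_trilinear(mesh.nodes[mesh.elements[e]], p_mm)
            if xi is not None:
                return e, xi
    return None, None


def _invert_trilinear(xe: np.ndarray, p: np.ndarray, tol: float = 1.0e-10):
    xi = np.zeros(3)
    for _ in range(30):
        n = ((1 + _XI_A[:, 0] * xi[0]) * (1 + _XI_A[:, 1] * xi[1])
             * (1 + _XI_A[:, 2] * xi[2]) / 8.0)
        r = n @ xe - p
        if np.dot(r, r) < tol * tol:
            break
        jac = np.einsum("ai,aj->ji", shape_gradients(xi), xe).T
        try:
            xi = xi - np.linalg.solve(jac.T, r)
        except np.linalg.LinAlgError:
            return None
    if np.all(np.abs(xi) <= 1.0 + 1.0e-8):
        return np.clip(xi, -1.0, 1.0)
    return None


def distribute_beams(mesh: HexMesh, planar_spacing_um: float = 4.0,
                     thickness_spacing_um: float = 2.5,
                     r_outer_um: float = 0.5, r_inner_um: float = 0.0,
                     margin_um: float = 2.0) -> BeamNetwork:
    """Lay fiber control points on a 4 um (planar) x 2.5 um (thickness)
    lattice inside the TM and JCT bands, connected along curves that run
    offset-parallel to the anterior and posterior TM edges (blended linearly
    across the band), and build 2-noded segments between neighbours.
    """
    if not np.any((mesh.tissue_tag == TissueTag.TM) | (mesh.tissue_tag == TissueTag.JCT)):
        raise GeometryError("mesh has no TM/JCT elements; partition first")
    xg = mesh.meta["x_grid_um"]
    y_top = mesh.meta["y_top_um"]
    y_bot = mesh.meta["y_bot_um"]
    sc_th = mesh.meta.get("sc_thickness_um", 2.2)

    x0, x1 = xg[0], xg[-1]
    n_along = int(np.floor((x1 - x0 - 2 * margin_um) / planar_spacing_um)) + 1
    if n_along < 2:
        raise GeometryError("domain too small for the beam lattice")
    xs = x0 + margin_um + planar_spacing_um * np.arange(n_along)

    yt = np.interp(xs, xg, y_top)
    yjct = np.interp(xs, xg, y_bot) - sc_th        # TM+JCT lower boundary
    depth_ref = float((yjct - yt).mean())
    n_curves = int(np.floor((depth_ref - 2 * margin_um) / planar_spacing_um)) + 1
    if n_curves < 1:
        raise GeometryError("tissue band too thin for the beam lattice")
    offsets = margin_um + planar_spacing_um * np.arange(n_curves)

    thick_um = EXTRUSION_THICKNESS_MM * MM_TO_UM
    n_sheets = max(1, int(np.floor(thick_um / thickness_spacing_um)) - 1)
    z0 = 0.5 * (thick_um - (n_sheets - 1) * thickness_spacing_um)
    z_levels = z0 + thickness_spacing_um * np.arange(n_sheets)

    pts = []
    segs = []
    hosts = []
    for z in z_levels:
        for d in offsets:
            s = d / depth_ref
            ys = yt * (1 - s) + yjct * s
            first = None
            prev = None
            for xq, yq in zip(xs, ys):
                p_mm = np.array([xq, yq, z]) * UM_TO_MM
                e, _ = locate_point(mesh, p_mm)
                if e is None or mesh.tissue_tag[e] not in (TissueTag.TM, TissueTag.JCT):
                    prev = None
                    continue
                idx = len(pts)
                pts.append(p_mm)
                hosts.append(e)
                if prev is not None:
                    segs.append((prev, idx))
                prev = idx
                if first is None:
                    first = idx
    if not pts:
        raise GeometryError("beam lattice produced zero control points")

    pts = np.asarray(pts)
    segs = np.asarray(segs, dtype=np.int64).reshape(-1, 2)
    hosts = np.asarray(hosts, dtype=np.int64)
    group = np.empty(segs.shape[0], dtype=np.int64)
    for k, (a, b) in enumerate(segs):
        mid = 0.5 * (pts[a] + pts[b])
        e, _ = locate_point(mesh, mid)
        group[k] = mesh.tissue_tag[e] if e is not None else mesh.tissue_tag[hosts[a]]

    return BeamNetwork(
        control_points=pts,
        segments=segs,
        group_tag=group,
        r_outer=r_outer_um * UM_TO_MM,
        r_inner=r_inner_um * UM_TO_MM,
        meta={
            "host_elements": hosts,
            "n_curves": n_curves,
            "n_sheets": n_sheets,
            "planar_spacing_um": planar_spacing_um,
            "thickness_spacing_um": thickness_spacing_um,
        },
    )


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int = 1) -> HexMesh:
    """Structured box mesh in mm (used for specimen bars and unit tests).

    Provides face node sets ``face_x0/x1/y0/y1/z0/z1``.  With ``nz = 1`` the
    element ordering matches the band mesher so point location works.
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    nn_plane = (nx + 1) * (ny + 1)
    nodes = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    for k in range(nz + 1):
        for j in range(ny + 1):
            for i in range(nx + 1):
                nodes[k * nn_plane + j * (nx + 1) + i] = (xs[i], ys[j], zs[k])

    def nid(i, j, k):
        return k * nn_plane + j * (nx + 1) + i

    elems = np.empty((nx * ny * nz, 8), dtype=np.int64)
    e = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems[e] = [
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                    nid(i, j + 1, k + 1),
                ]
                e += 1

    all_ids = np.arange(nodes.shape[0])
    mesh = HexMesh(
        nodes=nodes,
        elements=elems,
        tissue_tag=np.full(elems.shape[0], TissueTag.TM, dtype=np.int64),
        node_sets={
            "face_x0": all_ids[np.isclose(nodes[:, 0], 0.0)],
            "face_x1": all_ids[np.isclose(nodes[:, 0], lx)],
            "face_y0": all_ids[np.isclose(nodes[:, 1], 0.0)],
            "face_y1": all_ids[np.isclose(nodes[:, 1], ly)],
            "face_z0": all_ids[np.isclose(nodes[:, 2], 0.0)],
            "face_z1": all_ids[np.isclose(nodes[:, 2], lz)],
        },
        meta={
            "nx": nx,
            "ny": ny,
            "x_grid_um": xs * MM_TO_UM,
            "y_top_um": np.zeros(nx + 1),
            "y_bot_um": np.full(nx + 1, ly * MM_TO_UM),
            "edge_um": float(min(lx / nx, ly / ny) * MM_TO_UM),
        },
    )
    if mesh.corner_jacobians().min() <= 0:
        raise GeometryError("box mesh produced inverted elements")
    return mesh


# ---------------------------------------------------------------------------
# quality and stability
# ---------------------------------------------------------------------------

_CORNER_EDGES = {
    0: (1, 3, 4), 1: (2, 0, 5), 2: (3, 1, 6), 3: (0, 2, 7),
    4: (5, 7, 0), 5: (6, 4, 1), 6: (7, 5, 2), 7: (4, 6, 3),
}

_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
]


def element_quality(mesh: HexMesh) -> QualityReport:
    """Corner angles, edge aspect ratio and Gauss-integrated volume."""
    xe = mesh.element_coords()
    ne = mesh.n_elements
    min_ang = np.full(ne, 180.0)
    max_ang = np.zeros(ne)
    for corner, neigh in _CORNER_EDGES.items():
        vecs = [xe[:, n, :] - xe[:, corner, :] for n in neigh]
        for i in range(3):
            for j in range(i + 1, 3):
                u, v = vecs[i], vecs[j]
                c = np.einsum("ei,ei->e", u, v) / (
                    np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
                min_ang = np.minimum(min_ang, ang)
                max_ang = np.maximum(max_ang, ang)
    lengths = np.stack(
        [np.linalg.norm(xe[:, b, :] - xe[:, a, :], axis=1) for a, b in _EDGES], axis=1
    )
    aspect = lengths.max(axis=1) / lengths.min(axis=1)
    vol_mm3 = mesh.volumes()
    return QualityReport(
        min_angle=min_ang,
        max_angle=max_ang,
        aspect_ratio=aspect,
        volume_um3=vol_mm3 * MM_TO_UM**3,
    )


_FACES = [
    (0, 1, 2, 3), (4, 5, 6, 7),
    (0, 1, 5, 4), (3, 2, 6, 7),
    (0, 3, 7, 4), (1, 2, 6, 5),
]


def _face_areas(xe: np.ndarray) -> np.ndarray:
    """Areas of the 6 quad faces of each element, shape (ne, 6)."""
    areas = np.empty((xe.shape[0], 6))
    for f, (a, b, c, d) in enumerate(_FACES):
        d1 = xe[:, c, :] - xe[:, a, :]
        d2 = xe[:, d, :] - xe[:, b, :]
        areas[:, f] = 0.5 * np.linalg.norm(np.cross(d1, d2), axis=1)
    return areas


def dilatational_wave_speed(e: float, nu: float, rho: float) -> float:
    """C = sqrt(E (1 - nu) / ((1 + nu)(1 - 2 nu) rho)), mm/s in our units."""
    if not (0.0 < nu < 0.5):
        raise ValueError("Poisson ratio must lie in (0, 0.5) for the dilation wave")
    if rho <= 0:
        raise ValueError("density must be positive")
    return float(np.sqrt(e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * rho)))


def critical_timestep(mesh: HexMesh, e: float, nu: float, rho: float):
    """Per-element critical time step dt = l / C with l = V / A_max.

    Special case nu = 0 is allowed (C collapses to sqrt(E/rho)).
    Returns ``(dt_per_element, dt_min)`` in seconds.
    """
    if nu == 0.0:
        if rho <= 0:
            raise ValueError("density must be positive")
        c = float(np.sqrt(e / rho))
    else:
        c = dilatational_wave_speed(e, nu, rho)
    xe = mesh.element_coords()
    vol = mesh.volumes()
    a_max = _face_areas(xe).max(axis=1)
    l_char = vol / a_max
    dt = l_char / c
    return dt, float(dt.min())


def fit_circle_diameter(points) -> float:
    """Algebraic (Kasa) least-squares circle fit; returns the diameter.

    Input points are planar (n, 2); at least 3 non-collinear points required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 planar points")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity check via the area of the point cloud
    d = pts - pts.mean(axis=0)
    sv = np.linalg.svd(d, compute_uv=False)
    if sv[1] < 1.0e-9 * max(sv[0], 1.0):
        raise ValueError("points are collinear; circle fit is degenerate")
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx**2 + cy**2)
    return float(2.0 * r)


def make_probe_sets(mesh: HexMesh, seed: int, n_sets: int = 6, set_size: int = 8):
    """Randomly selected node sets inside the TM region (for displacement probes)."""
    rng = np.random.default_rng(seed)
    tm_elems = np.flatnonzero(mesh.tissue_tag == TissueTag.TM)
    tm_nodes = np.unique(mesh.elements[tm_elems].ravel())
    interior = np.setdiff1d(tm_nodes, np.concatenate(list(mesh.node_sets.values())))
    pool = interior if interior.size >= n_sets * set_size else tm_nodes
    sets = []
    for _ in range(n_sets):
        sets.append(np.sort(rng.choice(pool, size=min(set_size, pool.size), replace=False)))
    for i, s in enumerate(sets):
        mesh.node_sets[f"probe_{i}"] = s
    return sets
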