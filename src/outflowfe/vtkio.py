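"""Legacy-ASCII VTK writers for meshes, beams and results (output only)."""

from __future__ import annotations

import numpy as np

from .meshing import HexMesh, BeamNetwork

__all__ = ["write_mesh_vtk", "write_beams_vtk"]


def _header(fh, title):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def write_mesh_vtk(mesh: HexMesh, path, point_data=None, cell_data=None):
    """Hexahedron cells; node sets exported as integer point masks."""
    with open(path, "w") as fh:
        _header(fh, "outflowfe hexahedral mesh")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 9}\n")
        for conn in mesh.elements:
            fh.write("8 " + " ".join(str(int(c)) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["12"] * ne) + "\n")

        fh.write(f"CELL_DATA {ne}\n")
        fh.write("SCALARS tissue_tag int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.tissue_tag) + "\n")
        if cell_data:
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")

        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, ids in mesh.node_sets.items():
            mask = np.zeros(mesh.n_nodes, dtype=int)
            mask[ids] = 1
            fh.write(f"SCALARS set_{name} int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(v) for v in mask) + "\n")
        if point_data:
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")


def write_beams_vtk(beams: BeamNetwork, path, segment_scalars=None):
    """Beam segments as VTK line cells with optional per-segment scalars."""
    with open(path, "w") as fh:
        _header(fh, "outflowfe beam network")
        fh.write(f"POINTS {beams.n_points} double\n")
        for p in beams.control_points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        ns = beams.n_segments
        fh.write(f"CELLS {ns} {ns * 3}\n")
        for a, b in beams.segments:
            fh.write(f"2 {int(a)} {int(b)}\n")
        fh.write(f"CELL_TYPES {ns}\n")
        fh.write("\n".join(["3"] * ns) + "\n")
        fh.write(f"CELL_DATA {ns}\n")
        fh.write("SCALARS group_tag int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in beams.group_tag) + "\n")
        if segment_scalars:
            for name, arr in segment_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")
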