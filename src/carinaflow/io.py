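"""Writers for standard interchange formats and run artifacts.

Meshes go out as legacy-VTK ASCII and Gmsh MSH 2.2; fields as legacy
VTK with named point arrays ``velocity`` (m/s) and ``pressure`` (Pa);
trajectories as CSV and VTK polylines.  ``save_mesh``/``load_mesh`` and
``save_flowfield``/``load_flowfield`` persist stages of the pipeline so
CLI subcommands can run standalone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .flow import BoundaryConditions, FlowField, FluidProperties, P2Space
from .geometry import Mesh

__all__ = [
    "write_vtk_mesh", "write_vtk_flow", "write_vtk_trajectories",
    "write_msh", "trajectories_to_csv", "residuals_to_csv",
    "save_mesh", "load_mesh", "save_flowfield", "load_flowfield",
    "MissingArtifactError",
]

_TAG_IDS = {"inlet": 1, "outlet_1": 2, "outlet_2": 3, "wall": 4}


class MissingArtifactError(FileNotFoundError):
    """A pipeline stage requires an artifact that has not been produced."""


def _require(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise MissingArtifactError(
            f"stage {stage!r} requires {p} — run the producing stage first")
    return p


# ---------------------------------------------------------------------------
# Legacy VTK
# ---------------------------------------------------------------------------

def _vtk_header(fh, title: str, dataset: str):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(title + "\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _vtk_points(fh, pts: np.ndarray):
    fh.write(f"POINTS {len(pts)} double\n")
    for x, y in pts:
        fh.write(f"{x:.10e} {y:.10e} 0.0\n")


def write_vtk_mesh(mesh: Mesh, path) -> None:
    """Write the triangulation as a legacy-VTK unstructured grid."""
    with open(path, "w") as fh:
        _vtk_header(fh, "carinaflow mesh", "UNSTRUCTURED_GRID")
        _vtk_points(fh, mesh.points)
        nt = len(mesh.triangles)
        fh.write(f"CELLS {nt} {4 * nt}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {nt}\n")
        fh.write("5\n" * nt)


def write_vtk_flow(flowfield: FlowField, path) -> None:
    """Write velocity/pressure vertex data on the mesh as legacy VTK."""
    mesh = flowfield.mesh
    with open(path, "w") as fh:
        _vtk_header(fh, "carinaflow flow field", "UNSTRUCTURED_GRID")
        _vtk_points(fh, mesh.points)
        nt = len(mesh.triangles)
        fh.write(f"CELLS {nt} {4 * nt}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {nt}\n")
        fh.write("5\n" * nt)
        fh.write(f"POINT_DATA {len(mesh.points)}\n")
        fh.write("VECTORS velocity double\n")
        for u, v in flowfield.vertex_velocity:
            fh.write(f"{u:.10e} {v:.10e} 0.0\n")
        fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        for p in flowfield.pressure:
            fh.write(f"{p:.10e}\n")


def write_vtk_trajectories(trajectories: dict, path) -> None:
    """Write stored trajectories (id -> (t,x,y,u,v) rows) as VTK polylines."""
    pts, lines = [], []
    for _pid, arr in sorted(trajectories.items()):
        start = len(pts)
        pts.extend(arr[:, 1:3])
        lines.append(list(range(start, start + len(arr))))
    pts = np.array(pts) if pts else np.empty((0, 2))
    with open(path, "w") as fh:
        _vtk_header(fh, "carinaflow trajectories", "POLYDATA")
        _vtk_points(fh, pts)
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(str(len(l)) + " " + " ".join(map(str, l)) + "\n")


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2
# ---------------------------------------------------------------------------

def write_msh(mesh: Mesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII with tagged boundary lines."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n%d\n" % (len(_TAG_IDS) + 1))
        for name, pid in _TAG_IDS.items():
            fh.write(f'1 {pid} "{name}"\n')
        fh.write('2 10 "fluid"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write(f"$Nodes\n{len(mesh.points)}\n")
        for i, (x, y) in enumerate(mesh.points, 1):
            fh.write(f"{i} {x:.10e} {y:.10e} 0\n")
        fh.write("$EndNodes\n")
        ne = len(mesh.boundary_edges) + len(mesh.triangles)
        fh.write(f"$Elements\n{ne}\n")
        eid = 1
        for (a, b), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
            pid = _TAG_IDS[str(tag)]
            fh.write(f"{eid} 1 2 {pid} {pid} {a + 1} {b + 1}\n")
            eid += 1
        for a, b, c in mesh.triangles:
            fh.write(f"{eid} 2 2 10 10 {a + 1} {b + 1} {c + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def trajectories_to_csv(trajectories: dict, path) -> None:
    import pandas as pd
    frames = []
    for pid, arr in sorted(trajectories.items()):
        df = pd.DataFrame(arr, columns=["t", "x", "y", "u", "v"])
        df.insert(0, "particle_id", pid)
        frames.append(df)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["particle_id", "t", "x", "y", "u", "v"]))
    out.to_csv(path, index=False)


def residuals_to_csv(flowfield: FlowField, path) -> None:
    import pandas as pd
    pd.DataFrame({"iteration": range(len(flowfield.residuals)),
                  "relative_residual": flowfield.residuals}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stage persistence
# ---------------------------------------------------------------------------

def save_mesh(mesh: Mesh, path) -> None:
    geom_json = mesh.geometry.to_json() if hasattr(mesh.geometry, "to_json") else ""
    np.savez(path, points=mesh.points, triangles=mesh.triangles,
             boundary_edges=mesh.boundary_edges,
             boundary_tags=mesh.boundary_tags.astype("U16"),
             target_cell_size=mesh.target_cell_size,
             wall_layers=mesh.wall_layers,
             geometry_json=np.array(geom_json))


def load_mesh(path, stage: str = "load") -> Mesh:
    from .geometry import BifurcationGeometry
    d = np.load(_require(path, stage), allow_pickle=False)
    gj = str(d["geometry_json"])
    geometry = BifurcationGeometry.from_json(gj) if gj else None
    return Mesh(points=d["points"], triangles=d["triangles"],
                boundary_edges=d["boundary_edges"],
                boundary_tags=d["boundary_tags"].astype(object).astype(str),
                target_cell_size=float(d["target_cell_size"]),
                wall_layers=int(d["wall_layers"]), geometry=geometry)


def save_flowfield(flowfield: FlowField, path) -> None:
    np.savez(path, velocity=flowfield.velocity, pressure=flowfield.pressure,
             residuals=np.asarray(flowfield.residuals),
             fluid=np.array([flowfield.fluid.density,
                             flowfield.fluid.dynamic_viscosity]),
             fluid_label=np.array(flowfield.fluid.label),
             bc=np.array([flowfield.bc.inlet_flow_rate,
                          flowfield.bc.outlet_pressure]),
             inlet_profile=np.array(flowfield.bc.inlet_profile),
             mean_inlet_speed=flowfield.mean_inlet_speed)


def load_flowfield(path, mesh: Mesh, stage: str = "load") -> FlowField:
    d = np.load(_require(path, stage), allow_pickle=False)
    fluid = FluidProperties(float(d["fluid"][0]), float(d["fluid"][1]),
                            str(d["fluid_label"]))
    bc = BoundaryConditions(inlet_flow_rate=float(d["bc"][0]),
                            outlet_pressure=float(d["bc"][1]),
                            inlet_profile=str(d["inlet_profile"]))
    return FlowField(mesh=mesh, space=P2Space(mesh), velocity=d["velocity"],
                     pressure=d["pressure"], residuals=list(d["residuals"]),
                     converged=True, fluid=fluid, bc=bc,
                     mean_inlet_speed=float(d["mean_inlet_speed"]))
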