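"""Legacy-ASCII VTK and CSV export of meshes and flow solutions.

Legacy VTK unstructured grids are plain text and readable by ParaView and
any VTK-based viewer; fields are attached as point data on the mesh vertices
(quadratic fields are restricted to vertex values for display).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FEMesh

__all__ = ["write_vtk_mesh", "write_vtk_solution", "write_csv_solution"]

_VTK_CELL = {2: 5, 3: 10}  # triangle, tetrahedron


def _header(fh, title: str):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _points_and_cells(fh, mesh: FEMesh):
    n = mesh.n_nodes
    fh.write(f"POINTS {n} double\n")
    coords = mesh.nodes
    if mesh.dim == 2:
        coords = np.column_stack([coords, np.zeros(n)])
    for p in coords:
        fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    m, k = mesh.simplices.shape
    fh.write(f"CELLS {m} {m * (k + 1)}\n")
    for s in mesh.simplices:
        fh.write(f"{k} " + " ".join(str(int(v)) for v in s) + "\n")
    fh.write(f"CELL_TYPES {m}\n")
    fh.writelines([f"{_VTK_CELL[mesh.dim]}\n"] * m)


def _vector_data(fh, name: str, values: np.ndarray, dim: int):
    fh.write(f"VECTORS {name} double\n")
    vals = values.T
    if dim == 2:
        vals = np.column_stack([vals, np.zeros(len(vals))])
    for v in vals:
        fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")


def _scalar_data(fh, name: str, values: np.ndarray):
    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    for v in values:
        fh.write(f"{v:.10g}\n")


def write_vtk_mesh(path, mesh: FEMesh, title: str = "mesh") -> None:
    with open(path, "w") as fh:
        _header(fh, title)
        _points_and_cells(fh, mesh)


def write_vtk_solution(path, solution, title: str = "flow solution") -> None:
    """Write u, p, f (and r, g where present) as vertex point data."""
    mesh = solution.mesh
    nv = mesh.n_nodes
    with open(path, "w") as fh:
        _header(fh, title)
        _points_and_cells(fh, mesh)
        fh.write(f"POINT_DATA {nv}\n")
        _vector_data(fh, "velocity_um_per_s", solution.u.dofs[:, :nv], mesh.dim)
        _scalar_data(fh, "pressure_Pa", solution.p.dofs[:nv])
        _vector_data(fh, "force_Pa_per_um", solution.f.dofs, mesh.dim)
        if solution.r is not None:
            _scalar_data(fh, "divergence_per_s", solution.r.dofs)
        # boundary velocity as a vertex field, zero off Γ
        space = solution.u.space
        g_full = np.zeros((mesh.dim, nv))
        bd = space.boundary_dofs
        vertex_bd = bd[bd < nv]
        pos = np.searchsorted(bd, vertex_bd)
        g_full[:, vertex_bd] = solution.g.dofs[:, pos]
        _vector_data(fh, "boundary_velocity_um_per_s", g_full, mesh.dim)


def write_csv_solution(path, solution) -> None:
    """Node table: id, coordinates, u, p, f, r (vertex values)."""
    mesh = solution.mesh
    nv = mesh.n_nodes
    cols = {"node": np.arange(nv)}
    for k, ax in enumerate("xyz"[: mesh.dim]):
        cols[f"{ax}_um"] = mesh.nodes[:, k]
    for k, ax in enumerate("xyz"[: mesh.dim]):
        cols[f"u_{ax}"] = solution.u.dofs[k, :nv]
    cols["p_Pa"] = solution.p.dofs[:nv]
    for k, ax in enumerate("xyz"[: mesh.dim]):
        cols[f"f_{ax}"] = solution.f.dofs[k]
    if solution.r is not None:
        cols["r_per_s"] = solution.r.dofs
    pd.DataFrame(cols).to_csv(path, index=False)


def read_csv_solution_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
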