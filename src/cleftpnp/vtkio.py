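"""Plain-text output: legacy-ASCII VTK rectilinear grids and CSV tables.

Snapshots are written as VTK ``RECTILINEAR_GRID`` datasets (one file per
time point) with cell data: the region labels, the five concentrations and
the potential.  Scalar time series go to CSV with the header
``t_ms,quantity,value``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import Mesh
from .state import FieldState

__all__ = ["write_vtk_rectilinear", "write_state_vtk", "write_ampa_surface_vtk",
           "write_timeseries_csv"]


def write_vtk_rectilinear(path: str | Path, mesh: Mesh,
                          cell_data: dict[str, np.ndarray],
                          title: str = "cleftpnp snapshot") -> Path:
    """Write a legacy-ASCII VTK rectilinear grid with cell data fields."""
    path = Path(path)
    nx, ny, nz = mesh.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"X_COORDINATES {nx + 1} double",
        " ".join(f"{v:.10g}" for v in mesh.ex),
        f"Y_COORDINATES {ny + 1} double",
        " ".join(f"{v:.10g}" for v in mesh.ey),
        f"Z_COORDINATES {nz + 1} double",
        " ".join(f"{v:.10g}" for v in mesh.ez),
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, values in cell_data.items():
        arr = np.asarray(values)
        if arr.shape != (nx, ny, nz):
            raise ValueError(f"cell data {name!r} does not match the mesh")
        is_int = np.issubdtype(arr.dtype, np.integer)
        vtk_type = "int" if is_int else "double"
        lines.append(f"SCALARS {name} {vtk_type} 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell data is x-fastest; our arrays are (x, y, z) C-order
        flat = arr.transpose(2, 1, 0).ravel()
        fmt = "{:d}" if is_int else "{:.10g}"
        lines.extend(" ".join(fmt.format(v) for v in flat[i:i + 9])
                     for i in range(0, len(flat), 9))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_state_vtk(path: str | Path, mesh: Mesh, state: FieldState) -> Path:
    """Write one field state (concentrations, potential, regions) to VTK."""
    data: dict[str, np.ndarray] = {"region": mesh.region.astype(np.int32)}
    for k, sp in enumerate(state.species):
        safe = sp.name.replace("+", "p").replace("-", "m")
        data[f"conc_{safe}_mM"] = state.conc[k]
    if state.phi is not None:
        data["phi_mV"] = state.phi
    return write_vtk_rectilinear(path, mesh, data,
                                 title=f"t = {state.t:.6g} ms")


def write_ampa_surface_vtk(path: str | Path, mesh: Mesh,
                           state: FieldState) -> Path:
    """Write the receptor state over the AMPA zone as a flat VTK grid.

    One cell per AMPA membrane face (x-z plane), with the open probability
    and the six closed-state probabilities as cell data.
    """
    if state.markov is None or len(mesh.ampa_ix) == 0:
        raise ValueError("state carries no receptor data")
    path = Path(path)
    ix = np.unique(mesh.ampa_ix)
    iz = np.unique(mesh.ampa_iz)
    ex = mesh.ex[ix[0]:ix[-1] + 2]
    ez = mesh.ez[iz[0]:iz[-1] + 2]
    nx, nz = len(ix), len(iz)
    # markov rows follow the (ix, iz) C-order of the mesh AMPA columns
    o = state.open_probability().reshape(nx, nz)
    data: dict[str, np.ndarray] = {
        "open_probability": o.reshape(nx, 1, nz)}
    for s in range(6):
        data[f"C{s}"] = state.markov[:, s].reshape(nx, 1, nz)
    y_face = mesh.ey[mesh.j_cleft_top + 1]
    flat = Mesh(ex=ex, ey=np.array([y_face, y_face + 1e-9]), ez=ez,
                region=np.zeros((nx, 1, nz), dtype=np.int8))
    return write_vtk_rectilinear(path, flat, data,
                                 title=f"AMPA zone, t = {state.t:.6g} ms")


def write_timeseries_csv(path: str | Path, df: pd.DataFrame) -> Path:
    """Write a long-format time series with header ``t_ms,quantity,value``.

    A probe column, if present, is folded into the quantity name.
    """
    path = Path(path)
    out = df.copy()
    if "probe" in out.columns:
        out["quantity"] = out["probe"] + ":" + out["quantity"].astype(str)
        out = out.drop(columns=["probe"])
    out = out[["t_ms", "quantity", "value"]]
    out.to_csv(path, index=False)
    return path
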