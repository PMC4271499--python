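"""Plain-text exporters: legacy VTK, Gmsh .msh (v2.2), CSV traces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import MATERIAL_NAMES
from .mesh import AxisymmetricMesh


def write_vtk(path, mesh: AxisymmetricMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid of the (r, z) triangulation."""
    path = Path(path)
    pts, tris = mesh.points, mesh.triangles
    lines = ["# vtk DataFile Version 3.0", "salinerf axisymmetric mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(pts)} double"]
    lines += [f"{r:.9g} {z:.9g} 0" for r, z in pts]
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    lines.append(f"CELL_TYPES {len(tris)}")
    lines += ["5"] * len(tris)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("material", mesh.material.astype(float))
    lines.append(f"CELL_DATA {len(tris)}")
    for name, vals in cell_data.items():
        lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        lines += [f"{v:.9g}" for v in np.asarray(vals, float)]
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, vals in point_data.items():
            vals = np.asarray(vals, float)
            if vals.ndim == 1:
                lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                lines += [f"{v:.9g}" for v in vals]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [f"{v[0]:.9g} {v[1]:.9g} 0" for v in vals]
    path.write_text("\n".join(lines) + "\n")


def write_msh(path, mesh: AxisymmetricMesh) -> None:
    """Gmsh v2.2 ASCII mesh with material codes as physical tags."""
    path = Path(path)
    pts, tris = mesh.points, mesh.triangles
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
           str(len(MATERIAL_NAMES))]
    for i, name in enumerate(MATERIAL_NAMES):
        out.append(f'2 {i + 1} "{name}"')
    out += ["$EndPhysicalNames", "$Nodes", str(len(pts))]
    out += [f"{i + 1} {r:.9g} {z:.9g} 0" for i, (r, z) in enumerate(pts)]
    out += ["$EndNodes", "$Elements", str(len(tris))]
    for i, ((a, b, c), m) in enumerate(zip(tris, mesh.material)):
        out.append(f"{i + 1} 2 2 {m + 1} {m + 1} {a + 1} {b + 1} {c + 1}")
    out += ["$EndElements"]
    path.write_text("\n".join(out) + "\n")


def impedance_frame(result) -> pd.DataFrame:
    """Impedance/temperature trace of a simulation result as a DataFrame."""
    data = {"t_s": result.times, "Z_ohm": result.impedance}
    if result.power is not None:
        data["P_W"] = result.power
    for name, trace in result.Tmax.items():
        data[f"Tmax_{name}_C"] = trace
    return pd.DataFrame(data)


def write_result(result, out_dir) -> None:
    """Write the trace CSV, lesion JSON and field snapshots of a run."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    impedance_frame(result).to_csv(out / "impedance.csv", index=False)
    summary = {
        "scenario": result.config.scenario,
        "Z0_ohm": float(result.impedance[0]),
        "Z_end_ohm": float(result.impedance[-1]),
        "n_elements": int(result.mesh.n_elements),
        "dt_s": result.config.dt,
        "alpha_pct_per_C": result.config.alpha,
    }
    for tag, les in (("60C", result.lesion), ("50C", result.lesion50)):
        if les is not None:
            summary[f"lesion_{tag}"] = {
                "depth_mm": les.depth, "width_mm": les.width,
                "max_tissue_T": les.max_tissue_T,
                "max_saline_T": les.max_saline_T,
            }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    for t, T in result.snapshots.items():
        pd_data = {"temperature": T}
        if result.velocity is not None:
            pd_data["velocity"] = result.velocity.u
        write_vtk(out / f"fields_t{t:g}.vtk", result.mesh, point_data=pd_data)
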