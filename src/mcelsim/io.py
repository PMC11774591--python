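"""Output writers: legacy-ASCII VTK fields, tidy CSV tables, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .meshing import Mesh


def write_vtk(path: str | Path, mesh: Mesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the mesh and per-node/per-cell fields as legacy ASCII VTK."""
    path = Path(path)
    n, m = len(mesh.nodes), len(mesh.tris)
    lines = ["# vtk DataFile Version 3.0", "mcelsim field", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.12g} {y:.12g} 0.0")
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.tris:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    cell = dict(cell_data or {})
    cell.setdefault("region", mesh.tri_region)
    point_data = point_data or {}
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.12g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.12g} {v[1]:.12g} 0.0" for v in arr)
    lines.append(f"CELL_DATA {m}")
    for name, arr in cell.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v):.12g}" for v in np.asarray(arr))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sweep_csv(path: str | Path, rows: list[dict]) -> Path:
    """One row per run, all dimensionless inputs plus metrics."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value"):
        return obj.value
    return str(obj)
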