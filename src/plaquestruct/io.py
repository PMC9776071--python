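"""File interfaces: centerline/contour CSV, legacy-VTK mesh output, JSON.

Volumes travel as NIfTI (see :mod:`plaquestruct.grids`), waveforms as
two-column CSV (:mod:`plaquestruct.waveforms`); meshes are written as
ASCII legacy VTK unstructured grids with per-element scalar fields.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def centerline_to_csv(centerline, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_mm": centerline.points[:, 0],
            "y_mm": centerline.points[:, 1],
            "z_mm": centerline.points[:, 2],
            "arclength_mm": centerline.arclength,
            "branch": centerline.branch_id,
        }
    ).to_csv(path, index=False)


def contours_to_csv(segmentations: dict, path: str | Path) -> None:
    """Per-slice contour vertices: slice, vertex index, x, y, kind."""
    rows = []
    for z, seg in sorted(segmentations.items()):
        for group in (seg.lumen, seg.outer):
            for contour in group:
                for i, (x, y) in enumerate(contour.vertices):
                    rows.append(
                        {"slice": z, "vertex": i, "x_mm": x, "y_mm": y,
                         "kind": contour.kind}
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def wss_field_to_csv(field, path: str | Path) -> None:
    """Long-format WSS table (point, position, branch, time, tau vector)."""
    p, t = field.points.shape[0], field.times.size
    rows = {
        "point_id": np.repeat(np.arange(p), t),
        "x_mm": np.repeat(field.points[:, 0], t),
        "y_mm": np.repeat(field.points[:, 1], t),
        "z_mm": np.repeat(field.points[:, 2], t),
        "branch": np.repeat(field.branch, t),
        "arclength_mm": np.repeat(field.arclength, t),
        "t_s": np.tile(field.times, p),
        "taux_pa": field.tau[:, :, 0].ravel(),
        "tauy_pa": field.tau[:, :, 1].ravel(),
        "tauz_pa": field.tau[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vtk_unstructured(
    path: str | Path,
    nodes: np.ndarray,
    tets: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "plaquestruct mesh",
) -> None:
    """ASCII legacy-VTK tetrahedral mesh with optional per-cell scalars."""
    nodes = np.asarray(nodes, float)
    tets = np.asarray(tets, int)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in row) for row in nodes]
    lines.append(f"CELLS {len(tets)} {len(tets) * 5}")
    lines += ["4 " + " ".join(str(i) for i in row) for row in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)  # VTK_TETRA
    if cell_data:
        lines.append(f"CELL_DATA {len(tets)}")
        for name, values in cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.6g}" for v in np.asarray(values).ravel()]
    Path(path).write_text("\n".join(lines) + "\n")


def material_mesh_to_vtk(mesh, path: str | Path) -> None:
    write_vtk_unstructured(
        path,
        mesh.nodes,
        mesh.tets,
        {"E_MPa": mesh.E, "nu": mesh.nu, "tissue_id": mesh.tissue.astype(float)},
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, stable float repr)."""
    Path(path).write_text(
        json.dumps(obj, cls=_NumpyEncoder, sort_keys=True, indent=2) + "\n"
    )
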