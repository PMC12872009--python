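"""Plain-text export of meshes, fields and contours.

Meshes go out as legacy ASCII VTK (POLYDATA with one vertex cell per
element centroid, per-point tissue label / EVOL / strain / injured arrays),
which loads directly in ParaView/VisIt; region contours go out as a simple
CSV polygon file (region, ring, x, y).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import LABELS, CrossSection, LabeledMesh

__all__ = ["write_vtk_points", "write_region_contours"]


def write_vtk_points(mesh: LabeledMesh, path: str | Path,
                     fields: dict[str, np.ndarray] | None = None,
                     title: str = "cordpop epicenter slab") -> None:
    """Write a LabeledMesh (plus optional per-element fields) as legacy
    ASCII VTK polydata vertices."""
    n = len(mesh)
    fields = dict(fields or {})
    for name, arr in fields.items():
        if np.asarray(arr).shape != (n,):
            raise ValueError(f"field {name!r} must have one value per element")
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    z = np.zeros(n)
    for xi, yi, zi in zip(mesh.x, mesh.y, z):
        lines.append(f"{xi:.6g} {yi:.6g} {zi:.6g}")
    lines.append(f"VERTICES {n} {2 * n}")
    lines.extend(f"1 {i}" for i in range(n))
    lines.append(f"POINT_DATA {n}")
    base = {"tissue_label": mesh.label.astype(float), "evol": mesh.evol}
    for name, arr in {**base, **fields}.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6g}" for v in np.asarray(arr, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def write_region_contours(section: CrossSection, path: str | Path) -> None:
    """Write each tissue region's boundary rings as CSV (region,ring,x,y)."""
    rows = ["region,ring,x_mm,y_mm"]
    regions = {"gray": section.gray, "white": section.white,
               "pia": section.pia, "csf": section.csf, "dura": section.dura,
               "cord": section.cord, "canal": section.canal}
    for name, poly in regions.items():
        polys = poly.geoms if hasattr(poly, "geoms") else [poly]
        ring_i = 0
        for p in polys:
            for ring in [p.exterior, *p.interiors]:
                for xx, yy in ring.coords:
                    rows.append(f"{name},{ring_i},{xx:.6g},{yy:.6g}")
                ring_i += 1
    Path(path).write_text("\n".join(rows) + "\n")


def label_name(code: int) -> str:
    return LABELS[int(code)]
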