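"""On-disk formats: contour-set files, result tables, VTK export.

The primary contour-set format is a self-describing JSON document::

    {
      "units": "mm",
      "label": "aorta",
      "time_label": "systole",          # optional
      "fiducial": [x, y, z],            # optional
      "contours": [
        {"index": 0, "points": [[x, y, z], ...]},
        ...
      ]
    }

A flat CSV dialect with columns ``contour_id,x,y,z`` is also accepted.
Result tables are CSV with units in the headers; masked values are written as
empty cells.  Surfaces are exported as legacy-ASCII VTK polydata with one
scalar array per curvature field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ContourStack
from .eccentricity import profile_to_dataframe
from .errors import ContourFileError
from .pipeline import AnalysisResult

__all__ = ["write_contour_set", "read_contour_set", "write_results", "write_vtk_surface"]


def write_contour_set(stack: ContourStack, path, fiducial=None) -> Path:
    """Serialize a stack to the JSON contour-set format (or CSV if the path
    ends in ``.csv``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for c in stack:
            for p in c.points:
                rows.append((c.index, p[0], p[1], p[2]))
        pd.DataFrame(rows, columns=["contour_id", "x", "y", "z"]).to_csv(path, index=False)
        return path
    doc = {
        "units": "mm",
        "label": stack.label,
        "time_label": stack.time_label,
        "fiducial": None if fiducial is None else [float(v) for v in fiducial],
        "contours": [{"index": c.index, "points": c.points.tolist()} for c in stack],
    }
    path.write_text(json.dumps(doc))
    return path


def _stack_from_records(records, label="", time_label=None) -> ContourStack:
    from .core import Contour
    contours = []
    last = None
    for idx, pts in records:
        if last is not None and idx <= last:
            raise ContourFileError(f"contour indices must be strictly increasing (at {idx})")
        last = idx
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ContourFileError(f"contour {idx} must have >= 3 xyz points")
        contours.append(Contour.from_points(idx, pts))
    return ContourStack(contours, label=label, time_label=time_label)


def read_contour_set(path) -> tuple[ContourStack, dict]:
    """Read a contour-set file (JSON or the CSV dialect).

    Returns ``(stack, metadata)``; metadata holds label, time_label and any
    stored fiducial.
    """
    path = Path(path)
    if not path.exists():
        raise ContourFileError(f"no such file: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"contour_id", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ContourFileError(f"CSV dialect needs columns {sorted(required)}")
        records = [(int(cid), g[["x", "y", "z"]].to_numpy())
                   for cid, g in df.groupby("contour_id", sort=True)]
        return _stack_from_records(records), {"units": "mm", "fiducial": None,
                                              "label": "", "time_label": None}
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ContourFileError(f"{path} is not valid JSON: {exc}") from exc
    units = doc.get("units")
    if units != "mm":
        raise ContourFileError(f"units must be declared as 'mm', got {units!r}")
    if "contours" not in doc or not doc["contours"]:
        raise ContourFileError("document has no contours")
    records = [(int(c.get("index", i)), c["points"]) for i, c in enumerate(doc["contours"])]
    stack = _stack_from_records(records, label=doc.get("label", ""),
                                time_label=doc.get("time_label"))
    meta = {"units": units, "label": doc.get("label", ""),
            "time_label": doc.get("time_label"),
            "fiducial": doc.get("fiducial")}
    return stack, meta


def _fmt(x: float) -> str:
    return "" if not np.isfinite(x) else repr(float(x))


def write_results(result: AnalysisResult, outdir) -> dict[str, Path]:
    """Write the standard result files for one analyzed state.

    ``nodes.csv``  -- one row per (contour, boundary point): sigma, theta, r,
    both curvatures and the two proxies (masked values empty).
    ``contours.csv`` -- per-contour eccentricity records.
    ``greenwich.csv`` -- the Greenwich curve polyline.
    ``surface.vtk`` -- legacy-ASCII polydata with curvature scalars.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surf = result.surface
    lf, cf, px = result.longitudinal, result.circumferential, result.proxies
    u = lf.units
    rows = []
    for i in range(surf.n):
        for j in range(len(surf.theta_samples[i])):
            rows.append({
                "contour": int(surf.contour_indices[i]),
                "point": int(surf.point_order[i][j]),
                "sigma_mm": float(surf.sigma_grid[i]),
                "theta_rad": float(surf.theta_samples[i][j]),
                "r_mm": float(surf.radii[i][j]),
                f"kappa_long_{u}^-1": _fmt(lf.values[i][j]) if lf.defined[i][j] else "",
                f"kappa_circ_{u}^-1": _fmt(cf.values[i][j]) if cf.defined[i][j] else "",
                f"gaussian_proxy_{u}^-2": _fmt(px.gaussian_proxy[i][j]) if px.defined[i][j] else "",
                f"mean_proxy_{u}^-1": _fmt(px.mean_proxy[i][j]) if px.defined[i][j] else "",
            })
    nodes_path = outdir / "nodes.csv"
    pd.DataFrame(rows).to_csv(nodes_path, index=False)

    prof = profile_to_dataframe(result.eccentricity)
    prof["spirality_rad_per_mm"] = result.spirality
    contours_path = outdir / "contours.csv"
    prof.to_csv(contours_path, index=False, na_rep="")

    gw = pd.DataFrame(result.frame.gamma_points, columns=["x_mm", "y_mm", "z_mm"])
    gw.insert(0, "contour", result.surface.contour_indices)
    greenwich_path = outdir / "greenwich.csv"
    gw.to_csv(greenwich_path, index=False)

    vtk_path = outdir / "surface.vtk"
    write_vtk_surface(result, vtk_path)
    return {"nodes": nodes_path, "contours": contours_path,
            "greenwich": greenwich_path, "vtk": vtk_path}


def write_vtk_surface(result: AnalysisResult, path) -> Optional[Path]:
    """Legacy-ASCII VTK polydata of the surface with curvature scalars.

    Quads join consecutive contours; requires a uniform point count per
    contour (returns None otherwise, with no file written).
    """
    surf = result.surface
    counts = {len(t) for t in surf.theta_samples}
    if len(counts) != 1:
        return None
    m = counts.pop()
    n = surf.n
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "tubegeom surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {n * m} float"]
    for i in range(n):
        for p in surf.points[i]:
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    quads = []
    for i in range(n - 1):
        for j in range(m):
            j2 = (j + 1) % m
            quads.append((i * m + j, i * m + j2, (i + 1) * m + j2, (i + 1) * m + j))
    lines.append(f"POLYGONS {len(quads)} {5 * len(quads)}")
    for q in quads:
        lines.append("4 " + " ".join(str(v) for v in q))
    lines.append(f"POINT_DATA {n * m}")
    u = result.longitudinal.units

    def scalar_block(name, field):
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        for i in range(n):
            vals = np.where(field.defined[i], field.values[i], np.nan)
            for v in vals:
                lines.append(f"{v:.6g}" if np.isfinite(v) else "nan")

    scalar_block(f"kappa_longitudinal_{u}", result.longitudinal)
    scalar_block(f"kappa_circumferential_{u}", result.circumferential)
    path.write_text("\n".join(lines) + "\n")
    return path
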