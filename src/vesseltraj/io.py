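"""Readers and writers for centerline scans, manifests and ground truth.

Two on-disk curve formats are supported:

* legacy-VTK ASCII polydata (``.vtk``): one POLYDATA with one polyline cell per
  artery, a POINT_DATA scalar array ``radius`` and the artery labels, subject
  id and age encoded on the title line (the legacy format has no string cell
  arrays);
* CSV (``.csv``): tidy table with columns ``label,point_index,x,y,z,radius``.

A cohort on disk is a directory of per-scan files plus a manifest CSV
(``subject_id,scan_id,age,path``) and a covariates CSV; generator ground
truth is stored as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .curves import CenterlineCurve, VesselScan, VesselGeometryError

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------- VTK legacy


def write_vtk(scan: VesselScan, path: str | Path) -> None:
    """Write a scan as legacy-VTK ASCII polydata with polyline cells."""
    path = Path(path)
    all_pts = np.vstack([c.points for c in scan.curves])
    all_rad = np.concatenate([c.radii for c in scan.curves])
    title = (
        f"vesseltraj subject={scan.subject_id} scan={scan.scan_id} "
        f"age={scan.age!r} labels={','.join(scan.labels)}"
    )
    lines = [
        "# vtk DataFile Version 3.0",
        title[:255],
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(all_pts)} double",
    ]
    for p in all_pts:
        lines.append(" ".join(_FLOAT_FMT % v for v in p))
    n_cells = len(scan.curves)
    conn_size = sum(c.n_points + 1 for c in scan.curves)
    lines.append(f"LINES {n_cells} {conn_size}")
    offset = 0
    for c in scan.curves:
        ids = range(offset, offset + c.n_points)
        lines.append(f"{c.n_points} " + " ".join(str(i) for i in ids))
        offset += c.n_points
    lines += [
        f"POINT_DATA {len(all_pts)}",
        "SCALARS radius double 1",
        "LOOKUP_TABLE default",
    ]
    lines += [_FLOAT_FMT % r for r in all_rad]
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> VesselScan:
    """Read a scan written by :func:`write_vtk`."""
    tokens_meta: dict[str, str] = {}
    text = Path(path).read_text().splitlines()
    if len(text) < 5 or "vtk DataFile" not in text[0]:
        raise VesselGeometryError(f"{path}: not a legacy VTK file")
    for item in text[1].split():
        if "=" in item:
            k, _, v = item.partition("=")
            tokens_meta[k] = v
    if text[3].strip() != "DATASET POLYDATA":
        raise VesselGeometryError(f"{path}: expected DATASET POLYDATA")

    i = 4
    if not text[i].startswith("POINTS"):
        raise VesselGeometryError(f"{path}: missing POINTS block")
    n_pts = int(text[i].split()[1])
    i += 1
    pts = np.array(
        [[float(v) for v in text[i + j].split()] for j in range(n_pts)]
    )
    i += n_pts
    if not text[i].startswith("LINES"):
        raise VesselGeometryError(f"{path}: missing LINES block")
    n_cells = int(text[i].split()[1])
    i += 1
    cells = []
    for _ in range(n_cells):
        row = [int(v) for v in text[i].split()]
        if row[0] != len(row) - 1:
            raise VesselGeometryError(f"{path}: malformed polyline cell")
        cells.append(row[1:])
        i += 1
    if not text[i].startswith("POINT_DATA"):
        raise VesselGeometryError(f"{path}: missing POINT_DATA")
    i += 3  # POINT_DATA / SCALARS / LOOKUP_TABLE
    rad = np.array([float(text[i + j]) for j in range(n_pts)])

    labels = tokens_meta.get("labels", "").split(",")
    if len(labels) != n_cells:
        raise VesselGeometryError(f"{path}: label count != polyline count")
    curves = tuple(
        CenterlineCurve(lab, pts[ids], rad[ids]) for lab, ids in zip(labels, cells)
    )
    return VesselScan(
        subject_id=tokens_meta.get("subject", ""),
        age=float(tokens_meta.get("age", "nan")),
        curves=curves,
        scan_id=tokens_meta.get("scan", ""),
    )


# ----------------------------------------------------------------------- CSV


def write_csv(scan: VesselScan, path: str | Path) -> None:
    rows = []
    for c in scan.curves:
        for j, (p, r) in enumerate(zip(c.points, c.radii)):
            rows.append((c.label, j, p[0], p[1], p[2], r))
    df = pd.DataFrame(rows, columns=["label", "point_index", "x", "y", "z", "radius"])
    df.insert(0, "subject_id", scan.subject_id)
    df.insert(1, "scan_id", scan.scan_id)
    df.insert(2, "age", scan.age)
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv(path: str | Path) -> VesselScan:
    df = pd.read_csv(path)
    curves = []
    for lab, g in df.groupby("label", sort=False):
        g = g.sort_values("point_index")
        curves.append(
            CenterlineCurve(str(lab), g[["x", "y", "z"]].to_numpy(), g["radius"].to_numpy())
        )
    return VesselScan(
        subject_id=str(df["subject_id"].iloc[0]),
        age=float(df["age"].iloc[0]),
        curves=tuple(curves),
        scan_id=str(df["scan_id"].iloc[0]),
    )


def write_scan(scan: VesselScan, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".vtk":
        write_vtk(scan, path)
    elif path.suffix == ".csv":
        write_csv(scan, path)
    else:
        raise VesselGeometryError(f"unknown curve format {path.suffix!r}")


def read_scan(path: str | Path) -> VesselScan:
    path = Path(path)
    if path.suffix == ".vtk":
        return read_vtk(path)
    if path.suffix == ".csv":
        return read_csv(path)
    raise VesselGeometryError(f"unknown curve format {path.suffix!r}")


# ----------------------------------------------------- manifests and cohorts


def write_cohort(cohort, out_dir: str | Path, fmt: str = "vtk") -> Path:
    """Write every scan of a cohort plus manifest and covariates CSVs.

    Returns the manifest path.  ``cohort`` is a :class:`~vesseltraj.synthetic.Cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        for scan in subj.scans:
            fname = f"{scan.subject_id}_{scan.scan_id}.{fmt}"
            write_scan(scan, out_dir / fname)
            rows.append((scan.subject_id, scan.scan_id, scan.age, fname))
    manifest = pd.DataFrame(rows, columns=["subject_id", "scan_id", "age", "path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.9g")
    cov = cohort.covariates_frame()
    cov.to_csv(out_dir / "covariates.csv", index=False)
    return out_dir / "manifest.csv"


def read_manifest(manifest_path: str | Path) -> list[VesselScan]:
    """Load every scan referenced by a manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    scans = []
    for _, row in df.iterrows():
        scan = read_scan(manifest_path.parent / str(row["path"]))
        scans.append(scan)
    return scans


def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_ground_truth_dict(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
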