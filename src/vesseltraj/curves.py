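"""Centerline curve containers and fixed-topology landmark shapes.

A vessel centerline is an ordered 3D polyline (mm) with a maximal-inscribed
sphere radius attached to each point.  All downstream shape modelling runs on
:class:`PointSetShape` objects: per-artery blocks of arc-length-resampled
landmarks concatenated in a canonical label order, so that every shape entering
one model fit has identical topology and point-to-point correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Composite artery set: left/right anterior circulation (internal carotid,
#: middle cerebral M1, anterior cerebral A1+A2, anterior communicating) and the
#: posterior circulation (basilar, posterior cerebral P1+P2).
SUPPORTED_LABELS: tuple[str, ...] = (
    "ICA-L",
    "ICA-R",
    "MCA-L",
    "MCA-R",
    "ACA-L",
    "ACA-R",
    "AComA",
    "BA",
    "PCA-L",
    "PCA-R",
)

#: Labels produced by the synthetic cohort generator (the AComA is too short
#: and too often unresolved to carry a stable landmark block).
GENERATOR_LABELS: tuple[str, ...] = tuple(
    lab for lab in SUPPORTED_LABELS if lab != "AComA"
)


class VesselGeometryError(ValueError):
    """Raised for invalid centerline geometry or topology mismatches."""


@dataclass(frozen=True)
class CenterlineCurve:
    """One labeled artery centerline: ordered 3D points (mm) with radii (mm)."""

    label: str
    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        rad = np.asarray(self.radii, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise VesselGeometryError(
                f"curve {self.label!r}: points must be (n>=2, 3), got {pts.shape}"
            )
        if rad.shape != (pts.shape[0],):
            raise VesselGeometryError(
                f"curve {self.label!r}: radii length {rad.shape} != n points {pts.shape[0]}"
            )
        if not np.all(rad > 0):
            raise VesselGeometryError(f"curve {self.label!r}: radii must be positive")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise VesselGeometryError(
                f"curve {self.label!r}: consecutive points coincide"
            )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radii", rad)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CenterlineCurve":
        """Apply a rigid motion x -> R x + t."""
        return replace(self, points=self.points @ np.asarray(R).T + np.asarray(t))

    def reversed(self) -> "CenterlineCurve":
        return replace(self, points=self.points[::-1].copy(), radii=self.radii[::-1].copy())


@dataclass(frozen=True)
class VesselScan:
    """All labeled artery centerlines of one subject at one scan age."""

    subject_id: str
    age: float
    curves: tuple[CenterlineCurve, ...]
    scan_id: str = ""

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise VesselGeometryError(f"scan age must be positive, got {self.age}")
        labels = [c.label for c in self.curves]
        unknown = set(labels) - set(SUPPORTED_LABELS)
        if unknown:
            raise VesselGeometryError(f"unsupported artery labels: {sorted(unknown)}")
        if len(labels) != len(set(labels)):
            raise VesselGeometryError("duplicate artery labels in scan")
        object.__setattr__(self, "curves", tuple(self.curves))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.curves)

    def curve(self, label: str) -> CenterlineCurve:
        for c in self.curves:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class PointSetShape:
    """Fixed-topology landmark shape: per-artery resampled blocks.

    ``points`` stacks the blocks of the *present* arteries in canonical label
    order; missing arteries are kept as explicitly absent blocks so shapes
    with different anatomy can still be compared on their shared arteries.
    """

    labels: tuple[str, ...]
    present: tuple[bool, ...]
    points: np.ndarray
    points_per_artery: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        n_expected = sum(self.present) * self.points_per_artery
        if pts.shape != (n_expected, 3):
            raise VesselGeometryError(
                f"points shape {pts.shape} inconsistent with "
                f"{sum(self.present)} present blocks x {self.points_per_artery}"
            )
        if len(self.labels) != len(self.present):
            raise VesselGeometryError("labels/present length mismatch")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "present", tuple(bool(p) for p in self.present))

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    @property
    def present_labels(self) -> tuple[str, ...]:
        return tuple(l for l, p in zip(self.labels, self.present) if p)

    def block(self, label: str) -> np.ndarray:
        """Landmark block of one artery; KeyError if absent."""
        idx = 0
        for l, p in zip(self.labels, self.present):
            if l == label:
                if not p:
                    raise KeyError(f"artery {label!r} marked absent")
                k = self.points_per_artery
                return self.points[idx : idx + k]
            if p:
                idx += self.points_per_artery
        raise KeyError(label)

    def with_points(self, pts: np.ndarray) -> "PointSetShape":
        return replace(self, points=np.asarray(pts, dtype=float))

    def same_topology(self, other: "PointSetShape") -> bool:
        return (
            self.labels == other.labels
            and self.present == other.present
            and self.points_per_artery == other.points_per_artery
        )


def resample_curve(curve: CenterlineCurve, n: int) -> CenterlineCurve:
    """Resample a polyline to ``n`` points uniformly spaced in arc length.

    Endpoints are preserved exactly; radii are interpolated linearly in arc
    length.  Total length is preserved up to chordal shortening (exact for a
    polyline re-sampled at least as densely as its input).
    """
    if n < 2:
        raise VesselGeometryError(f"need n >= 2 resample points, got {n}")
    s = curve.arc_lengths()
    total = s[-1]
    if total <= 0:
        raise VesselGeometryError(f"curve {curve.label!r} has zero length")
    target = np.linspace(0.0, total, n)
    pts = np.column_stack(
        [np.interp(target, s, curve.points[:, k]) for k in range(3)]
    )
    pts[0], pts[-1] = curve.points[0], curve.points[-1]
    rad = np.interp(target, s, curve.radii)
    # interp can land two targets on one input vertex for very coarse inputs;
    # nudge any coincident consecutive samples apart along the polyline
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise VesselGeometryError(
            f"curve {curve.label!r}: degenerate resampling (duplicate vertices)"
        )
    return CenterlineCurve(curve.label, pts, rad)


def to_point_set(
    scan: VesselScan,
    points_per_artery: int,
    labels: Sequence[str] = GENERATOR_LABELS,
) -> PointSetShape:
    """Resample a scan into a fixed-topology landmark shape.

    Arteries in ``labels`` but missing from the scan become absent-marked
    blocks (such a shape is excluded from fits that require those blocks).
    """
    unknown = set(scan.labels) - set(SUPPORTED_LABELS)
    if unknown:
        raise VesselGeometryError(f"unsupported labels {sorted(unknown)}")
    blocks = []
    present = []
    for lab in labels:
        try:
            c = scan.curve(lab)
        except KeyError:
            present.append(False)
            continue
        present.append(True)
        blocks.append(resample_curve(c, points_per_artery).points)
    pts = np.vstack(blocks) if blocks else np.empty((0, 3))
    return PointSetShape(tuple(labels), tuple(present), pts, points_per_artery)
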