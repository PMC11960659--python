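"""Rigid (Kabsch) alignment of landmark shapes and iterative mean templates.

Rigid — never affine or elastic — alignment is used throughout so that
registration cannot absorb the morphological change the trajectory model is
meant to estimate.  The cross-sectional template is an iterative Procrustes
mean: align every shape to the current mean, re-average landmark-wise, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd

from .curves import PointSetShape, VesselGeometryError


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise VesselGeometryError("rigid transform needs 3x3 R and 3-vector t")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise VesselGeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise VesselGeometryError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    A = moving - mu_m
    B = fixed - mu_f
    # guard: rigid alignment is ill-posed for (near-)collinear landmarks
    sv = np.linalg.svd(A, compute_uv=False)
    if A.shape[0] < 3 or sv[1] < 1e-9 * max(sv[0], 1.0):
        raise VesselGeometryError(
            "rigid alignment needs >= 3 non-collinear landmarks"
        )
    U, _, Vt = svd(A.T @ B)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_f - R @ mu_m
    return RigidTransform(R, t)


def rigid_align(
    moving: PointSetShape, fixed: PointSetShape
) -> tuple[RigidTransform, PointSetShape]:
    """Least-squares optimal rigid alignment of ``moving`` onto ``fixed``.

    Closed-form Kabsch solution: the returned transform globally minimises the
    summed squared landmark distances over all proper rigid motions.
    """
    if not moving.same_topology(fixed):
        raise VesselGeometryError("rigid_align requires identical topology")
    T = _kabsch(moving.points, fixed.points)
    return T, moving.with_points(T.apply(moving.points))


def build_initial_template(
    shapes: list[PointSetShape],
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[PointSetShape, bool]:
    """Iterative Procrustes mean of a set of same-topology shapes.

    Returns the converged mean, centered at the origin, and a convergence
    flag (False if ``max_iter`` was exhausted before the mean moved < ``tol``).
    """
    if len(shapes) < 2:
        raise VesselGeometryError("template construction needs >= 2 shapes")
    first = shapes[0]
    for s in shapes[1:]:
        if not s.same_topology(first):
            raise VesselGeometryError("template construction: topology mismatch")

    mean = first.points - first.points.mean(axis=0)
    converged = False
    for _ in range(max_iter):
        aligned = []
        for s in shapes:
            T = _kabsch(s.points, mean)
            aligned.append(T.apply(s.points))
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        move = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if move < tol:
            converged = True
            break
    return first.with_points(mean), converged
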