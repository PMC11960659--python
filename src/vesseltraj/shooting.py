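"""Landmark geodesic shooting with a Gaussian kernel (control-point LDDMM).

A deformation is parameterized by control points ``c_k`` carrying momenta
``m_k``.  They induce the velocity field ``v(x) = sum_k K(x, c_k) m_k`` with
Gaussian kernel ``K(x, y) = exp(-|x-y|^2 / (2 sigma^2))``.  Geodesics follow
the Hamiltonian system

    dc_k/dt =  sum_l K(c_k, c_l) m_l
    dm_k/dt = -grad_{c_k} H,     H = 1/2 sum_{k,l} (m_k . m_l) K(c_k, c_l)

integrated with classical RK4; landmarks are passively advected through the
velocity field.  The kinetic energy H is conserved along exact geodesics,
which provides a sharp integration-accuracy diagnostic.

Shooting with momenta ``a*m`` for unit time equals shooting with ``m`` for
time ``a`` (the Hamiltonian is quadratic), which the rest of the package uses
to reach arbitrary — including negative — time points with a single
unit-time integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import VesselGeometryError


class ShootingError(RuntimeError):
    pass


@dataclass(frozen=True)
class KernelDeformation:
    """Control points (mm) with attached momenta and kernel width sigma (mm)."""

    control_points: np.ndarray
    momenta: np.ndarray
    sigma: float = 4.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        m = np.atleast_2d(np.asarray(self.momenta, dtype=float))
        if c.shape != m.shape or c.ndim != 2 or c.shape[1] != 3:
            raise VesselGeometryError(
                f"control points {c.shape} and momenta {m.shape} must both be (k, 3)"
            )
        if not self.sigma > 0:
            raise VesselGeometryError("kernel width sigma must be positive")
        object.__setattr__(self, "control_points", c)
        object.__setattr__(self, "momenta", m)

    def scaled(self, factor: float) -> "KernelDeformation":
        return KernelDeformation(self.control_points, self.momenta * factor, self.sigma)


def kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix exp(-|x_i - y_j|^2 / (2 sigma^2))."""
    if not sigma > 0:
        raise VesselGeometryError("sigma must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def hamiltonian(c: np.ndarray, m: np.ndarray, sigma: float) -> float:
    """Kinetic energy H = 1/2 sum_{k,l} (m_k . m_l) K(c_k, c_l)."""
    K = kernel(c, c, sigma)
    return 0.5 * float(np.einsum("ki,li,kl->", m, m, K))


def _rhs(c: np.ndarray, m: np.ndarray, x: np.ndarray | None, sigma: float):
    inv2s2 = 1.0 / (2.0 * sigma**2)
    c2 = (c**2).sum(-1)
    K = np.exp(-(c2[:, None] + c2[None, :] - 2.0 * c @ c.T) * inv2s2)
    dc = K @ m
    # dm_k = sum_l (m_k.m_l) (c_k - c_l)/sigma^2 K_kl  (= -grad_{c_k} H),
    # assembled as two matmuls: c_k * sum_l w_kl - (w c)_k with w = (mm^T ∘ K)/s^2
    w = (m @ m.T) * K / sigma**2
    dm = c * w.sum(-1)[:, None] - w @ c
    dx = None
    if x is not None:
        x2 = (x**2).sum(-1)
        Kx = np.exp(-(x2[:, None] + c2[None, :] - 2.0 * x @ c.T) * inv2s2)
        dx = Kx @ m
    return dc, dm, dx


def shoot(
    deformation: KernelDeformation,
    landmarks: np.ndarray | None = None,
    t: float = 1.0,
    n_steps: int = 10,
) -> tuple[KernelDeformation, np.ndarray | None]:
    """Integrate the geodesic to time ``t`` and advect ``landmarks`` along it.

    Negative ``t`` shoots backwards.  Returns the evolved deformation state
    and the advected landmarks (None if none given).
    """
    if n_steps < 1:
        raise VesselGeometryError("n_steps must be >= 1")
    if not np.isfinite(t):
        raise VesselGeometryError("shooting time must be finite")
    sigma = deformation.sigma
    c = deformation.control_points.copy()
    # time rescaling: momenta m over time t == momenta t*m over unit time
    m = deformation.momenta * t
    x = None if landmarks is None else np.asarray(landmarks, dtype=float).copy()
    if np.allclose(m, 0.0):
        return KernelDeformation(c, deformation.momenta, sigma), x

    h = 1.0 / n_steps
    for _ in range(n_steps):
        k1 = _rhs(c, m, x, sigma)
        k2 = _rhs(c + h / 2 * k1[0], m + h / 2 * k1[1],
                  None if x is None else x + h / 2 * k1[2], sigma)
        k3 = _rhs(c + h / 2 * k2[0], m + h / 2 * k2[1],
                  None if x is None else x + h / 2 * k2[2], sigma)
        k4 = _rhs(c + h * k3[0], m + h * k3[1],
                  None if x is None else x + h * k3[2], sigma)
        c = c + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m = m + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if x is not None:
            x = x + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(m))):
        raise ShootingError(
            "geodesic integration diverged; increase n_steps or reduce momenta"
        )
    # return momenta on the original (per-unit-t) scale
    final = KernelDeformation(c, m / t if t != 0 else deformation.momenta, sigma)
    return final, x


def shoot_landmarks(
    deformation: KernelDeformation,
    landmarks: np.ndarray,
    t: float = 1.0,
    n_steps: int = 10,
) -> np.ndarray:
    """Convenience wrapper returning only the advected landmarks."""
    return shoot(deformation, landmarks, t=t, n_steps=n_steps)[1]


def control_point_grid(
    landmarks: np.ndarray, spacing: float, prune_distance: float | None = None
) -> np.ndarray:
    """Regular control-point grid over the landmark bounding box.

    Grid spacing defaults to the kernel width; points farther than
    ``prune_distance`` (default: the spacing) from every landmark are pruned.
    """
    pts = np.asarray(landmarks, dtype=float)
    if prune_distance is None:
        prune_distance = spacing
    lo = pts.min(axis=0) - spacing / 2
    hi = pts.max(axis=0) + spacing / 2
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(grid)
    kept = grid[d <= prune_distance]
    if kept.shape[0] == 0:
        raise VesselGeometryError("control-point grid pruned to nothing")
    return kept
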