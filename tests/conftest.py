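import numpy as np
import pytest

from vesseltraj import (
    CenterlineCurve,
    CohortConfig,
    GENERATOR_LABELS,
    VesselScan,
    generate_artery_curve,
    to_point_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_helix(n=2000, radius=1.0, pitch=2 * np.pi, turns=1.0, label="ICA-L"):
    """Unit helix: one turn, closed-form length 2*pi*sqrt(2) for defaults."""
    u = np.linspace(0.0, turns, n)
    pts = np.column_stack([radius * np.cos(2 * np.pi * u), radius * np.sin(2 * np.pi * u), pitch * u])
    return CenterlineCurve(label, pts, np.full(n, 1.0))


def make_semicircle(n=1000, r=1.0, label="BA"):
    th = np.linspace(0.0, np.pi, n)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
    return CenterlineCurve(label, pts, np.full(n, 1.0))


def random_rigid(rng):
    """Uniformly random proper rotation + translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-20, 20, 3)


@pytest.fixture
def population_scan():
    """Noise-free population-mean scan at the reference age."""
    cfg = CohortConfig(sigma_xi=0, sigma_tau=0, sigma_source=0, sigma_noise=0)
    curves = tuple(
        generate_artery_curve(lab, None, cfg.reference_age, cfg) for lab in GENERATOR_LABELS
    )
    return VesselScan("pop", cfg.reference_age, curves, "v00")


@pytest.fixture
def small_shape(population_scan):
    return to_point_set(population_scan, 6)
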