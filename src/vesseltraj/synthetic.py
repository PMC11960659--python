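"""Synthetic longitudinal cohorts of cerebral-artery centerlines.

The generator emulates the statistical structure of a longitudinal MRA
follow-up cohort — ~110 subjects, first scan at 57.3 (15.8) years, 3.6 (1.3)
visits spanning 6.1 (2.6) years — with a known ground-truth trajectory so
that every downstream estimator can be validated against the latent truth.

Each artery is a parametric helical arc placed in a common head frame.  A
helix with ``n`` turns, transverse radius ``R`` and axial rise ``H`` has
closed-form arc length ``L = sqrt((2 pi n R)^2 + H^2)`` and chord
``C = sqrt(H^2 + 2 R^2 (1 - cos 2 pi n))``, so for any target (length,
tortuosity-index) pair the pair (R, H) is solved exactly and the generated
curve's analytic morphometrics follow the configured per-artery trend —
linear in *warped* age — by construction.  The internal carotid gets two full
turns (a siphon-like segment, tortuosity index O(1)); the middle cerebral and
basilar are gentle arcs (index < 0.2).

Subject-level structure mirrors the trajectory model: log-acceleration
``xi_i ~ N(0, sigma_xi^2)``, time shift ``tau_i ~ N(0, sigma_tau^2)`` (plus
configured covariate effects), source loadings ``s_i ~ N(0, sigma_source^2)``
applied through fixed smooth sinusoidal displacement fields, and i.i.d.
Gaussian landmark noise.  Each visit at age ``t`` renders the population
geometry at the warped age ``psi_i(t) = alpha_i (t - t0 - tau_i) + t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import CenterlineCurve, GENERATOR_LABELS, VesselGeometryError, VesselScan

MIN_ADULT_AGE = 18.0
_FIELD_SEED = 20240917  # fixes the smooth source displacement fields


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ArteryTrend:
    """Per-decade drift of one artery's analytic morphometrics."""

    length_pct: float = 0.0  # percent of baseline length per decade
    tortuosity: float = 0.0  # tortuosity-index units per decade
    radius_mm: float = 0.0  # mm per decade


@dataclass(frozen=True)
class ArteryFamily:
    """Baseline helix parameters of one artery family at the reference age."""

    length0: float
    tortuosity0: float
    radius0: float
    turns: float
    origin: tuple[float, float, float]
    axis: tuple[float, float, float]


#: Baselines match typical first-visit medians of the artery set: a long,
#: strongly coiled carotid siphon, short near-straight M1, mid-length A1+A2
#: with small caliber, and moderately curved posterior vessels.
ARTERY_FAMILIES: dict[str, ArteryFamily] = {
    "ICA": ArteryFamily(78.0, 0.88, 2.04, 2.0, (14.0, -6.0, -32.0), (0.05, 0.15, 0.99)),
    "MCA": ArteryFamily(17.6, 0.08, 1.28, 0.75, (13.0, 2.0, 0.0), (0.95, 0.25, 0.15)),
    "ACA": ArteryFamily(47.8, 0.14, 0.92, 1.0, (4.0, 6.0, 2.0), (-0.1, 0.75, 0.65)),
    "BA": ArteryFamily(29.6, 0.10, 1.56, 0.5, (0.0, -26.0, -28.0), (0.0, 0.2, 0.98)),
    "PCA": ArteryFamily(32.4, 0.30, 0.94, 0.5, (3.0, -20.0, -4.0), (0.85, -0.5, 0.1)),
}

#: Trend defaults calibrated so a typical 6-year interval reproduces the
#: reported sign pattern and rough magnitudes: carotid/anterior lengthening
#: ~1 % per 6 y, rising tortuosity, ACA caliber loss of 3-5 % per 6 y.
DEFAULT_TRENDS: dict[str, ArteryTrend] = {
    "ICA": ArteryTrend(length_pct=2.0, tortuosity=0.033, radius_mm=0.03),
    "MCA": ArteryTrend(length_pct=2.5, tortuosity=0.010, radius_mm=0.02),
    "ACA": ArteryTrend(length_pct=1.8, tortuosity=0.017, radius_mm=-0.065),
    "BA": ArteryTrend(length_pct=0.8, tortuosity=0.008, radius_mm=0.0),
    "PCA": ArteryTrend(length_pct=0.3, tortuosity=0.0, radius_mm=-0.02),
}


@dataclass(frozen=True)
class CovariateSpec:
    """A binary per-subject factor with optional latent effects."""

    name: str
    prevalence: float
    effect_xi: float = 0.0
    effect_tau: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise CohortConfigError(f"prevalence of {self.name!r} outside [0, 1]")


#: Default factor panel with prevalences from a 110-patient follow-up cohort
#: (61/110 hypertensive, 18/110 diabetic, ...); all latent effects zero.
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("male", 19 / 110),
    CovariateSpec("smoker", 39 / 110),
    CovariateSpec("hypertension", 61 / 110),
    CovariateSpec("diabetes", 18 / 110),
    CovariateSpec("dyslipidemia", 65 / 110),
    CovariateSpec("ica_aneurysm", 83 / 110),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and variance parameters of the synthetic cohort."""

    n_subjects: int = 110
    age_mean: float = 57.32
    age_sd: float = 15.82
    followup_mean: float = 6.11
    followup_sd: float = 2.60
    visits_mean: float = 3.6
    visits_sd: float = 1.3
    min_visits: int = 2
    sigma_xi: float = 0.4
    sigma_tau: float = 5.0
    n_sources: int = 10
    sigma_source: float = 1.0
    sigma_noise: float = 0.05
    t0: float | None = None  # reference age; default age_mean
    points_per_curve: int = 60
    trends: dict[str, ArteryTrend] = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortConfigError("need n_subjects >= 2")
        for name in ("age_sd", "followup_sd", "visits_sd", "sigma_xi", "sigma_tau",
                     "sigma_source", "sigma_noise"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if self.min_visits < 2:
            raise CohortConfigError("min_visits must be >= 2")
        if self.points_per_curve < 30:
            raise CohortConfigError("points_per_curve must be >= 30")

    @property
    def reference_age(self) -> float:
        return self.age_mean if self.t0 is None else self.t0

    def trend_for(self, label: str) -> ArteryTrend:
        family = label.split("-")[0]
        return self.trends.get(label, self.trends.get(family, ArteryTrend()))


@dataclass(frozen=True)
class GroundTruth:
    """Latent variables behind one generated cohort."""

    subject_ids: tuple[str, ...]
    xi: np.ndarray
    tau: np.ndarray
    sources: np.ndarray  # (n_subjects, n_sources)
    t0: float

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.xi.shape != (n,) or self.tau.shape != (n,) or self.sources.shape[0] != n:
            raise CohortConfigError("ground-truth dimensions do not match subjects")

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.xi)

    def to_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "xi": self.xi.tolist(),
            "tau": self.tau.tolist(),
            "sources": self.sources.tolist(),
            "t0": self.t0,
        }


@dataclass(frozen=True)
class Subject:
    subject_id: str
    scans: tuple[VesselScan, ...]
    covariates: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]
    config: CohortConfig

    def covariates_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": s.subject_id, **{k: int(v) for k, v in s.covariates.items()}}
                for s in self.subjects]
        return pd.DataFrame(rows)

    def all_scans(self) -> list[VesselScan]:
        return [sc for s in self.subjects for sc in s.scans]


# -------------------------------------------------------------- geometry


def _rotation_to(axis: Sequence[float]) -> np.ndarray:
    """Rotation taking +z onto ``axis`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def analytic_morphometrics(
    label: str, warped_age: float, config: CohortConfig
) -> tuple[float, float, float]:
    """Closed-form (length, tortuosity index, mean radius) of one artery."""
    family = label.split("-")[0]
    if family not in ARTERY_FAMILIES:
        raise VesselGeometryError(f"unknown artery label {label!r}")
    fam = ARTERY_FAMILIES[family]
    tr = config.trend_for(label)
    decades = (warped_age - config.reference_age) / 10.0
    L = fam.length0 * (1.0 + tr.length_pct / 100.0 * decades)
    T = fam.tortuosity0 + tr.tortuosity * decades
    r = fam.radius0 + tr.radius_mm * decades
    if L <= 0 or r <= 0:
        raise VesselGeometryError(
            f"{label}: trend drives length/radius non-positive at warped age {warped_age}"
        )
    return float(L), float(max(T, 1e-4)), float(r)


def _helix_geometry(L: float, T: float, turns: float) -> tuple[float, float]:
    """Solve (R, H) of a ``turns``-turn helix with arc length L, index T."""
    C = L / (1.0 + T)
    omega = 2.0 * np.pi * turns
    q = 2.0 * (1.0 - np.cos(omega))
    denom = omega**2 - q
    if denom <= 0:
        raise VesselGeometryError("helix turn count too small for tortuosity control")
    R2 = (L**2 - C**2) / denom
    H2 = C**2 - q * R2
    if H2 <= 0:
        raise VesselGeometryError(
            f"tortuosity {T} unreachable with {turns} turns (chord collapses)"
        )
    return float(np.sqrt(R2)), float(np.sqrt(H2))


def _source_fields(n_sources: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed smooth sinusoidal displacement fields (amplitude, wavevector, phase)."""
    rng = np.random.default_rng(_FIELD_SEED)
    amp = rng.standard_normal((n_sources, 3))
    amp /= np.linalg.norm(amp, axis=1, keepdims=True)
    # wavelengths ~ 30-80 mm: smooth over the whole arterial tree
    k = rng.uniform(2 * np.pi / 80.0, 2 * np.pi / 30.0, (n_sources, 3))
    k *= rng.choice([-1.0, 1.0], (n_sources, 3))
    phase = rng.uniform(0.0, 2 * np.pi, n_sources)
    return amp, k, phase


def source_displacement(points: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Evaluate the fixed source fields: sum_j s_j a_j sin(k_j . x + phi_j)."""
    loadings = np.atleast_1d(np.asarray(loadings, dtype=float))
    amp, k, phase = _source_fields(len(loadings))
    disp = np.zeros_like(points)
    for j, s in enumerate(loadings):
        if s == 0.0:
            continue
        disp += s * np.sin(points @ k[j] + phase[j])[:, None] * amp[j][None, :]
    return disp


def generate_artery_curve(
    label: str,
    subject_base: np.ndarray | None,
    warped_age: float,
    config: CohortConfig,
) -> CenterlineCurve:
    """Render one artery at a warped age, with the subject's source shifts.

    ``subject_base`` is the subject's source-loading vector (age-constant);
    None or empty means the population-mean geometry.  Landmark noise is NOT
    added here — the curve is the noiseless subject geometry.
    """
    if label not in GENERATOR_LABELS:
        raise VesselGeometryError(f"generator does not produce artery {label!r}")
    family = label.split("-")[0]
    fam = ARTERY_FAMILIES[family]
    L, T, rbar = analytic_morphometrics(label, warped_age, config)
    R, H = _helix_geometry(L, T, fam.turns)

    n = config.points_per_curve
    u = np.linspace(0.0, 1.0, n)
    omega = 2.0 * np.pi * fam.turns
    local = np.column_stack(
        [R * (np.cos(omega * u) - 1.0), R * np.sin(omega * u), H * u]
    )
    pts = local @ _rotation_to(fam.axis).T + np.asarray(fam.origin)
    if label.endswith("-L"):
        pts = pts * np.array([-1.0, 1.0, 1.0])
    # helix is constant-speed, so a linear taper in u keeps the arc-length
    # weighted mean radius exactly at rbar
    radii = rbar * (1.0 - 0.3 * (u - 0.5))
    if subject_base is not None and np.asarray(subject_base).size:
        pts = pts + source_displacement(pts, subject_base)
    return CenterlineCurve(label, pts, radii)


# ------------------------------------------------------------ cohort draws


def sample_subject_schedule(config: CohortConfig, rng: np.random.Generator) -> list[float]:
    """Visit ages for one subject: truncated-normal first age (adults only),
    follow-up span and visit count; interior visits uniform over the span."""
    age0 = rng.normal(config.age_mean, config.age_sd)
    while age0 < MIN_ADULT_AGE:
        age0 = rng.normal(config.age_mean, config.age_sd)
    span = rng.normal(config.followup_mean, config.followup_sd)
    tries = 0
    while span <= 0:
        span = rng.normal(config.followup_mean, config.followup_sd)
        tries += 1
        if tries > 1000:  # degenerate config (mean<=0, sd 0)
            raise CohortConfigError("follow-up span distribution never positive")
    n_visits = max(config.min_visits, int(np.rint(rng.normal(config.visits_mean, config.visits_sd))))
    interior = np.sort(rng.uniform(0.0, span, n_visits - 2)) if n_visits > 2 else np.array([])
    ages = np.concatenate([[0.0], interior, [span]]) + age0
    # interior uniforms are a.s. distinct; enforce strictness for safety
    for i in range(1, len(ages)):
        if ages[i] <= ages[i - 1]:
            ages[i] = ages[i - 1] + 1e-6
    return [float(a) for a in ages]


def attach_covariates(
    subject_ids: Sequence[str], config: CohortConfig, rng: np.random.Generator
) -> list[dict[str, bool]]:
    """Draw the binary factor panel for each subject."""
    flags: list[dict[str, bool]] = [dict() for _ in subject_ids]
    for cov in config.covariates:
        draws = rng.uniform(size=len(subject_ids)) < cov.prevalence
        for f, d in zip(flags, draws):
            f[cov.name] = bool(d)
    return flags


def population_points(warped_age: float, config: CohortConfig) -> np.ndarray:
    """Population-mean landmark stack (all arteries, generator order)."""
    return np.vstack(
        [
            generate_artery_curve(lab, None, warped_age, config).points
            for lab in GENERATOR_LABELS
        ]
    )


def source_basis_fields(config: CohortConfig) -> np.ndarray:
    """Per-landmark source displacement blocks (n_sources, N, 3).

    The fixed sinusoidal fields are evaluated at the reference-age population
    landmarks and orthogonalized against the instantaneous trend velocity, so
    geometric variability is separable from progression — mirroring the
    trajectory model, whose space shifts are orthogonal to the population
    geodesic by construction.  Applied by landmark index, the resulting
    displacement is exactly age-constant per subject.
    """
    P0 = population_points(config.reference_age, config)
    eps = 0.5
    # tangent directions of the population trajectory across the cohort's
    # age range: geometric variability is orthogonal to all of them, so a
    # static source shift can never mimic a position on the trajectory
    half_range = 2.5 * config.age_sd + 10.0
    tangents = []
    for d in np.linspace(-half_range, half_range, 9):
        t = config.reference_age + d
        v = (
            population_points(t + eps, config) - population_points(t - eps, config)
        ) / (2 * eps)
        tangents.append(v.ravel())
    T = np.array(tangents).T  # (3N, q)
    norms = np.linalg.norm(T, axis=0)
    T = T[:, norms > 1e-12]
    Q = None
    if T.shape[1]:
        Q, R = np.linalg.qr(T)
        Q = Q[:, np.abs(np.diag(R)) > 1e-10 * np.abs(R).max()]
    amp, k, phase = _source_fields(config.n_sources)
    fields = np.empty((config.n_sources, P0.shape[0], 3))
    for j in range(config.n_sources):
        F = np.sin(P0 @ k[j] + phase[j])[:, None] * amp[j][None, :]
        if Q is not None:
            Ff = F.ravel()
            F = (Ff - Q @ (Q.T @ Ff)).reshape(F.shape)
        fields[j] = F
    return fields


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full longitudinal cohort and its latent ground truth.

    Covariate flags are drawn first so their configured effects are already
    reflected in each subject's (xi, tau); all randomness flows from
    ``config.seed``.  With all variance parameters zero every subject's scan
    at age t reproduces the population geometry at t exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = tuple(f"S{i:04d}" for i in range(n))
    flags = attach_covariates(ids, config, rng)

    xi = rng.normal(0.0, config.sigma_xi, n) if config.sigma_xi > 0 else np.zeros(n)
    tau = rng.normal(0.0, config.sigma_tau, n) if config.sigma_tau > 0 else np.zeros(n)
    for i, f in enumerate(flags):
        for cov in config.covariates:
            if f[cov.name]:
                xi[i] += cov.effect_xi
                tau[i] += cov.effect_tau
    J = config.n_sources
    sources = (
        rng.normal(0.0, config.sigma_source, (n, J))
        if config.sigma_source > 0
        else np.zeros((n, J))
    )
    t0 = config.reference_age
    alpha = np.exp(xi)
    fields = source_basis_fields(config)  # (J, N_total, 3), trend-orthogonal
    n_pts = config.points_per_curve

    subjects = []
    for i, sid in enumerate(ids):
        ages = sample_subject_schedule(config, rng)
        shift = np.einsum("j,jnk->nk", sources[i], fields)  # age-constant
        scans = []
        for v, t in enumerate(ages):
            warped = alpha[i] * (t - t0 - tau[i]) + t0
            curves = []
            for a, lab in enumerate(GENERATOR_LABELS):
                c = generate_artery_curve(lab, None, warped, config)
                pts = c.points + shift[a * n_pts : (a + 1) * n_pts]
                if config.sigma_noise > 0:
                    pts = pts + rng.normal(0.0, config.sigma_noise, pts.shape)
                c = CenterlineCurve(lab, pts, c.radii)
                curves.append(c)
            scans.append(
                VesselScan(subject_id=sid, age=t, curves=tuple(curves), scan_id=f"v{v:02d}")
            )
        subjects.append(Subject(sid, tuple(scans), flags[i]))
    truth = GroundTruth(ids, xi, tau, sources, t0)
    return Cohort(tuple(subjects), config), truth
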