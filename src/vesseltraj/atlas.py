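"""Mixed-effects diffeomorphic trajectory model for longitudinal shapes.

The population follows a geodesic through a template ``X0`` at reference time
``t0``, parameterized by control-point momenta ``m0`` (per year).  Subject
``i`` deviates from the population in time and in space:

* time reparameterization  ``psi_i(t) = alpha_i (t - t0 - tau_i) + t0`` with
  acceleration ``alpha_i = exp(xi_i)`` (speed of progression relative to the
  population) and time shift ``tau_i`` (vascular age offset: positive tau
  means the subject's anatomy lags its chronological age);
* a space shift ``sum_j s_ij A_j`` built from a low-dimensional basis of
  geometric sources ``A_j`` with standardized loadings ``s_ij``.

The prediction for subject ``i`` at age ``t`` applies the space shift to the
template and transports it along the population geodesic to the warped time:
``X_i(t) = Shoot(m0 * (psi_i(t) - t0), X0 + sum_j s_ij A_j)`` — a first-order
stand-in for exact parallel transport of the shift along the geodesic.

Estimation mirrors the staged initialization of longitudinal shape atlases:
Procrustes template; per-subject geodesic regressions; averaged momenta shot
from the mean initial age to the mean age over all scans (giving ``m0`` and
``t0``); ICA of residual displacement fields (the sources); per-subject
longitudinal registration; then block-coordinate MAP ascent of the Gaussian
log-posterior, with an optional short-chain MCMC-SAEM refinement.  The model
is invariant to joint rescaling of (alpha, m0) and joint shifts of (tau, t0),
so after every population update the latents are centered: mean xi = 0 and
mean tau = 0 exactly, absorbed into ``m0`` and ``t0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA, FastICA

from .curves import PointSetShape, VesselGeometryError
from .registration import build_initial_template, rigid_align
from .shooting import KernelDeformation, control_point_grid, shoot

__all__ = [
    "SubjectParams",
    "LongitudinalAtlas",
    "FitReport",
    "AtlasConfig",
    "SubjectShapeSeries",
    "time_warp",
    "predict_shape",
    "geodesic_regression",
    "extract_sources",
    "estimate_atlas",
]


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject latent variables of the trajectory model."""

    xi: float = 0.0  # log-acceleration
    tau: float = 0.0  # time shift, years
    sources: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.sources, dtype=float))
        if not np.all(np.isfinite(s)) or not np.isfinite(self.xi) or not np.isfinite(self.tau):
            raise VesselGeometryError("subject parameters must be finite")
        object.__setattr__(self, "sources", s)

    @property
    def alpha(self) -> float:
        """Acceleration factor, always positive."""
        return float(np.exp(self.xi))


def time_warp(t, params: SubjectParams, t0: float):
    """Warped age psi_i(t) = alpha_i (t - t0 - tau_i) + t0."""
    return params.alpha * (np.asarray(t, dtype=float) - t0 - params.tau) + t0


@dataclass
class FitReport:
    log_posterior: float
    residual_rms: float
    trace: list[float]
    converged: bool
    n_control_points: int = 0
    mode: str = "map"


@dataclass
class LongitudinalAtlas:
    """Fitted population trajectory plus per-subject parameters."""

    template: PointSetShape  # X0, at reference time t0
    t0: float
    momenta: KernelDeformation  # m0, per year
    source_modes: np.ndarray  # (J, N, 3), unit Frobenius norm each
    source_scales: np.ndarray  # (J,), mm — fold loadings back to displacements
    sigma_eps: float  # residual noise sd, mm
    sigma_xi: float
    sigma_tau: float
    subject_ids: list[str] = field(default_factory=list)
    subject_params: list[SubjectParams] = field(default_factory=list)
    n_steps: int = 10

    def __post_init__(self) -> None:
        J = self.source_modes.shape[0] if self.source_modes.size else 0
        if J:
            flat = self.source_modes.reshape(J, -1)
            # degenerate (near-identical) modes would make loadings unidentifiable
            norms = np.linalg.norm(flat, axis=1)
            nz = norms > 0
            if nz.sum() > 1:
                C = np.corrcoef(flat[nz])
                off = np.abs(C - np.eye(nz.sum())).max()
                if off >= 0.99:
                    raise VesselGeometryError("source basis modes are degenerate")
        if not self.sigma_eps > 0:
            raise VesselGeometryError("sigma_eps must be positive")

    @property
    def n_sources(self) -> int:
        return int(self.source_modes.shape[0]) if self.source_modes.size else 0

    def space_shift(self, params: SubjectParams) -> np.ndarray:
        if self.n_sources == 0 or params.sources.size == 0:
            return np.zeros_like(self.template.points)
        s = params.sources[: self.n_sources]
        return np.einsum("j,jnk->nk", s * self.source_scales, self.source_modes)

    def params_frame(self):
        import pandas as pd

        rows = []
        for sid, p in zip(self.subject_ids, self.subject_params):
            row = {"subject_id": sid, "alpha": p.alpha, "xi": p.xi, "tau": p.tau}
            for j, s in enumerate(p.sources, start=1):
                row[f"s_{j}"] = s
            rows.append(row)
        return pd.DataFrame(rows)


def predict_shape(atlas: LongitudinalAtlas, params: SubjectParams, t: float) -> PointSetShape:
    """Subject-specific shape at age ``t`` under the fitted model."""
    if params.sources.size not in (0, atlas.n_sources):
        raise VesselGeometryError(
            f"params carry {params.sources.size} loadings, atlas has {atlas.n_sources} sources"
        )
    X = atlas.template.points + atlas.space_shift(params)
    dt = float(time_warp(t, params, atlas.t0) - atlas.t0)
    _, moved = shoot(atlas.momenta, X, t=dt, n_steps=atlas.n_steps)
    return atlas.template.with_points(moved)


# ----------------------------------------------------------- batched shooting


def _shoot_batch(
    c0: np.ndarray, momenta: np.ndarray, landmarks: np.ndarray, sigma: float, n_steps: int
) -> np.ndarray:
    """RK4-integrate B geodesics at once; returns advected landmarks (B,N,3).

    ``c0`` (K,3) is shared across the batch, ``momenta`` is (B,K,3) (already
    scaled by each shot's time) and ``landmarks`` is (B,N,3).
    """
    B = momenta.shape[0]
    c = np.broadcast_to(c0, momenta.shape).copy()
    m = momenta.copy()
    x = landmarks.copy()
    if np.allclose(m, 0.0):
        return x
    inv2s2 = 1.0 / (2.0 * sigma**2)

    def rhs(c, m, x):
        # all-matmul formulation (no B*K*K*3 temporaries):
        #   dm_k = [c_k * sum_l w_kl - (w c)_k] / 1,  w = (m m^T ∘ K) / sigma^2
        c2 = (c**2).sum(-1)
        K = np.exp(-(c2[:, :, None] + c2[:, None, :] - 2.0 * (c @ c.transpose(0, 2, 1))) * inv2s2)
        dc = K @ m
        w = (m @ m.transpose(0, 2, 1)) * K / sigma**2
        dm = c * w.sum(-1)[..., None] - w @ c
        x2 = (x**2).sum(-1)
        Kx = np.exp(-(x2[:, :, None] + c2[:, None, :] - 2.0 * (x @ c.transpose(0, 2, 1))) * inv2s2)
        dx = Kx @ m
        return dc, dm, dx

    h = 1.0 / n_steps
    for _ in range(n_steps):
        k1 = rhs(c, m, x)
        k2 = rhs(c + h / 2 * k1[0], m + h / 2 * k1[1], x + h / 2 * k1[2])
        k3 = rhs(c + h / 2 * k2[0], m + h / 2 * k2[1], x + h / 2 * k2[2])
        k4 = rhs(c + h * k3[0], m + h * k3[1], x + h * k3[2])
        c = c + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m = m + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        x = x + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    if not np.all(np.isfinite(x)):
        raise VesselGeometryError("batched geodesic integration diverged")
    return x


# -------------------------------------------------------- geodesic regression


def geodesic_regression(
    scans: Sequence[tuple[float, PointSetShape]],
    sigma: float,
    control_points: np.ndarray | None = None,
    n_steps: int = 10,
    maxiter: int = 20,
) -> tuple[PointSetShape, KernelDeformation, float]:
    """Fit per-year momenta carrying the first scan onto the later ones.

    The template is fixed to the first-visit shape; the summed squared
    landmark mismatch over later visits is minimized over the momenta
    (L-BFGS with a linearized least-squares initialization).  Returns
    (initial shape, fitted per-year momenta, residual RMS in mm).
    """
    if len(scans) < 2:
        raise VesselGeometryError("geodesic regression needs >= 2 scans")
    scans = sorted(scans, key=lambda az: az[0])
    ages = np.array([a for a, _ in scans], dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise VesselGeometryError("geodesic regression needs distinct, increasing ages")
    X1 = scans[0][1]
    Ys = np.stack([s.points for _, s in scans[1:]])
    dts = ages[1:] - ages[0]
    if control_points is None:
        control_points = control_point_grid(X1.points, spacing=sigma)
    cp = np.asarray(control_points, dtype=float)
    K = cp.shape[0]
    N = X1.points.shape[0]

    # linearized warm start: displacement ~= dt * K_xc m  (small-deformation limit)
    d2 = ((X1.points[:, None, :] - cp[None, :, :]) ** 2).sum(-1)
    Kxc = np.exp(-d2 / (2.0 * sigma**2))
    A_blocks = np.concatenate([dt * Kxc for dt in dts], axis=0)  # (V*N, K)
    b = (Ys - X1.points).reshape(-1, 3)
    lam = 1e-6 * np.trace(A_blocks.T @ A_blocks) / K
    m0 = np.linalg.solve(A_blocks.T @ A_blocks + lam * np.eye(K), A_blocks.T @ b)

    X_tiled = np.broadcast_to(X1.points, (len(dts), N, 3)).copy()

    def objective(m_flat: np.ndarray) -> float:
        m = m_flat.reshape(K, 3)
        mom = m[None] * dts[:, None, None]
        pred = _shoot_batch(cp, mom, X_tiled, sigma, n_steps)
        return float(((pred - Ys) ** 2).sum())

    if maxiter > 0:
        f0 = objective(m0.ravel())
        res = minimize(
            objective,
            m0.ravel(),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": maxiter * (3 * K + 2)},
        )
        m_fit = (res.x if res.fun <= f0 else m0.ravel()).reshape(K, 3)
    else:  # linearized solution only (small-deformation regime)
        m_fit = m0
    rms = float(np.sqrt(objective(m_fit.ravel()) / (len(dts) * N * 3)))
    return X1, KernelDeformation(cp, m_fit, sigma), rms


# ------------------------------------------------------------------- sources


@dataclass
class SourceModel:
    modes: np.ndarray  # (J, N, 3), unit norm
    loadings: np.ndarray  # (n_subjects, J), unit sample variance per mode
    scales: np.ndarray  # (J,)
    zero_variance: bool = False
    reduced: bool = False
    method: str = "ica"


def extract_sources(
    space_shifts: np.ndarray, n_sources: int, seed: int = 0
) -> SourceModel:
    """ICA (fallback: PCA) decomposition of per-subject space-shift fields.

    ``space_shifts`` is (n_subjects, N, 3) or (n_subjects, D).  Modes are
    unit-normalized; loadings are standardized to unit sample variance with
    the displacement scale (mm) carried by ``scales``.
    """
    X = np.asarray(space_shifts, dtype=float)
    n = X.shape[0]
    shape3 = X.shape[1:] if X.ndim == 3 else None
    X = X.reshape(n, -1)
    D = X.shape[1]
    if n < n_sources:
        raise VesselGeometryError(f"need >= {n_sources} subjects for {n_sources} sources")
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-12):
        J = n_sources
        modes = np.zeros((J, D))
        return SourceModel(
            modes.reshape((J, *shape3) if shape3 else (J, D)),
            np.zeros((n, J)),
            np.zeros(J),
            zero_variance=True,
        )
    rank = np.linalg.matrix_rank(Xc, tol=1e-10 * max(1.0, np.abs(Xc).max()))
    J = min(n_sources, rank)
    reduced = J < n_sources
    if reduced:
        warnings.warn(
            f"space shifts have rank {rank}; reducing sources {n_sources} -> {J}",
            RuntimeWarning,
            stacklevel=2,
        )
    method = "ica"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ica = FastICA(
                n_components=J, whiten="unit-variance", random_state=seed, max_iter=1000
            )
            load = ica.fit_transform(Xc)  # (n, J), unit variance
            mixing = ica.mixing_  # (D, J)
    except Exception:
        method = "pca"
        pca = PCA(n_components=J, random_state=seed)
        raw = pca.fit_transform(Xc)
        sd = raw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        load = raw / sd
        mixing = (pca.components_.T * sd)  # (D, J)
    # normalize modes; fold displacement magnitude into scales
    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    modes = (mixing / norms).T  # (J, D)
    sd = load.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scales = norms * sd
    load = load / sd
    # deterministic sign convention: largest-magnitude mode entry positive
    for j in range(J):
        k = np.argmax(np.abs(modes[j]))
        if modes[j, k] < 0:
            modes[j] = -modes[j]
            load[:, j] = -load[:, j]
    return SourceModel(
        modes.reshape((J, *shape3) if shape3 else (J, D)),
        load,
        scales,
        reduced=reduced,
        method=method,
    )


# ------------------------------------------------------------- full estimator


@dataclass
class SubjectShapeSeries:
    """Longitudinal shape observations of one subject."""

    subject_id: str
    ages: list[float]
    shapes: list[PointSetShape]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.shapes) or len(self.ages) < 2:
            raise VesselGeometryError("each subject needs >= 2 age-matched shapes")
        order = np.argsort(self.ages)
        self.ages = [float(self.ages[i]) for i in order]
        self.shapes = [self.shapes[i] for i in order]


@dataclass
class AtlasConfig:
    kernel_mm: float = 4.0
    n_sources: int = 10
    n_steps: int = 10  # RK4 steps for unit-time shooting (predictions)
    mode: str = "map"  # "map" or "saem"
    iters: int = 10  # outer block-coordinate iterations
    seed: int = 0
    control_spacing: float | None = None  # default: kernel_mm
    reg_maxiter: int = 0  # 0: linearized per-subject regressions
    subject_maxiter: int = 50
    update_population: bool = True
    update_template: bool = True
    sigma_xi: float = 0.4
    sigma_tau: float = 5.0
    sigma_eps: float | None = None  # None: estimated from regressions
    tol: float = 1e-4
    align: str = "rigid"  # "rigid" | "none"
    source_projection: str = "v0"  # "v0" | "span": tangent directions removed
    table_step: float = 0.25  # warped-time tabulation step (years)
    xi_bound: float = 1.2  # ~3 prior sd
    tau_bound: float = 15.0  # ~3 prior sd
    source_bound: float = 6.0
    saem_sweeps: int = 20
    saem_proposal: float = 0.1


class _GeodesicTable:
    """Population trajectory tabulated on a dense warped-time grid.

    Landmark positions along the geodesic are recorded at every RK4 step of
    one forward and one backward integration from the template, then read off
    by linear interpolation in the warped-time offset ``d = psi - t0`` (and
    linearly extrapolated from the edge velocity outside the tabulated span).
    Because the trajectory moves by well under a millimetre per year, the
    interpolation error is far below the landmark noise for sub-year steps.
    """

    def __init__(
        self,
        cp: np.ndarray,
        m0: np.ndarray,
        X0: np.ndarray,
        sigma: float,
        span: float,
        step: float,
    ):
        from .shooting import KernelDeformation as _KD, shoot as _shoot

        self.span = float(max(span, step))
        n = max(int(np.ceil(self.span / step)), 1)
        self.h = self.span / n
        N = X0.shape[0]
        table = np.empty((2 * n + 1, N, 3))
        ctable = np.empty((2 * n + 1, cp.shape[0], 3))
        table[n] = X0
        ctable[n] = cp
        for direction in (+1.0, -1.0):
            order = range(n + 1, 2 * n + 1) if direction > 0 else range(n - 1, -1, -1)
            if np.allclose(m0, 0.0):
                for i in order:
                    table[i] = X0
                    ctable[i] = cp
                continue
            c, m, x = cp.copy(), m0 * direction, X0.copy()
            for i in order:
                state, x = _shoot(_KD(c, m, sigma), x, t=self.h, n_steps=1)
                c, m = state.control_points, state.momenta
                table[i] = x
                ctable[i] = c
        self.table = table
        self.ctable = ctable
        self.n = n

    def _interp(self, arr: np.ndarray, d: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        idx = d / self.h + self.n
        lo = np.clip(np.floor(idx).astype(int), 0, 2 * self.n - 1)
        frac = idx - lo  # may exceed [0,1] outside the span: linear extrapolation
        return (1.0 - frac)[:, None, None] * arr[lo] + frac[:, None, None] * arr[lo + 1]

    def at(self, d: np.ndarray) -> np.ndarray:
        """Landmark positions at warped-time offsets ``d`` (V,) -> (V, N, 3)."""
        return self._interp(self.table, d)

    def controls_at(self, d: np.ndarray) -> np.ndarray:
        """Control-point positions along the geodesic at offsets ``d``."""
        return self._interp(self.ctable, d)

def _subject_nlp(
    p: np.ndarray,
    ages: np.ndarray,
    Ys: np.ndarray,
    table: "_GeodesicTable",
    basis: np.ndarray,  # (J, N, 3) scaled modes
    t0: float,
    sig_eps: float,
    sig_xi: float,
    sig_tau: float,
) -> float:
    """Negative log-posterior of one subject's latents on the tabulated geodesic."""
    xi, tau = p[0], p[1]
    s = p[2:]
    d = np.exp(xi) * (ages - t0 - tau)
    pred = table.at(d)
    if s.size:
        pred = pred + np.einsum("j,jnk->nk", s, basis)[None]
    data = ((pred - Ys) ** 2).sum() / (2.0 * sig_eps**2)
    prior = xi**2 / (2 * sig_xi**2) + tau**2 / (2 * sig_tau**2) + (s**2).sum() / 2.0
    return float(data + prior)


def _profiled_nlp(
    q: np.ndarray,
    ages: np.ndarray,
    Ys: np.ndarray,
    table: "_GeodesicTable",
    Bf: np.ndarray,  # (J, 3N) flattened scaled modes
    BtB: np.ndarray,  # (J, J)
    t0: float,
    sig_eps: float,
    sig_xi: float,
    sig_tau: float,
) -> tuple[float, np.ndarray]:
    """(xi, tau) objective with the source loadings profiled out exactly.

    Given the time warp, the loadings are linear-Gaussian, so their MAP value
    is a J-dimensional ridge solve; returns the profiled objective and s*.
    """
    xi, tau = q
    d = np.exp(xi) * (ages - t0 - tau)
    r = Ys - table.at(d)  # (V, N, 3)
    V = r.shape[0]
    J = Bf.shape[0]
    if J:
        rhs = Bf @ r.sum(axis=0).ravel() / sig_eps**2
        s = np.linalg.solve(V * BtB / sig_eps**2 + np.eye(J), rhs)
        rf = r.reshape(V, -1) - (s @ Bf)[None]
        data = (rf**2).sum() / (2.0 * sig_eps**2)
        prior_s = (s**2).sum() / 2.0
    else:
        s = np.zeros(0)
        data = (r**2).sum() / (2.0 * sig_eps**2)
        prior_s = 0.0
    f = data + prior_s + xi**2 / (2 * sig_xi**2) + tau**2 / (2 * sig_tau**2)
    return float(f), s


def estimate_atlas(
    subjects: Sequence[SubjectShapeSeries], config: AtlasConfig | None = None
) -> tuple[LongitudinalAtlas, FitReport]:
    """Estimate the longitudinal atlas from per-subject shape series.

    Staged initialization — Procrustes template, linearized per-subject
    geodesic regressions, averaged momenta shot from the mean initial age to
    the mean age over all scans (t0), per-subject longitudinal registration,
    ICA of residual displacement fields — followed by block-coordinate MAP
    refinement.  High-dimensional blocks (population momenta, template) take
    guarded Gauss-Newton ridge steps in the small-deformation linearization;
    subject latents are optimized exactly on a tabulated population geodesic.
    ``config.mode == "saem"`` appends short-chain Metropolis sampling of the
    latents with stochastic-approximation variance updates.  Deterministic
    given ``config.seed``.
    """
    cfg = config or AtlasConfig()
    rng = np.random.default_rng(cfg.seed)
    if len(subjects) < 2:
        raise VesselGeometryError("atlas estimation needs >= 2 subjects")
    topo = subjects[0].shapes[0]
    for sub in subjects:
        for sh in sub.shapes:
            if not sh.same_topology(topo):
                raise VesselGeometryError(
                    f"subject {sub.subject_id}: shape topology mismatch"
                )
    sigma = cfg.kernel_mm
    N = topo.n_landmarks

    # (1) template from first-visit shapes; optionally move scans into its frame
    first_shapes = [sub.shapes[0] for sub in subjects]
    template0, _ = build_initial_template(first_shapes)
    if cfg.align == "rigid":
        aligned = [
            [rigid_align(sh, template0)[1].points for sh in sub.shapes]
            for sub in subjects
        ]
    else:
        aligned = [[sh.points for sh in sub.shapes] for sub in subjects]
        template0 = template0.with_points(np.mean([a[0] for a in aligned], axis=0))

    spacing = cfg.control_spacing or sigma
    cp = control_point_grid(template0.points, spacing=spacing)
    K = cp.shape[0]

    # (2) per-subject geodesic regressions (shared control points, linearized
    # by default) give initial momenta and the residual noise level
    reg_momenta, reg_rms = [], []
    for sub, pts in zip(subjects, aligned):
        scans = [(a, topo.with_points(p)) for a, p in zip(sub.ages, pts)]
        _, mom, rms = geodesic_regression(
            scans, sigma, control_points=cp, n_steps=cfg.n_steps, maxiter=cfg.reg_maxiter
        )
        reg_momenta.append(mom.momenta)
        reg_rms.append(rms)
    sig_eps = cfg.sigma_eps or max(float(np.mean(reg_rms)), 1e-3)
    update_sigma = cfg.sigma_eps is None
    sig_subj = np.full(len(subjects), sig_eps)  # heteroscedastic noise scale

    # (3) average momenta; shoot the template from the mean initial age to the
    # mean age over all scans, which becomes the reference time t0
    m0 = np.mean(reg_momenta, axis=0)
    t_init = float(np.mean([sub.ages[0] for sub in subjects]))
    t0 = float(np.mean([a for sub in subjects for a in sub.ages]))
    _, X0_pts = shoot(
        KernelDeformation(cp, m0, sigma), template0.points, t=t0 - t_init, n_steps=cfg.n_steps
    )
    X0 = X0_pts.copy()

    ages_arr = [np.asarray(sub.ages) for sub in subjects]
    Ys_arr = [np.stack(pts) for pts in aligned]
    params = [SubjectParams(0.0, 0.0, np.zeros(0)) for _ in subjects]
    empty_basis = np.zeros((0, N, 3))

    def make_table() -> _GeodesicTable:
        dmax = 1.0
        for i, p in enumerate(params):
            d = np.exp(p.xi) * (ages_arr[i] - t0 - p.tau)
            dmax = max(dmax, float(np.abs(d).max()))
        return _GeodesicTable(cp, m0, X0, sigma, span=dmax + 10.0, step=cfg.table_step)

    _xi_grid = np.linspace(-0.9, 0.9, 7)
    _tau_grid = np.linspace(-12.0, 12.0, 9)

    def register(i: int, p: SubjectParams, basis: np.ndarray, table: _GeodesicTable) -> SubjectParams:
        """Update one subject's latents: coarse (xi, tau) grid to escape local
        minima, L-BFGS polish, loadings profiled out exactly at each step."""
        J = basis.shape[0]
        Bf = basis.reshape(J, 3 * N) if J else np.zeros((0, 3 * N))
        BtB = Bf @ Bf.T
        args = (ages_arr[i], Ys_arr[i], table, Bf, BtB, t0, sig_subj[i], cfg.sigma_xi, cfg.sigma_tau)
        starts = [np.array([p.xi, p.tau])]
        f_best, _ = _profiled_nlp(starts[0], *args)
        q_best = starts[0]
        for xi0 in _xi_grid:
            for tau0 in _tau_grid:
                f, _ = _profiled_nlp(np.array([xi0, tau0]), *args)
                if f < f_best:
                    f_best, q_best = f, np.array([xi0, tau0])
        res = minimize(
            lambda q: _profiled_nlp(q, *args)[0],
            q_best,
            method="L-BFGS-B",
            bounds=[(-cfg.xi_bound, cfg.xi_bound), (-cfg.tau_bound, cfg.tau_bound)],
            options={"maxiter": cfg.subject_maxiter},
        )
        q = res.x if res.fun <= f_best else q_best
        f, s = _profiled_nlp(q, *args)
        return SubjectParams(q[0], q[1], s if J else np.zeros(0))

    def residuals(basis: np.ndarray, table: _GeodesicTable):
        """Per-scan residual Y - pred and warped offsets, concatenated."""
        res, dts = [], []
        for i, p in enumerate(params):
            d = np.exp(p.xi) * (ages_arr[i] - t0 - p.tau)
            pred = table.at(d)
            if basis.shape[0] and p.sources.size:
                pred = pred + np.einsum("j,jnk->nk", p.sources, basis)[None]
            res.append(Ys_arr[i] - pred)
            dts.append(d)
        return np.concatenate(res, axis=0), np.concatenate(dts)

    def total_objective(basis: np.ndarray, table: _GeodesicTable) -> float:
        # includes the Gaussian normalization M_i log sigma_i so that the
        # closed-form noise updates are exact M-steps (monotone objective)
        tot = 0.0
        for i, p in enumerate(params):
            pvec = np.concatenate([[p.xi, p.tau], p.sources[: basis.shape[0]]])
            tot += Ys_arr[i].size * np.log(sig_subj[i])
            tot += _subject_nlp(
                pvec, ages_arr[i], Ys_arr[i], table, basis, t0,
                sig_subj[i], cfg.sigma_xi, cfg.sigma_tau,
            )
        return float(tot)

    def center() -> None:
        nonlocal m0, t0, params, X0
        xi_bar = float(np.mean([p.xi for p in params]))
        tau_bar = float(np.mean([p.tau for p in params]))
        m0 = m0 * np.exp(xi_bar)
        t0 = t0 + tau_bar
        params = [
            SubjectParams(p.xi - xi_bar, p.tau - tau_bar, p.sources) for p in params
        ]

    # precompute the momenta design kernel at the template for ridge updates
    d2 = ((X0[:, None, :] - cp[None, :, :]) ** 2).sum(-1)
    Kxc = np.exp(-d2 / (2.0 * sigma**2))  # (N, K)

    scan_subject = np.concatenate(
        [np.full(len(sub.ages), i) for i, sub in enumerate(subjects)]
    )

    def refine_population(basis: np.ndarray, table: _GeodesicTable, obj: float):
        nonlocal m0, X0
        if cfg.update_population:
            # Gauss-Newton ridge step on the momenta, re-linearized around the
            # current trajectory: residual_v ~ d_v * K(x_v, c_v) dm with the
            # kernel design evaluated at each scan's predicted landmark and
            # control-point positions.  Residuals and design are centered
            # within subject so static per-subject space shifts cannot
            # contaminate the trend.
            r, d = residuals(basis, table)
            r = r.copy()
            d = d.copy()
            for i in range(len(subjects)):
                sel = scan_subject == i
                r[sel] -= r[sel].mean(axis=0)
                d[sel] -= d[sel].mean()
            r_raw, d_raw = residuals(basis, table)
            # robust weights: scans far out on the trajectory (extrapolation)
            # or fitting much worse than the bulk cannot dominate the
            # d^2-weighted normal equations
            scan_ms = (r_raw**2).mean(axis=(1, 2))
            bulk = max(float(np.median(scan_ms)), 1e-12)
            w_rob = np.minimum(1.0, (4.0 * bulk) / np.maximum(scan_ms, 1e-30))
            keep = np.abs(d_raw) <= max(3.0 * np.median(np.abs(d_raw)), 15.0)
            w = (w_rob * keep)[:, None]
            xs = table.at(d_raw)  # (S, N, 3)
            cs = table.controls_at(d_raw)  # (S, K, 3)
            x2 = (xs**2).sum(-1)
            c2 = (cs**2).sum(-1)
            Kv = np.exp(
                -(x2[:, :, None] + c2[:, None, :] - 2.0 * xs @ cs.transpose(0, 2, 1))
                / (2.0 * sigma**2)
            )  # (S, N, K)
            G = np.einsum("v,vnk,vnl->kl", w[:, 0] * d**2, Kv, Kv)
            b = np.einsum("v,vnk,vni->ki", w[:, 0] * d, Kv, r)
            lam = 1e-3 * max(np.trace(G) / K, 1e-12)
            A = G + lam * np.eye(K)
            dm = np.linalg.solve(A, b)
            step = 1.0
            for _try in range(4):
                m0_new = m0 + step * dm
                table_new = _GeodesicTable(cp, m0_new, X0, sigma, table.span, cfg.table_step)
                f_new = total_objective(basis, table_new)
                if f_new <= obj:
                    m0, table, obj = m0_new, table_new, f_new
                    break
                step /= 2.0
        if cfg.update_template:
            r, _ = residuals(basis, table)
            scan_ms = (r**2).mean(axis=(1, 2))
            bulk = max(float(np.median(scan_ms)), 1e-12)
            wt = np.minimum(1.0, (4.0 * bulk) / np.maximum(scan_ms, 1e-30))
            X0_new = X0 + np.einsum("v,vnk->nk", wt, r) / wt.sum()
            table_new = _GeodesicTable(cp, m0, X0_new, sigma, table.span, cfg.table_step)
            f_new = total_objective(basis, table_new)
            if f_new <= obj:
                X0, table, obj = X0_new, table_new, f_new
        if update_sigma:
            # robust global scale (median over per-scan mean squares), plus a
            # per-subject heteroscedastic scale floored at it: subjects the
            # trajectory extrapolates poorly for get wider error bars and
            # shrink toward the prior instead of chasing aliases
            nonlocal sig_eps
            r, _ = residuals(basis, table)
            per_scan = (r**2).mean(axis=(1, 2))
            sig_eps = max(float(np.sqrt(np.median(per_scan))), 1e-3)
            for i in range(len(subjects)):
                rms_i = float(np.sqrt(per_scan[scan_subject == i].mean()))
                sig_subj[i] = max(sig_eps, rms_i)
            obj = total_objective(basis, table)
        return table, obj

    def _trajectory_span(table: _GeodesicTable) -> np.ndarray | None:
        """Orthonormal basis (3N, q) of trajectory tangents over the data range.

        A static space shift lying along any tangent v(d) is indistinguishable
        from a position offset on the trajectory; projecting the source space
        against this span keeps the time warp identifiable.
        """
        _, d_raw = residuals(empty_basis, table)
        lo, hi = float(d_raw.min()) - 5.0, float(d_raw.max()) + 5.0
        if cfg.source_projection == "v0":
            ds = np.array([0.0])
        else:
            ds = np.linspace(lo, hi, 7)
        eps = table.h
        V = (table.at(ds + eps) - table.at(ds - eps)) / (2 * eps)
        Vf = V.reshape(len(ds), -1).T  # (3N, q)
        norms = np.linalg.norm(Vf, axis=0)
        Vf = Vf[:, norms > 1e-12]
        if Vf.shape[1] == 0:
            return None
        Q, R = np.linalg.qr(Vf)
        keep = np.abs(np.diag(R)) > 1e-10 * np.abs(R).max()
        return Q[:, keep]

    def extract_basis(table: _GeodesicTable):
        """Source basis from per-subject mean trajectory residuals,
        orthogonalized against the span of trajectory tangents (sources
        encode variability orthogonal to progression; a basis that could
        absorb the time warp would destroy tau identifiability)."""
        res_all, _ = residuals(empty_basis, table)
        shifts = np.zeros((len(subjects), N, 3))
        for i in range(len(subjects)):
            shifts[i] = res_all[scan_subject == i].mean(axis=0)
        Q = _trajectory_span(table)
        flat = shifts.reshape(len(subjects), -1)
        if Q is not None:
            flat = flat - (flat @ Q) @ Q.T
        src = extract_sources(flat.reshape(len(subjects), N, 3), J_req, seed=cfg.seed)
        J = src.modes.shape[0]
        if Q is not None and J:
            mflat = src.modes.reshape(J, -1)
            mflat = mflat - (mflat @ Q) @ Q.T
            norms = np.linalg.norm(mflat, axis=1)
            norms[norms == 0] = 1.0
            src.modes = (mflat / norms[:, None]).reshape(J, N, 3)
            src.scales = src.scales * norms
        if J > 1:
            # projection can collapse modes onto each other; keep a
            # non-degenerate subset (pairwise correlation < 0.99)
            mflat = src.modes.reshape(J, -1)
            keep: list[int] = []
            for j in range(J):
                if np.linalg.norm(mflat[j]) < 1e-10:
                    continue
                dup = any(
                    abs(np.dot(mflat[j], mflat[k]))
                    / max(np.linalg.norm(mflat[j]) * np.linalg.norm(mflat[k]), 1e-30)
                    >= 0.99
                    for k in keep
                )
                if not dup:
                    keep.append(j)
            if len(keep) < J:
                src.modes = src.modes[keep]
                src.scales = src.scales[keep]
                src.loadings = src.loadings[:, keep]
                src.reduced = True
        basis = src.scales[:, None, None] * src.modes
        return src, basis

    # (4) population-trend refinement before any latent registration (latents
    # start at zero, so static inter-subject variability cannot bias the
    # within-subject trend estimate), then source extraction, one preliminary
    # full registration pass, and a basis re-extraction with cleaner latents
    table = make_table()
    for _ in range(2):
        obj = total_objective(empty_basis, table)
        table, obj = refine_population(empty_basis, table, obj)

    J_req = min(cfg.n_sources, len(subjects))
    if J_req > 0:
        src, basis = extract_basis(table)
        J = src.modes.shape[0]
        params = [
            SubjectParams(p.xi, p.tau, src.loadings[i, :J]) for i, p in enumerate(params)
        ]
        params = [register(i, p, basis, table) for i, p in enumerate(params)]
        src, basis = extract_basis(table)
        params = [
            SubjectParams(p.xi, p.tau, src.loadings[i, :J]) for i, p in enumerate(params)
        ]
    else:
        src = SourceModel(np.zeros((0, N, 3)), np.zeros((len(subjects), 0)), np.zeros(0))
        J, basis = 0, empty_basis

    # (5) block-coordinate MAP refinement
    trace = [total_objective(basis, table)]
    converged = False
    for _ in range(cfg.iters):
        params = [register(i, p, basis, table) for i, p in enumerate(params)]
        obj = total_objective(basis, table)
        table, obj = refine_population(basis, table, obj)
        center()
        table = make_table()
        trace.append(total_objective(basis, table))
        if abs(trace[-2] - trace[-1]) < cfg.tol * max(1.0, abs(trace[-1])):
            converged = True
            break

    # ---------------------------------------------------------- SAEM option
    if cfg.mode == "saem":
        sig_xi_s, sig_tau_s = cfg.sigma_xi, cfg.sigma_tau
        for sweep in range(cfg.saem_sweeps):
            gamma = 1.0 / (1.0 + sweep)
            for i, p in enumerate(params):
                pvec = np.concatenate([[p.xi, p.tau], p.sources])
                args = (ages_arr[i], Ys_arr[i], table, basis, t0, sig_eps, sig_xi_s, sig_tau_s)
                f_cur = _subject_nlp(pvec, *args)
                prop = pvec + cfg.saem_proposal * rng.standard_normal(pvec.shape)
                if np.log(rng.uniform()) < f_cur - _subject_nlp(prop, *args):
                    params[i] = SubjectParams(prop[0], prop[1], prop[2:])
            xi2 = float(np.mean([p.xi**2 for p in params]))
            tau2 = float(np.mean([p.tau**2 for p in params]))
            sig_xi_s = float(np.sqrt((1 - gamma) * sig_xi_s**2 + gamma * max(xi2, 1e-8)))
            sig_tau_s = float(np.sqrt((1 - gamma) * sig_tau_s**2 + gamma * max(tau2, 1e-6)))
        center()
        table = make_table()
        trace.append(total_objective(basis, table))

    r, _ = residuals(basis, table)
    rms = float(np.sqrt((r**2).mean()))

    atlas = LongitudinalAtlas(
        template=topo.with_points(X0),
        t0=t0,
        momenta=KernelDeformation(cp, m0, sigma),
        source_modes=src.modes,
        source_scales=src.scales,
        sigma_eps=sig_eps,
        sigma_xi=cfg.sigma_xi,
        sigma_tau=cfg.sigma_tau,
        subject_ids=[s.subject_id for s in subjects],
        subject_params=params,
        n_steps=cfg.n_steps,
    )
    report = FitReport(
        log_posterior=-trace[-1],
        residual_rms=rms,
        trace=[-v for v in trace],
        converged=converged,
        n_control_points=K,
        mode=cfg.mode,
    )
    return atlas, report
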