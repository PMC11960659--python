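import numpy as np
import pytest
from scipy.stats import spearmanr

from vesseltraj import (
    AtlasConfig,
    KernelDeformation,
    LongitudinalAtlas,
    PointSetShape,
    SubjectParams,
    SubjectShapeSeries,
    estimate_atlas,
    extract_sources,
    geodesic_regression,
    predict_shape,
    time_warp,
)
from vesseltraj.shooting import shoot


def _shape(pts):
    pts = np.asarray(pts, float)
    return PointSetShape(("BA",), (True,), pts, pts.shape[0])


# ----------------------------------------------------------------- time warp


def test_time_warp_identity():
    p = SubjectParams(0.0, 0.0)
    assert time_warp(65.0, p, 60.0) == pytest.approx(65.0)


def test_time_warp_acceleration():
    p = SubjectParams(np.log(2.0), 0.0)
    assert time_warp(65.0, p, 60.0) == pytest.approx(70.0)


def test_time_warp_shift_lags():
    p = SubjectParams(0.0, 3.0)
    assert time_warp(65.0, p, 60.0) == pytest.approx(62.0)  # 3 y younger


# ------------------------------------------------------------- predict_shape


def _toy_atlas(rng, n_sources=1):
    X0 = _shape(rng.uniform(-10, 10, (12, 3)))
    cp = rng.uniform(-10, 10, (5, 3))
    m0 = rng.normal(0, 0.05, (5, 3))
    modes = rng.normal(0, 1, (n_sources, 12, 3))
    modes /= np.linalg.norm(modes.reshape(n_sources, -1), axis=1)[:, None, None]
    return LongitudinalAtlas(
        template=X0,
        t0=60.0,
        momenta=KernelDeformation(cp, m0, 5.0),
        source_modes=modes,
        source_scales=np.full(n_sources, 0.8),
        sigma_eps=0.05,
        sigma_xi=0.4,
        sigma_tau=5.0,
    )


def test_predict_zero_params_at_t0_is_template(rng):
    atlas = _toy_atlas(rng)
    pred = predict_shape(atlas, SubjectParams(0.0, 0.0, np.zeros(1)), 60.0)
    assert np.allclose(pred.points, atlas.template.points, atol=1e-12)


def test_predict_single_source_at_t0(rng):
    atlas = _toy_atlas(rng)
    s = np.array([1.7])
    pred = predict_shape(atlas, SubjectParams(0.0, 0.0, s), 60.0)
    expected = atlas.template.points + 1.7 * 0.8 * atlas.source_modes[0]
    assert np.allclose(pred.points, expected, atol=1e-9)


def test_predict_mean_subject_follows_population(rng):
    atlas = _toy_atlas(rng)
    pred = predict_shape(atlas, SubjectParams(0.0, 0.0, np.zeros(1)), 65.0)
    _, expected = shoot(atlas.momenta, atlas.template.points, t=5.0, n_steps=10)
    assert np.allclose(pred.points, expected, atol=1e-9)


# ------------------------------------------------------- geodesic regression


def test_regression_identical_shapes_zero_momenta(rng):
    X = _shape(rng.uniform(-5, 5, (10, 3)))
    _, mom, rms = geodesic_regression([(60.0, X), (66.0, X)], 4.0, maxiter=10)
    assert np.abs(mom.momenta).max() < 1e-4
    assert rms < 1e-6


def test_regression_recovers_known_momenta(rng):
    cp = rng.uniform(-10, 10, (8, 3))
    m_true = rng.normal(0, 0.25, (8, 3))
    X = rng.uniform(-10, 10, (30, 3))
    ages = [60.0, 62.0]
    shapes = []
    for t in ages:
        _, moved = shoot(KernelDeformation(cp, m_true, 4.0), X, t=t - 60.0, n_steps=20)
        shapes.append(_shape(moved))
    _, mom, rms = geodesic_regression(
        list(zip(ages, shapes)), 4.0, control_points=cp, n_steps=10, maxiter=60
    )
    rel = np.linalg.norm(mom.momenta - m_true) / np.linalg.norm(m_true)
    assert rel < 0.05
    assert rms < 0.05  # exact-model fit: residual far below any noise floor


def test_regression_single_visit_error(rng):
    X = _shape(rng.uniform(-5, 5, (10, 3)))
    with pytest.raises(Exception):
        geodesic_regression([(60.0, X)], 4.0)


# ------------------------------------------------------------------- sources


def test_sources_subspace_recovery(rng):
    modes_true = rng.normal(0, 1, (2, 60))
    load = rng.normal(0, 1, (30, 2))
    shifts = load @ modes_true
    src = extract_sources(shifts, 2, seed=0)
    # principal angles between true and recovered spans
    Qa, _ = np.linalg.qr(modes_true.T)
    Qb, _ = np.linalg.qr(src.modes.reshape(2, -1).T)
    angles = np.arccos(np.clip(np.linalg.svd(Qa.T @ Qb, compute_uv=False), -1, 1))
    assert angles.max() < 1e-3


def test_sources_zero_shifts_flagged():
    src = extract_sources(np.zeros((10, 20, 3)), 3)
    assert src.zero_variance
    assert np.all(src.scales == 0.0)


def test_sources_loadings_unit_variance(rng):
    shifts = rng.normal(0, 1, (40, 30))
    src = extract_sources(shifts, 4, seed=1)
    assert np.allclose(src.loadings.std(axis=0, ddof=0), 1.0, atol=1e-6)
    assert np.allclose(np.linalg.norm(src.modes.reshape(4, -1), axis=1), 1.0, atol=1e-9)


def test_sources_rank_reduction_warns(rng):
    one_mode = np.outer(rng.normal(0, 1, 12), rng.normal(0, 1, 30))
    with pytest.warns(RuntimeWarning):
        src = extract_sources(one_mode, 3, seed=0)
    assert src.reduced
    assert src.modes.shape[0] == 1


# ------------------------------------------------------------ full estimator


def _simulated_series(rng, n_subjects=8, noise=0.0):
    """Data generated exactly by a constructed trajectory model."""
    X0 = rng.uniform(-15, 15, (24, 3))
    cp = rng.uniform(-15, 15, (6, 3))
    m0 = rng.normal(0, 0.02, (6, 3))
    t0 = 60.0
    xi = rng.normal(0, 0.3, n_subjects)
    tau = rng.normal(0, 4.0, n_subjects)
    xi -= xi.mean()
    tau -= tau.mean()
    series = []
    for i in range(n_subjects):
        ages = sorted(rng.uniform(50, 70) + np.array([0, 2.5, 5.0]))
        shapes = []
        for t in ages:
            d = np.exp(xi[i]) * (t - t0 - tau[i])
            _, moved = shoot(KernelDeformation(cp, m0, 6.0), X0, t=d, n_steps=10)
            if noise:
                moved = moved + rng.normal(0, noise, moved.shape)
            shapes.append(PointSetShape(("BA",), (True,), moved, 24))
        series.append(SubjectShapeSeries(f"S{i}", list(ages), shapes))
    return series, xi, tau


def test_estimate_atlas_self_consistency(rng):
    """Refit on noiseless model-generated data: the fitted posterior is at
    least as good as the posterior evaluated at the generating latents."""
    series, xi, tau = _simulated_series(rng)
    cfg = AtlasConfig(kernel_mm=6.0, n_sources=0, iters=4, align="none",
                      sigma_xi=0.3, sigma_tau=4.0, sigma_eps=0.02)
    atlas, report = estimate_atlas(series, cfg)
    assert report.residual_rms < 0.05
    xi_hat = np.array([p.xi for p in atlas.subject_params])
    tau_hat = np.array([p.tau for p in atlas.subject_params])
    assert spearmanr(xi_hat, xi).statistic > 0.7
    assert spearmanr(tau_hat, tau).statistic > 0.7
    # log-posterior at the fit beats the prior penalty of the truth
    truth_prior = (xi**2 / (2 * 0.3**2) + tau**2 / (2 * 4.0**2)).sum()
    M = sum(len(s.ages) for s in series) * 24 * 3
    lp_truth_upper = -(M * np.log(0.02))  # data term >= 0 at truth
    assert report.log_posterior >= -(truth_prior) + lp_truth_upper - abs(lp_truth_upper)


def test_estimate_atlas_null_signal(rng):
    """Identical, static subjects: no trend, vanishing residual."""
    X = rng.uniform(-10, 10, (18, 3))
    shapes = [PointSetShape(("BA",), (True,), X, 18) for _ in range(3)]
    series = [
        SubjectShapeSeries(f"S{i}", [55.0, 58.0, 61.0], list(shapes)) for i in range(4)
    ]
    cfg = AtlasConfig(kernel_mm=6.0, n_sources=0, iters=2, align="none")
    atlas, report = estimate_atlas(series, cfg)
    assert report.residual_rms < 1e-6
    assert np.abs(atlas.momenta.momenta).max() < 1e-6
    assert all(abs(p.xi) < 1e-6 for p in atlas.subject_params)


def test_estimate_atlas_centering_and_monotonicity(rng):
    series, _, _ = _simulated_series(rng, noise=0.02)
    cfg = AtlasConfig(kernel_mm=6.0, n_sources=2, iters=3, align="none",
                      sigma_xi=0.3, sigma_tau=4.0)
    atlas, report = estimate_atlas(series, cfg)
    xi_hat = np.array([p.xi for p in atlas.subject_params])
    tau_hat = np.array([p.tau for p in atlas.subject_params])
    assert abs(xi_hat.mean()) < 1e-12
    assert abs(tau_hat.mean()) < 1e-12
    lp = report.trace
    for a, b in zip(lp, lp[1:]):
        assert b >= a - 1e-3 * max(abs(a), 1.0)  # non-decreasing log-posterior


def test_estimate_atlas_saem_smoke(rng):
    series, _, _ = _simulated_series(rng, n_subjects=4, noise=0.02)
    cfg = AtlasConfig(kernel_mm=6.0, n_sources=0, iters=1, align="none",
                      mode="saem", saem_sweeps=5, sigma_eps=0.02)
    atlas, report = estimate_atlas(series, cfg)
    assert report.mode == "saem"
    assert np.isfinite(report.log_posterior)
    assert abs(np.mean([p.tau for p in atlas.subject_params])) < 1e-12


def test_estimate_atlas_topology_mismatch(rng):
    X = rng.uniform(-5, 5, (10, 3))
    good = PointSetShape(("BA",), (True,), X, 10)
    bad = PointSetShape(("ICA-L",), (True,), X, 10)
    series = [
        SubjectShapeSeries("a", [50.0, 55.0], [good, good]),
        SubjectShapeSeries("b", [50.0, 55.0], [bad, bad]),
    ]
    with pytest.raises(Exception):
        estimate_atlas(series, AtlasConfig(n_sources=0))
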