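import dataclasses

import numpy as np
import pytest

from vesseltraj import (
    ArteryTrend,
    CohortConfig,
    CovariateSpec,
    GENERATOR_LABELS,
    VesselGeometryError,
    analytic_morphometrics,
    attach_covariates,
    centerline_length,
    generate_artery_curve,
    generate_cohort,
    mean_radius,
    sample_subject_schedule,
    tortuosity_index,
)
from vesseltraj.synthetic import CohortConfigError


ZERO_TRENDS = {k: ArteryTrend() for k in ("ICA", "MCA", "ACA", "BA", "PCA")}


def quiet_config(**kw):
    base = dict(
        n_subjects=4, sigma_xi=0.0, sigma_tau=0.0, sigma_source=0.0, sigma_noise=0.0,
        n_sources=2, seed=0,
    )
    base.update(kw)
    return CohortConfig(**base)


def test_config_validation():
    with pytest.raises(CohortConfigError):
        CohortConfig(n_subjects=1)
    with pytest.raises(CohortConfigError):
        CohortConfig(sigma_tau=-1)
    with pytest.raises(CohortConfigError):
        CovariateSpec("x", 1.5)


def test_schedule_degenerate_two_visits():
    cfg = CohortConfig(visits_mean=2, visits_sd=0, followup_mean=6, followup_sd=0)
    rng = np.random.default_rng(0)
    ages = sample_subject_schedule(cfg, rng)
    assert len(ages) == 2
    assert ages[1] - ages[0] == pytest.approx(6.0)


def test_schedule_population_means():
    cfg = CohortConfig()
    rng = np.random.default_rng(7)
    firsts, counts = [], []
    for _ in range(10_000):
        ages = sample_subject_schedule(cfg, rng)
        firsts.append(ages[0])
        counts.append(len(ages))
        assert len(ages) >= 2 and np.all(np.diff(ages) > 0)
        assert ages[0] >= 18.0
    assert abs(np.mean(firsts) - 57.32) < 0.5
    assert abs(np.mean(counts) - 3.6) < 0.1


def test_zero_trend_curves_identical():
    cfg = quiet_config(trends=ZERO_TRENDS)
    a = generate_artery_curve("ICA-L", None, 50.0, cfg)
    b = generate_artery_curve("ICA-L", None, 70.0, cfg)
    assert np.array_equal(a.points, b.points)
    assert np.array_equal(a.radii, b.radii)


def test_reference_age_tortuosity_ranges():
    cfg = quiet_config(points_per_curve=1000)
    t_ica = tortuosity_index(generate_artery_curve("ICA-R", None, cfg.reference_age, cfg))
    t_mca = tortuosity_index(generate_artery_curve("MCA-R", None, cfg.reference_age, cfg))
    assert 0.5 <= t_ica <= 1.5  # carotid siphon: O(1) tortuosity index
    assert 0.0 <= t_mca <= 0.2  # near-straight M1


def test_analytic_length_trend_ratio():
    trends = dict(ZERO_TRENDS)
    trends["ICA"] = ArteryTrend(length_pct=1.0)
    cfg = quiet_config(trends=trends)
    t0 = cfg.reference_age
    L0 = analytic_morphometrics("ICA-L", t0, cfg)[0]
    L1 = analytic_morphometrics("ICA-L", t0 + 10.0, cfg)[0]
    assert L1 / L0 == pytest.approx(1.01, abs=1e-6)


def test_measured_morphometrics_follow_analytic_trend():
    """Trend consistency: noiseless generated curves match the closed form."""
    cfg = quiet_config(points_per_curve=2000)
    for lab in ("ICA-L", "ACA-R", "BA"):
        for age in (cfg.reference_age, cfg.reference_age + 8.0):
            L, T, r = analytic_morphometrics(lab, age, cfg)
            c = generate_artery_curve(lab, None, age, cfg)
            assert centerline_length(c) == pytest.approx(L, rel=1e-3)
            assert tortuosity_index(c) == pytest.approx(T, abs=1e-3)
            assert mean_radius(c) == pytest.approx(r, rel=1e-3)


def test_unknown_label_error():
    with pytest.raises(VesselGeometryError):
        generate_artery_curve("AComA", None, 50.0, quiet_config())
    with pytest.raises(VesselGeometryError):
        generate_artery_curve("XYZ", None, 50.0, quiet_config())


def test_cohort_determinism():
    cfg = CohortConfig(n_subjects=3, seed=11)
    c1, t1 = generate_cohort(cfg)
    c2, t2 = generate_cohort(cfg)
    assert np.array_equal(t1.xi, t2.xi) and np.array_equal(t1.sources, t2.sources)
    for s1, s2 in zip(c1.subjects, c2.subjects):
        assert s1.covariates == s2.covariates
        for a, b in zip(s1.scans, s2.scans):
            assert a.age == b.age
            for ca, cb in zip(a.curves, b.curves):
                assert np.array_equal(ca.points, cb.points)


def test_zero_variance_collapse():
    cfg = quiet_config(visits_mean=2, visits_sd=0, followup_mean=6, followup_sd=0)
    cohort, truth = generate_cohort(cfg)
    assert np.all(truth.alpha == 1.0) and np.all(truth.tau == 0.0)
    ref = {
        lab: generate_artery_curve(lab, None, cohort.subjects[0].scans[0].age, cfg)
        for lab in GENERATOR_LABELS
    }
    for c in cohort.subjects[0].scans[0].curves:
        assert np.array_equal(c.points, ref[c.label].points)


def test_latent_spread_matches_configured_sd():
    cfg = CohortConfig(n_subjects=200, sigma_xi=0.5, sigma_noise=0.0, seed=5,
                       visits_mean=2, visits_sd=0)
    _, truth = generate_cohort(cfg)
    assert abs(truth.xi.std(ddof=1) - 0.5) < 0.1


def test_warp_correctness():
    """A subject with alpha=2, tau=0 observed 5 y after t0 carries the
    population geometry of t0 + 10 y, exactly."""
    cfg = quiet_config(trends=None or dict(ZERO_TRENDS, ICA=ArteryTrend(2.0, 0.05, 0.02)))
    t0 = cfg.reference_age
    pop = generate_artery_curve("ICA-L", None, t0 + 10.0, cfg)
    warped_age = np.exp(np.log(2.0)) * ((t0 + 5.0) - t0 - 0.0) + t0
    subj = generate_artery_curve("ICA-L", None, warped_age, cfg)
    assert np.allclose(subj.points, pop.points, atol=1e-9)


def test_covariate_prevalence_extremes():
    rng = np.random.default_rng(0)
    cfg = dataclasses.replace(
        quiet_config(), covariates=(CovariateSpec("always", 1.0), CovariateSpec("never", 0.0))
    )
    flags = attach_covariates([f"S{i}" for i in range(50)], cfg, rng)
    assert all(f["always"] for f in flags)
    assert not any(f["never"] for f in flags)


def test_covariate_prevalence_mean():
    """Diabetes-style prevalence 18/110: mean flag count within 1 of 18."""
    cfg = dataclasses.replace(
        quiet_config(n_subjects=110), covariates=(CovariateSpec("dm", 18 / 110),)
    )
    rng = np.random.default_rng(21)
    counts = [
        sum(f["dm"] for f in attach_covariates([f"S{i}" for i in range(110)], cfg, rng))
        for _ in range(200)
    ]
    assert abs(np.mean(counts) - 18.0) < 1.0


def test_covariate_effect_enters_latents():
    covs = (CovariateSpec("dm", 0.5, effect_xi=1.0, effect_tau=-2.0),)
    cfg = CohortConfig(n_subjects=300, sigma_xi=0.01, sigma_tau=0.01, sigma_noise=0.0,
                       covariates=covs, seed=9, visits_mean=2, visits_sd=0)
    cohort, truth = generate_cohort(cfg)
    flags = np.array([s.covariates["dm"] for s in cohort.subjects])
    assert truth.xi[flags].mean() - truth.xi[~flags].mean() == pytest.approx(1.0, abs=0.05)
    assert truth.tau[flags].mean() - truth.tau[~flags].mean() == pytest.approx(-2.0, abs=0.05)
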