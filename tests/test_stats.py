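import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import rankdata

from vesseltraj import (
    compare_factor,
    holm_bonferroni,
    kruskal_wallis,
    wilcoxon_signed_rank,
)
from vesseltraj.stats import StatsError


def brute_force_wilcoxon(d):
    """Independent oracle: full enumeration over sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    M = ranks.sum()
    ws = []
    for mask in range(2**n):
        ws.append(sum(r for i, r in enumerate(ranks) if (mask >> i) & 1))
    ws = np.array(ws)
    return w, np.mean(np.abs(ws - M / 2) >= abs(w - M / 2) - 1e-12)


def test_wilcoxon_five_positive_exact():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
    assert res.exact
    assert res.pvalue == pytest.approx(0.0625)  # 2 / 2^5


def test_wilcoxon_matches_enumeration_oracle(rng):
    for _ in range(50):
        d = rng.normal(0, 1, 8)
        if rng.uniform() < 0.3:  # force ties in magnitude sometimes
            d[:3] = np.sign(d[:3]) * abs(d[3])
        w, p = brute_force_wilcoxon(d)
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.statistic == pytest.approx(w)
        assert res.pvalue == pytest.approx(p, abs=1e-12)


def test_wilcoxon_matches_scipy_exact_tie_free(rng):
    for _ in range(20):
        d = rng.normal(0, 1, 10)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_antisymmetric_null_center():
    x = np.array([1.0, 2.0, 3.0, 4.0, -1.0, -2.0, -3.0, -4.0])
    res = wilcoxon_signed_rank(x)
    assert res.pvalue >= 0.99


def test_wilcoxon_all_zero():
    res = wilcoxon_signed_rank(np.zeros(6))
    assert res.all_zero and res.pvalue == 1.0


def test_wilcoxon_normal_approximation_reasonable(rng):
    d = rng.normal(0.5, 1.0, 60)
    ours = wilcoxon_signed_rank(d)
    ref = sps.wilcoxon(d, alternative="two-sided", correction=True, method="approx")
    assert not ours.exact
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.05)


def test_kruskal_hand_computed():
    H, p = kruskal_wallis([[1, 2], [3, 4]])
    assert H == pytest.approx(2.4)
    assert p == pytest.approx(sps.chi2.sf(2.4, 1))


def test_kruskal_all_equal():
    H, p = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert H == 0.0 and p == 1.0


def test_kruskal_errors():
    with pytest.raises(StatsError):
        kruskal_wallis([[1, 2]])
    with pytest.raises(StatsError):
        kruskal_wallis([[1, 2], []])


def test_kruskal_two_groups_agrees_with_mannwhitney(rng):
    """On tie-free data the 2-group decision matches Mann-Whitney at alpha=.05."""
    agree = 0
    n_trials = 300
    for _ in range(n_trials):
        a = rng.normal(0, 1, 12)
        b = rng.normal(rng.uniform(-1, 1), 1, 15)
        _, p_kw = kruskal_wallis([a, b])
        p_mw = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        agree += (p_kw < 0.05) == (p_mw < 0.05)
    assert agree / n_trials >= 0.99


def test_holm_step_down():
    adj = holm_bonferroni([0.01, 0.04])
    assert np.allclose(adj, [0.02, 0.04])


def test_holm_single_unchanged():
    assert holm_bonferroni([0.3])[0] == pytest.approx(0.3)


def test_holm_matches_manual_step_down(rng):
    p = rng.uniform(0, 1, 7)
    adj = holm_bonferroni(p)
    # manual step-down with monotonicity enforcement
    order = np.argsort(p)
    m = len(p)
    manual = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        manual[idx] = min(running, 1.0)
    assert np.allclose(adj, manual)
    assert np.all(adj >= p - 1e-15)


def test_compare_factor_two_levels():
    rng = np.random.default_rng(3)
    vals = rng.normal(0, 1, 40)
    labels = np.array([0] * 20 + [1] * 20)
    comp = compare_factor(vals, labels, "flag")
    assert comp.group_sizes == {"0": 20, "1": 20}
    assert comp.posthoc == {}  # two-level factors get no post hoc


def test_compare_factor_posthoc_on_significant_multilevel():
    rng = np.random.default_rng(4)
    vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
    labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
    comp = compare_factor(vals, labels, "race")
    assert comp.pvalue < 0.05
    assert set(comp.posthoc) == {"a|b", "a|c", "b|c"}
    assert comp.posthoc["a|c"] < 0.05 and comp.posthoc["b|c"] < 0.05


def test_compare_factor_single_level_error():
    with pytest.raises(StatsError):
        compare_factor([1.0, 2.0], ["x", "x"], "f")


def test_rank_invariance_under_monotone_transform(rng):
    vals = rng.normal(0, 1, 50)
    labels = rng.integers(0, 2, 50)
    c1 = compare_factor(vals, labels, "f")
    c2 = compare_factor(np.exp(vals), labels, "f")
    assert c1.pvalue == pytest.approx(c2.pvalue, abs=1e-12)


# ----------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_holm_properties(pvals):
    adj = holm_bonferroni(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-15)  # never decreases
    assert np.all(adj <= 1.0)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_wilcoxon_p_is_valid_probability(seed):
    d = np.random.default_rng(seed).normal(0, 1, 9)
    res = wilcoxon_signed_rank(d)
    assert 0.0 <= res.pvalue <= 1.0
    # symmetry: negating all differences leaves the two-sided p unchanged
    assert wilcoxon_signed_rank(-d).pvalue == pytest.approx(res.pvalue, abs=1e-12)
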