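"""Nonparametric group statistics for trajectory parameters and morphometry.

Group comparisons follow the study design: Kruskal-Wallis between patient
groups, Wilcoxon signed-rank for paired first-vs-last measurements,
Holm-Bonferroni for post hoc families, alpha = 0.05 throughout.

The Wilcoxon signed-rank test is implemented here with exact two-sided
p-values by full enumeration of sign assignments for n <= 12 pairs (after the
zero-discard rule) and a tie/continuity-corrected normal approximation above;
mid-ranks are used for tied magnitudes.  Kruskal-Wallis and Holm-Bonferroni
delegate to scipy / statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 12


class StatsError(ValueError):
    pass


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ : sum of ranks of positive differences
    pvalue: float
    exact: bool
    all_zero: bool


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are discarded; tied magnitudes get mid-ranks.  For
    n <= 12 remaining pairs the two-sided p-value is exact:
    ``P(|W - M/2| >= |w - M/2|)`` over all 2^n equiprobable sign assignments
    (the null distribution is symmetric about M/2, M the total rank sum).
    Larger n uses the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise StatsError("need a 1-D nonempty sample of paired differences")
    d = d[d != 0.0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, True, True)
    n = d.size
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    M = float(ranks.sum())

    if n <= EXACT_WILCOXON_MAX_N:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
        w_all = np.where(signs, ranks, 0.0).sum(axis=1)
        p = float(np.mean(np.abs(w_all - M / 2) >= np.abs(w - M / 2) - 1e-12))
        return WilcoxonResult(w, min(p, 1.0), True, False)

    mu = M / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(w, 1.0, False, False)
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w, min(float(p), 1.0), False, False)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-rank tie correction) and chi-square p, k-1 df."""
    if len(groups) < 2:
        raise StatsError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise StatsError("kruskal_wallis: empty group")
    if sum(a.size for a in arrays) < 3:
        raise StatsError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all observations tied: no evidence against the null
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _median_iqr(a: np.ndarray) -> tuple[float, float]:
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return float(med), float(q3 - q1)


@dataclass
class GroupComparison:
    """One factor's Kruskal-Wallis comparison of a per-subject quantity."""

    factor: str
    levels: list[str]
    group_sizes: dict[str, int]
    statistic: float
    pvalue: float
    medians: dict[str, float]
    iqrs: dict[str, float]
    posthoc: dict[str, float] = field(default_factory=dict)  # "A|B" -> adjusted p

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "levels": list(self.levels),
            "group_sizes": dict(self.group_sizes),
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "medians": dict(self.medians),
            "iqrs": dict(self.iqrs),
            "posthoc": dict(self.posthoc),
        }


def compare_factor(
    values: Sequence[float],
    labels: Sequence,
    factor: str = "",
) -> GroupComparison:
    """Kruskal-Wallis comparison of a per-subject quantity across factor levels.

    For factors with more than two levels that reach significance, pairwise
    post hoc Kruskal-Wallis tests with Holm-Bonferroni adjustment are added.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise StatsError("values and labels must align")
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    levels = sorted(np.unique(labels).tolist(), key=str)
    if len(levels) < 2:
        raise StatsError(f"factor {factor!r} has a single level")
    samples = {str(l): values[labels == l] for l in levels}
    H, p = kruskal_wallis(list(samples.values()))
    med_iqr = {k: _median_iqr(v) for k, v in samples.items()}
    comp = GroupComparison(
        factor=factor,
        levels=[str(l) for l in levels],
        group_sizes={k: int(v.size) for k, v in samples.items()},
        statistic=H,
        pvalue=p,
        medians={k: mi[0] for k, mi in med_iqr.items()},
        iqrs={k: mi[1] for k, mi in med_iqr.items()},
    )
    if len(levels) > 2 and p < ALPHA:
        pairs = list(combinations(sorted(samples), 2))
        raw = [kruskal_wallis([samples[a], samples[b]])[1] for a, b in pairs]
        adj = holm_bonferroni(raw)
        comp.posthoc = {f"{a}|{b}": float(q) for (a, b), q in zip(pairs, adj)}
    return comp
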