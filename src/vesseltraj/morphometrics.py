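"""Per-artery centerline morphometrics and the first-vs-last comparison table.

Three measures per artery and scan:

* length ``L``: polyline arc length (mm);
* tortuosity index ``T = L/C - 1`` with ``C`` the straight-line chord between
  the endpoints (0 for a straight vessel; the Table-style summaries of this
  field print e.g. 0.08 for a near-straight M1 and ~0.9 for a carotid siphon,
  which a raw L/C ratio >= 1 could not produce);
* mean radius: arc-length-weighted (trapezoidal) average of the per-point
  maximal-inscribed-sphere radius (mm).

Also provides segmentation-reliability metrics (Dice, average symmetric
Hausdorff distance) and a cheap per-subject morphometric progression-rate
estimator used for fast covariate screening.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .curves import CenterlineCurve, VesselScan, VesselGeometryError
from .stats import wilcoxon_signed_rank

MIN_PAIRS_FOR_TEST = 5

#: Morphometric measures computed per artery.
MEASURES = ("length", "tortuosity", "mean_radius")


def centerline_length(curve: CenterlineCurve) -> float:
    """Arc length of the centerline polyline (mm)."""
    return float(np.linalg.norm(np.diff(curve.points, axis=0), axis=1).sum())


def tortuosity_index(curve: CenterlineCurve) -> float:
    """Arc-chord tortuosity index L/C - 1 (dimensionless, 0 iff straight)."""
    chord = float(np.linalg.norm(curve.points[-1] - curve.points[0]))
    if chord < 1e-9 * max(centerline_length(curve), 1e-9):
        raise VesselGeometryError(
            f"curve {curve.label!r}: coincident endpoints, tortuosity undefined"
        )
    return centerline_length(curve) / chord - 1.0


def mean_radius(curve: CenterlineCurve) -> float:
    """Arc-length-weighted (trapezoidal) mean of the radius function (mm)."""
    seg = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
    r = curve.radii
    return float(np.sum(seg * (r[:-1] + r[1:]) / 2.0) / seg.sum())


def measure_scan(scan: VesselScan) -> pd.DataFrame:
    """Tidy morphometry records (one row per artery) for one scan."""
    rows = [
        {
            "subject_id": scan.subject_id,
            "scan_id": scan.scan_id,
            "age": scan.age,
            "artery": c.label,
            "length": centerline_length(c),
            "tortuosity": tortuosity_index(c),
            "mean_radius": mean_radius(c),
        }
        for c in scan.curves
    ]
    return pd.DataFrame(rows)


def measure_scans(scans: list[VesselScan]) -> pd.DataFrame:
    if not scans:
        return pd.DataFrame(
            columns=["subject_id", "scan_id", "age", "artery", *MEASURES]
        )
    return pd.concat([measure_scan(s) for s in scans], ignore_index=True)


def first_last_table(records: pd.DataFrame) -> pd.DataFrame:
    """Paired first-vs-last scan comparison per artery and measure.

    For every (artery, measure): the number of subjects contributing a pair,
    initial and final median (IQR), per-subject change and percent-change
    median (IQR), and the Wilcoxon signed-rank p on the paired values.
    Change summaries are medians of per-subject changes, not differences of
    medians.  Subjects missing the artery in either scan are excluded for
    that row; rows with fewer than 5 pairs report p as NaN.
    """
    req = {"subject_id", "age", "artery", *MEASURES}
    missing = req - set(records.columns)
    if missing:
        raise VesselGeometryError(f"records missing columns {sorted(missing)}")
    rows = []
    for artery, g in records.groupby("artery", sort=False):
        firsts, lasts = [], []
        for _, sg in g.groupby("subject_id", sort=True):
            sg = sg.sort_values("age")
            if len(sg) < 2:
                continue
            firsts.append(sg.iloc[0])
            lasts.append(sg.iloc[-1])
        if not firsts:
            continue
        fi = pd.DataFrame(firsts)
        la = pd.DataFrame(lasts)
        n = len(fi)
        for meas in MEASURES:
            a = fi[meas].to_numpy(float)
            b = la[meas].to_numpy(float)
            change = b - a
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = np.where(a != 0, 100.0 * change / a, np.nan)
            if n >= MIN_PAIRS_FOR_TEST:
                p = wilcoxon_signed_rank(b, a).pvalue
            else:
                p = np.nan
            q = lambda v: (float(np.median(v)), float(np.subtract(*np.percentile(v, [75, 25]))))
            (mi, ii), (mf, if_), (mc, ic) = q(a), q(b), q(change)
            mp, ip = q(pct[np.isfinite(pct)]) if np.isfinite(pct).any() else (np.nan, np.nan)
            rows.append(
                {
                    "artery": artery,
                    "measure": meas,
                    "n": n,
                    "initial_median": mi,
                    "initial_iqr": ii,
                    "final_median": mf,
                    "final_iqr": if_,
                    "change_median": mc,
                    "change_iqr": ic,
                    "pct_change_median": mp,
                    "pct_change_iqr": ip,
                    "wilcoxon_p": p,
                }
            )
    return pd.DataFrame(rows)


def progression_rate(records: pd.DataFrame) -> pd.Series:
    """Per-subject morphometric progression rate (mm/year).

    Least-squares slope, against age, of a composite size score (the summed
    arc length of all arteries present in every scan of the subject).  The
    score is monotone in the subject's true progression speed, so rank-based
    group tests on it screen for acceleration effects without fitting the
    trajectory model.  Subjects with fewer than 2 scans get NaN.
    """
    rates = {}
    for sid, g in records.groupby("subject_id", sort=True):
        counts = g.groupby("artery")["age"].nunique()
        ages_n = g["age"].nunique()
        common = counts[counts == ages_n].index
        gg = g[g["artery"].isin(common)]
        tot = gg.groupby("age")["length"].sum()
        if len(tot) < 2:
            rates[sid] = np.nan
            continue
        ages = tot.index.to_numpy(float)
        rates[sid] = float(np.polyfit(ages, tot.to_numpy(float), 1)[0])
    return pd.Series(rates, name="progression_rate")


# --------------------------------------------------- reliability metrics


def average_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric average Hausdorff distance between two point sets (mm)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise VesselGeometryError("average_hausdorff: empty point set")
    dab = cKDTree(B).query(A)[0].mean()
    dba = cKDTree(A).query(B)[0].mean()
    return float((dab + dba) / 2.0)


def dice(maskA: np.ndarray, maskB: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks give 1."""
    A = np.asarray(maskA, dtype=bool)
    B = np.asarray(maskB, dtype=bool)
    if A.shape != B.shape:
        raise VesselGeometryError(f"dice: shape mismatch {A.shape} vs {B.shape}")
    denom = A.sum() + B.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(A, B).sum() / denom)
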