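import numpy as np
import pandas as pd
import pytest

from vesseltraj import (
    CenterlineCurve,
    VesselGeometryError,
    average_hausdorff,
    centerline_length,
    dice,
    first_last_table,
    mean_radius,
    tortuosity_index,
)
from vesseltraj.morphometrics import progression_rate

from conftest import make_helix, make_semicircle, random_rigid


def test_length_polyline():
    c = CenterlineCurve("BA", [[0, 0, 0], [1, 0, 0], [1, 1, 0]], [1, 1, 1])
    assert centerline_length(c) == pytest.approx(2.0)


def test_length_helix_closed_form():
    # unit radius, pitch 2*pi, one turn: L = 2*pi*sqrt(2)
    c = make_helix(n=2000)
    assert centerline_length(c) == pytest.approx(2 * np.pi * np.sqrt(2), abs=1e-3)


def test_tortuosity_straight_is_zero():
    c = CenterlineCurve("BA", [[0, 0, 0], [1, 0, 0], [2.5, 0, 0]], [1, 1, 1])
    assert tortuosity_index(c) == pytest.approx(0.0, abs=1e-12)


def test_tortuosity_semicircle():
    assert tortuosity_index(make_semicircle(1000)) == pytest.approx(np.pi / 2 - 1, abs=1e-3)


def test_tortuosity_helix():
    assert tortuosity_index(make_helix(2000)) == pytest.approx(np.sqrt(2) - 1, abs=1e-3)


def test_tortuosity_coincident_endpoints_error():
    th = np.linspace(0, 2 * np.pi, 100)
    loop = CenterlineCurve(
        "BA", np.column_stack([np.cos(th), np.sin(th), np.zeros(100)]), np.ones(100)
    )
    with pytest.raises(VesselGeometryError):
        tortuosity_index(loop)


@pytest.mark.parametrize(
    "radii_fn,expected",
    [
        (lambda u: np.full_like(u, 1.5), 1.5),
        (lambda u: 1.0 + u, 1.5),  # linear taper on a straight segment
        (lambda u: np.where(u < 0.5, 1.0, 3.0), 2.0),  # step profile
    ],
)
def test_mean_radius(radii_fn, expected):
    n = 10_000
    u = np.linspace(0, 1, n)
    pts = np.column_stack([u, np.zeros(n), np.zeros(n)])
    c = CenterlineCurve("BA", pts, radii_fn(u))
    assert mean_radius(c) == pytest.approx(expected, abs=1e-3)


def test_morphometrics_rigid_and_reversal_invariance(rng):
    c = make_helix(500)
    base = (centerline_length(c), tortuosity_index(c), mean_radius(c))
    for _ in range(20):
        R, t = random_rigid(rng)
        moved = c.transformed(R, t)
        for a, b in zip(base, (centerline_length(moved), tortuosity_index(moved), mean_radius(moved))):
            assert abs(a - b) <= 1e-9 * max(abs(a), 1.0)
    rev = c.reversed()
    for a, b in zip(base, (centerline_length(rev), tortuosity_index(rev), mean_radius(rev))):
        assert abs(a - b) <= 1e-9 * max(abs(a), 1.0)


def test_refinement_stability():
    from vesseltraj import resample_curve

    c = make_helix(4000)
    coarse = resample_curve(c, 500)
    fine = resample_curve(c, 1000)
    for f in (centerline_length, tortuosity_index, mean_radius):
        assert abs(f(fine) - f(coarse)) < 1e-3 * max(abs(f(fine)), 1.0)


# ------------------------------------------------------------- reliability


def test_average_hausdorff_trivial():
    assert average_hausdorff([[0, 0, 0]], [[0, 0, 0]]) == 0.0
    assert average_hausdorff([[0, 0, 0]], [[1, 0, 0]]) == pytest.approx(1.0)


def test_average_hausdorff_matches_brute_force(rng):
    A = rng.uniform(-3, 3, (20, 3))
    B = rng.uniform(-3, 3, (20, 3))
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    brute = (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2
    assert average_hausdorff(A, B) == pytest.approx(brute, abs=1e-12)


def test_average_hausdorff_empty_error():
    with pytest.raises(VesselGeometryError):
        average_hausdorff(np.empty((0, 3)), [[0, 0, 0]])


def test_dice():
    a = np.zeros((4, 4, 4), bool)
    a[:2] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool)) == 1.0
    b = np.zeros_like(a)
    b[1:3] = True  # |A|=|B|=32, overlap 16 -> dice 0.5
    assert dice(a, b) == pytest.approx(0.5)
    with pytest.raises(VesselGeometryError):
        dice(a, np.zeros((3, 3, 3), bool))


# ---------------------------------------------------------- first/last table


def _records(subject_values):
    """Build tidy records: {sid: [(age, length), ...]} on one artery."""
    rows = []
    for sid, visits in subject_values.items():
        for age, L in visits:
            rows.append(
                {
                    "subject_id": sid,
                    "scan_id": f"{age}",
                    "age": age,
                    "artery": "ICA-L",
                    "length": L,
                    "tortuosity": 0.5,
                    "mean_radius": 2.0,
                }
            )
    return pd.DataFrame(rows)


def test_first_last_all_unchanged():
    rec = _records({f"S{i}": [(60, 80.0), (66, 80.0)] for i in range(8)})
    tab = first_last_table(rec).set_index("measure")
    row = tab.loc["length"]
    assert row.change_median == 0.0
    assert row.wilcoxon_p == 1.0  # all-zero differences under the zero rule


def test_first_last_single_subject_no_test():
    rec = _records({"S0": [(60, 80.0), (66, 82.0)]})
    tab = first_last_table(rec).set_index("measure")
    row = tab.loc["length"]
    assert row.n == 1
    assert row.initial_median == 80.0 and row.final_median == 82.0
    assert np.isnan(row.wilcoxon_p)  # fewer than 5 pairs


def test_first_last_detects_growth():
    rng = np.random.default_rng(0)
    rec = _records(
        {f"S{i}": [(60, 80 + rng.normal(0, 0.1)), (66, 81 + rng.normal(0, 0.1))] for i in range(20)}
    )
    tab = first_last_table(rec).set_index("measure")
    row = tab.loc["length"]
    assert row.change_median > 0.5
    assert row.wilcoxon_p < 0.01


def test_progression_rate_monotone_in_slope():
    rec = pd.concat(
        [
            _records({"fast": [(60, 80.0), (63, 83.0), (66, 86.0)]}),
            _records({"slow": [(60, 80.0), (63, 81.0), (66, 82.0)]}),
        ]
    )
    rate = progression_rate(rec)
    assert rate["fast"] == pytest.approx(1.0)
    assert rate["slow"] == pytest.approx(1.0 / 3.0)


# ----------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_tortuosity_nonnegative_zero_iff_straight(seed):
    g = np.random.default_rng(seed)
    pts = np.cumsum(g.uniform(0.05, 1.0, (12, 3)) * np.array([1.0, 0.3, 0.3]), axis=0)
    c = CenterlineCurve("BA", pts, np.ones(12))
    t = tortuosity_index(c)
    assert t >= -1e-12
    straight = CenterlineCurve("BA", np.outer(np.sort(g.uniform(0, 5, 8)), [1, 0, 0]) + 0.0, np.ones(8))
    assert tortuosity_index(straight) == pytest.approx(0.0, abs=1e-12)
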