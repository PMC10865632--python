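"""Evaluation metrics against independent oracles: sample-F1 vs a confusion
recount, segment-F1 vs exhaustive matching, ICC vs a from-scratch ANOVA and
a reference implementation, Bland-Altman vs direct formulas."""

import itertools

import numpy as np
import pytest

from fogkit.datamodel import Segment, labels_to_segments
from fogkit.metrics import (
    bland_altman,
    count_fog_episodes,
    f1_from_counts,
    icc_2_1,
    percent_time_frozen,
    percent_time_frozen_pooled,
    sample_f1,
    segment_f1_at_k,
    segment_iou,
    strength_category,
)


# ---------------------------------------------------------------------------
# oracles


def exhaustive_segment_f1(gt, pred, k):
    """Best F1 over all one-to-one matchings of overlapping segment pairs."""
    n_p, n_g = len(pred), len(gt)
    if n_p == 0 and n_g == 0:
        return 1.0
    pairs = [
        (i, j, segment_iou(p, g))
        for i, p in enumerate(pred)
        for j, g in enumerate(gt)
        if segment_iou(p, g) > 0
    ]
    best = 0.0
    for r in range(min(n_p, n_g, len(pairs)) + 1):
        for combo in itertools.combinations(pairs, r):
            used_p = [c[0] for c in combo]
            used_g = [c[1] for c in combo]
            if len(set(used_p)) < r or len(set(used_g)) < r:
                continue
            tp = sum(1 for c in combo if c[2] > k)
            fp = n_p - tp
            fn = n_g - r
            best = max(best, f1_from_counts(tp, fp, fn, degenerate=1.0))
    return best


def random_segments(rng, max_n=6, length=60):
    cuts = np.sort(rng.choice(length, size=2 * int(rng.integers(0, max_n + 1)), replace=False))
    return [Segment(int(a), int(b)) for a, b in zip(cuts[::2], cuts[1::2]) if b > a]


def anova_icc_oracle(x):
    """Independent mean-squares route: explicit loops over the two-way layout."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i]) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# F1 family


def test_f1_formula_values():
    assert f1_from_counts(1, 1, 0) == pytest.approx(2 / 3)
    assert f1_from_counts(0, 1, 0) == 0.0
    assert f1_from_counts(5, 0, 0) == 1.0


def test_f1_symmetry_range_and_perfection():
    rng = np.random.default_rng(0)
    for _ in range(100):
        tp, fp, fn = (int(v) for v in rng.integers(0, 20, size=3))
        f = f1_from_counts(tp, fp, fn)
        assert 0.0 <= f <= 1.0
        assert f == f1_from_counts(tp, fn, fp)  # symmetric in FP <-> FN
        assert (f == 1.0 and tp > 0) == (fp == 0 and fn == 0 and tp > 0)


def test_degenerate_f1_policy():
    assert f1_from_counts(0, 0, 0) == 1.0
    assert np.isnan(f1_from_counts(0, 0, 0, degenerate=np.nan))


def test_sample_f1_matches_sklearn():
    from sklearn.metrics import f1_score

    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(2, 200))
        gt = rng.integers(0, 2, size=n)
        pred = rng.integers(0, 2, size=n)
        if gt.sum() == 0 and pred.sum() == 0:
            continue
        assert sample_f1(gt, pred) == pytest.approx(
            f1_score(gt, pred, zero_division=0), abs=1e-12
        )


def test_sample_f1_extremes_and_length_mismatch():
    gt = np.array([0, 1, 1, 0])
    assert sample_f1(gt, gt) == 1.0
    assert sample_f1(gt, np.zeros(4, dtype=int)) == 0.0
    with pytest.raises(ValueError, match="length"):
        sample_f1(gt, np.zeros(5, dtype=int))


def test_segment_iou_values():
    assert segment_iou(Segment(3, 9), Segment(3, 9)) == 1.0
    assert segment_iou(Segment(0, 5), Segment(7, 9)) == 0.0
    assert segment_iou(Segment(0, 10), Segment(5, 15)) == pytest.approx(5 / 15)


class TestSegmentF1:
    def test_one_hit_one_miss_no_unmatched_truth(self):
        # two episodes; one prediction above the IoU threshold, one below,
        # and every ground-truth episode claimed: TP=1, FP=1, FN=0 -> 0.67
        gt = [Segment(0, 10), Segment(20, 30)]
        pred = [Segment(6, 14), Segment(21, 30)]
        assert segment_iou(pred[0], gt[0]) < 0.5 < segment_iou(pred[1], gt[1])
        assert segment_f1_at_k(gt, pred, 0.5) == pytest.approx(2 / 3)

    def test_single_low_overlap_prediction_scores_zero(self):
        # a shifted prediction claims its episode (FN=0) but is FP: F1 = 0
        gt = [Segment(0, 10)]
        pred = [Segment(5, 13)]
        assert segment_f1_at_k(gt, pred, 0.5) == 0.0

    def test_empty_sides(self):
        assert segment_f1_at_k([], [Segment(0, 5)], 0.5) == 0.0
        assert segment_f1_at_k([Segment(0, 5)], [], 0.5) == 0.0
        assert segment_f1_at_k([], [], 0.5) == 1.0

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            segment_f1_at_k([Segment(0, 5), Segment(3, 8)], [Segment(0, 5)])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            gt = random_segments(rng)
            pred = random_segments(rng)
            assert segment_f1_at_k(gt, pred, 0.5) == pytest.approx(
                exhaustive_segment_f1(gt, pred, 0.5)
            )

    def test_monotone_nonincreasing_in_k(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            gt = random_segments(rng)
            pred = random_segments(rng)
            scores = [segment_f1_at_k(gt, pred, k) for k in (0.1, 0.25, 0.5, 0.75, 0.9)]
            assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# clinical outcomes


def test_percent_tf_pooled_is_duration_weighted_mean():
    rng = np.random.default_rng(3)
    trials = [rng.integers(0, 2, size=int(rng.integers(10, 300))) for _ in range(8)]
    pooled = percent_time_frozen_pooled(trials)
    weights = np.array([t.size for t in trials], dtype=float)
    per_trial = np.array([percent_time_frozen(t) for t in trials])
    assert pooled == pytest.approx(np.average(per_trial, weights=weights))


def test_count_fog_episodes():
    assert count_fog_episodes(np.array([0, 1, 1, 0, 1, 0])) == 2
    assert count_fog_episodes(np.ones(50, dtype=int)) == 1
    rng = np.random.default_rng(4)
    for _ in range(50):
        labels = rng.integers(0, 2, size=int(rng.integers(1, 80)))
        assert count_fog_episodes(labels) == len(labels_to_segments(labels, 1))


# ---------------------------------------------------------------------------
# agreement statistics


class TestICC:
    def test_identical_raters_give_unity(self):
        icc, lo, hi = icc_2_1(np.array([[40.0, 40.0], [10.0, 10.0]]))
        assert icc == 1.0

    def test_uncorrelated_raters_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=200)
        b = a + rng.normal(scale=25.0, size=200)
        icc, _, _ = icc_2_1(np.column_stack([a, b]))
        assert abs(icc) < 0.2

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(loc=10, scale=5, size=(12, 2))
            icc, _, _ = icc_2_1(x)
            assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(loc=20, scale=8, size=(12, 2))
            icc, lo, hi = icc_2_1(x)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(12), 2),
                    "raters": np.tile([0, 1], 12),
                    "scores": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(df, "targets", "raters", "scores").set_index("Type")
            row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
            assert icc == pytest.approx(row["ICC"], abs=1e-8)
            ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
            ref_lo, ref_hi = row[ci_col]
            assert lo == pytest.approx(ref_lo, abs=6e-3)  # reference CI is rounded
            assert hi == pytest.approx(ref_hi, abs=6e-3)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 2))
        icc_a, _, _ = icc_2_1(x)
        icc_b, _, _ = icc_2_1(x + 123.4)
        assert icc_a == pytest.approx(icc_b, abs=1e-9)

    def test_no_variance_is_signaled(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_2_1(np.full((5, 2), 7.0))


class TestBlandAltman:
    def test_identical_raters(self):
        a = np.array([1.0, 5.0, 9.0, 2.0])
        bias, bias_ci, loa, _ = bland_altman(a, a)
        assert bias == 0.0
        assert loa == (0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([1.0, 5.0, 9.0])
        bias, _, loa, _ = bland_altman(a + 2.5, a)
        assert bias == pytest.approx(2.5)
        assert loa[0] == pytest.approx(2.5)
        assert loa[1] == pytest.approx(2.5)

    def test_matches_direct_formulas(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        bias, bias_ci, loa, loa_cis = bland_altman(a, b)
        d = a - b
        sd = d.std(ddof=1)
        assert bias == pytest.approx(d.mean())
        assert loa[0] == pytest.approx(d.mean() - 1.96 * sd)
        assert loa[1] == pytest.approx(d.mean() + 1.96 * sd)
        t = stats.t.ppf(0.975, 29)
        assert bias_ci[1] - bias_ci[0] == pytest.approx(2 * t * sd / np.sqrt(30))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


@pytest.mark.parametrize(
    "icc,expected",
    [
        (0.92, "strong"),
        (0.80, "strong"),
        (0.79, "moderately_strong"),
        (0.60, "moderately_strong"),
        (0.59, "fair"),
        (0.30, "fair"),
        (0.29, "poor"),
        (-0.5, "poor"),
    ],
)
def test_strength_categories(icc, expected):
    assert strength_category(icc) == expected
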