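"""Condition subsets, paired comparisons, and stop/FOG-related error analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fogkit.datamodel import FrameLabels
from fogkit.experiments import (
    ModelSubset,
    build_subset,
    compare_models,
    count_stop_false_positives,
    error_attribution,
    run_experiment,
)
from fogkit.simulate import Protocol, SimConfig, simulate_cohort

from conftest import small_detector_config


@pytest.fixture(scope="module")
def one_subject_full():
    cfg = SimConfig(seed=6, n_subjects=1, protocol=Protocol.FULL_32, tug_duration_s=(15, 20))
    return simulate_cohort(cfg).manifest


class TestBuildSubset:
    def test_table_style_counts(self, one_subject_full):
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_CLINICAL)) == 12
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_STOP)) == 20
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_TUG)) == 8
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_360TURN)) == 4
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_OFF)) == 6
        assert len(build_subset(one_subject_full, ModelSubset.MODEL_ON)) == 6

    def test_task_subsets_partition_clinical(self, one_subject_full):
        clinical = set(build_subset(one_subject_full, ModelSubset.MODEL_CLINICAL)["trial_id"])
        tug = set(build_subset(one_subject_full, ModelSubset.MODEL_TUG)["trial_id"])
        turn = set(build_subset(one_subject_full, ModelSubset.MODEL_360TURN)["trial_id"])
        assert tug | turn == clinical
        assert not tug & turn

    def test_empty_subset_names_filter(self):
        cfg = SimConfig(seed=6, n_subjects=1, protocol=Protocol.CLINICAL_ONLY,
                        tug_duration_s=(15, 20))
        manifest = simulate_cohort(cfg).manifest
        with pytest.raises(ValueError, match="Model_Stop"):
            build_subset(manifest, ModelSubset.MODEL_STOP)


class TestCompareModels:
    @staticmethod
    def _result(values):
        df = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(len(values))], "sample_f1": values}
        )
        from fogkit.experiments import ExperimentResult

        return ExperimentResult("x", df, {})

    def test_identical_values(self):
        r = self._result([0.5, 0.6, 0.7, 0.8])
        cmp = compare_models(r, r, "sample_f1")
        assert cmp.t == 0.0 and cmp.p == 1.0 and not cmp.degenerate

    def test_constant_nonzero_difference_is_degenerate(self):
        a = self._result([0.5, 0.6, 0.7])
        b = self._result([0.4, 0.5, 0.6])
        cmp = compare_models(a, b, "sample_f1")
        assert cmp.degenerate
        assert np.isnan(cmp.t)

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(3)
        va = rng.random(12)
        vb = rng.random(12)
        cmp = compare_models(self._result(va), self._result(vb), "sample_f1")
        d = va - vb
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert cmp.t == pytest.approx(t_expected)
        assert cmp.n_pairs == 12
        assert cmp.shapiro_p == pytest.approx(float(stats.shapiro(d).pvalue))

    def test_too_few_pairs_rejected(self):
        a = self._result([0.5, 0.6])
        with pytest.raises(ValueError):
            compare_models(a, a, "sample_f1")


class TestStopFalsePositives:
    @staticmethod
    def _fixture():
        # three stop intervals across two trials; FOG predicted inside one
        tiers1 = np.zeros(100, dtype=int)
        tiers1[10:20] = 3
        tiers1[50:60] = 3
        tiers2 = np.zeros(80, dtype=int)
        tiers2[30:45] = 3
        pred1 = np.zeros(100, dtype=int)
        pred1[54] = 1  # one sample inside the second stop
        pred2 = np.zeros(80, dtype=int)
        return (
            [FrameLabels(tiers1), FrameLabels(tiers2)],
            [FrameLabels(pred1), FrameLabels(pred2)],
        )

    def test_hand_traced_fixture(self):
        truth, preds = self._fixture()
        assert count_stop_false_positives(truth, preds) == (1, 3)

    def test_no_predicted_fog(self):
        truth, _ = self._fixture()
        silent = [FrameLabels(np.zeros(len(t), dtype=int)) for t in truth]
        assert count_stop_false_positives(truth, silent) == (0, 3)

    def test_truth_predictions_never_flag_stops(self):
        # stops and FOG never overlap in ground truth, so predicting the
        # true FOG labels flags no stop
        tiers = np.zeros(100, dtype=int)
        tiers[10:20] = 3
        tiers[40:60] = 1
        truth = [FrameLabels(tiers)]
        assert count_stop_false_positives(truth, [FrameLabels(tiers).binary_labels()]) == (0, 1)

    def test_no_stops_warns(self):
        truth = [FrameLabels(np.zeros(50, dtype=int))]
        with pytest.warns(UserWarning, match="no stop"):
            assert count_stop_false_positives(truth, truth) == (0, 0)


class TestErrorAttribution:
    def test_all_fp_inside_fog_related(self):
        tiers = np.zeros(60, dtype=int)
        tiers[20:30] = 2
        pred = np.zeros(60, dtype=int)
        pred[22:28] = 1
        assert error_attribution([FrameLabels(tiers)], [FrameLabels(pred)]) == 100.0

    def test_no_fog_related_tier(self):
        tiers = np.zeros(60, dtype=int)
        pred = np.zeros(60, dtype=int)
        pred[5:10] = 1
        assert error_attribution([FrameLabels(tiers)], [FrameLabels(pred)]) == 0.0

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(14)
        tiers = rng.choice([0, 0, 1, 2, 3], size=500)
        pred = rng.integers(0, 2, size=500)
        got = error_attribution([FrameLabels(tiers)], [FrameLabels(pred)])
        fp = (pred == 1) & (tiers != 1)
        expected = 100.0 * np.sum(fp & (tiers == 2)) / np.sum(fp)
        assert got == pytest.approx(expected)

    def test_zero_fp_signaled(self):
        tiers = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="attribution undefined"):
            error_attribution([FrameLabels(tiers)], [FrameLabels(tiers)])


def test_sanity_mode_experiment_structure():
    """A model evaluated on its own training trials: the segment metric is
    the stricter one, and re-running with the same seed reproduces the
    report bit for bit."""
    cfg = SimConfig(seed=31, n_subjects=3, protocol=Protocol.CLINICAL_ONLY,
                    tug_duration_s=(15, 25))
    cohort = simulate_cohort(cfg)
    dc = small_detector_config(seed=2, epochs=6)
    res = run_experiment(cohort, ModelSubset.MODEL_CLINICAL, ModelSubset.MODEL_CLINICAL,
                         config=dc, loso=False)
    res2 = run_experiment(cohort, ModelSubset.MODEL_CLINICAL, ModelSubset.MODEL_CLINICAL,
                         config=dc, loso=False)
    assert res.per_subject.equals(res2.per_subject)
    assert len(res.per_subject) == 3
    assert (res.per_subject["sample_f1"] >= res.per_subject["segment_f1_at_50"] - 1e-9).mean() >= 0.9
    assert res.mean_sample_f1 > 0.8  # training-set fit on separable data


def test_perfect_predictions_give_unit_agreement():
    """Injecting the expert annotation as the prediction yields ICC 1 and
    F1 1 across subjects."""
    from fogkit.experiments import _evaluate_subject  # noqa: PLC2701
    from fogkit.metrics import icc_2_1

    cfg = SimConfig(seed=32, n_subjects=4, protocol=Protocol.CLINICAL_ONLY,
                    tug_duration_s=(15, 20))
    cohort = simulate_cohort(cfg)

    class Oracle:
        def forward_probs(self, signal):
            raise AssertionError("unused")

    rows_out = []
    for subject in cohort.subjects:
        rows = cohort.manifest[cohort.manifest["subject_id"] == subject]
        truth, pred, f1s, seg = [], [], [], []
        from fogkit.metrics import percent_time_frozen_pooled, count_fog_episodes, sample_f1, segment_f1_at_k
        from fogkit.datamodel import labels_to_segments

        for _, trial, tiers in cohort.iter_trials(rows):
            lab = tiers.binary_labels()
            truth.append(tiers.binary_labels())
            pred.append(lab)
            f1s.append(sample_f1(tiers, lab))
            seg.append(segment_f1_at_k(labels_to_segments(tiers.binary(), 1),
                                       labels_to_segments(lab, 1)))
        rows_out.append(
            (percent_time_frozen_pooled(pred), percent_time_frozen_pooled(truth),
             float(np.mean(f1s)), float(np.mean(seg)))
        )
    table = np.array([(m, e) for m, e, _, _ in rows_out])
    assert icc_2_1(table)[0] == pytest.approx(1.0)
    assert all(f == 1.0 and s == 1.0 for _, _, f, s in rows_out)
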