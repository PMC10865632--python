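"""Experimental designs: condition-specific training subsets, leave-one-
subject-out evaluation, paired model comparisons, and stop-false-positive
analysis.

Training subsets follow the standard naming convention for condition-specific
models: Model_TUG / Model_360Turn / Model_Off / Model_On restrict the
no-stopping ("clinical") trials to one task or one medication state;
Model_Clinical uses all no-stopping trials; Model_Stop uses only trials that
contain a volitional or imposed stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import FrameLabels, LABEL_FOG_RELATED, LABEL_STOP, labels_to_segments
from .detector import DetectorConfig, FOGDetector, build_detector, loso_folds, predict_labels, train_detector
from .metrics import (
    SubjectOutcome,
    agreement_report,
    count_fog_episodes,
    icc_2_1,
    percent_time_frozen_pooled,
    sample_f1,
    segment_f1_at_k,
)
from .postprocess import PostprocessConfig, postprocess_labels
from .simulate import Cohort

__all__ = [
    "ModelSubset",
    "build_subset",
    "ExperimentResult",
    "run_experiment",
    "ComparisonResult",
    "compare_models",
    "count_stop_false_positives",
    "error_attribution",
]


class ModelSubset(str, Enum):
    MODEL_CLINICAL = "Model_Clinical"
    MODEL_TUG = "Model_TUG"
    MODEL_360TURN = "Model_360Turn"
    MODEL_OFF = "Model_Off"
    MODEL_ON = "Model_On"
    MODEL_STOP = "Model_Stop"


_SUBSET_FILTERS: dict[ModelSubset, Callable[[pd.DataFrame], pd.Series]] = {
    ModelSubset.MODEL_CLINICAL: lambda m: m["stop_condition"] == "NONE",
    ModelSubset.MODEL_TUG: lambda m: (m["stop_condition"] == "NONE") & (m["task"] == "TUG"),
    ModelSubset.MODEL_360TURN: lambda m: (m["stop_condition"] == "NONE") & (m["task"] == "TURN360"),
    ModelSubset.MODEL_OFF: lambda m: (m["stop_condition"] == "NONE") & (m["medication"] == "OFF"),
    ModelSubset.MODEL_ON: lambda m: (m["stop_condition"] == "NONE") & (m["medication"] == "ON"),
    ModelSubset.MODEL_STOP: lambda m: m["stop_condition"] != "NONE",
}


def build_subset(manifest: pd.DataFrame, spec: ModelSubset) -> pd.DataFrame:
    """Filter a manifest to the training trials of one named model."""
    spec = ModelSubset(spec)
    mask = _SUBSET_FILTERS[spec](manifest)
    out = manifest[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"subset {spec.value} selected no trials from the manifest")
    return out


# ---------------------------------------------------------------------------
# experiment runner


@dataclass
class ExperimentResult:
    """Per-subject outcomes and pooled agreement for one (train, eval) design."""

    train_subset: str
    per_subject: pd.DataFrame  # subject_id, model/expert %TF and #FOG, F1s
    predictions: dict[str, FrameLabels]  # manifest path -> predicted labels
    skipped_subjects: list[str] = field(default_factory=list)

    @property
    def mean_sample_f1(self) -> float:
        return float(self.per_subject["sample_f1"].mean())

    @property
    def mean_segment_f1(self) -> float:
        return float(self.per_subject["segment_f1_at_50"].mean())

    def icc(self, outcome: str = "percent_tf") -> tuple[float, float, float]:
        return icc_2_1(
            np.column_stack(
                [self.per_subject[f"model_{outcome}"], self.per_subject[f"expert_{outcome}"]]
            )
        )

    def agreement(self, outcome: str = "percent_tf"):
        return agreement_report(
            self.per_subject[f"model_{outcome}"].to_numpy(),
            self.per_subject[f"expert_{outcome}"].to_numpy(),
        )

    def subject_outcomes(self) -> list[SubjectOutcome]:
        return [
            SubjectOutcome(
                subject_id=row["subject_id"],
                percent_tf=row["model_percent_tf"],
                n_fog=int(row["model_n_fog"]),
                mean_sample_f1=row["sample_f1"],
                mean_segment_f1_at_50=row["segment_f1_at_50"],
            )
            for _, row in self.per_subject.iterrows()
        ]


def _evaluate_subject(
    model: FOGDetector,
    cohort: Cohort,
    rows: pd.DataFrame,
    postprocess: PostprocessConfig | None,
) -> tuple[dict, dict[str, FrameLabels]]:
    preds: dict[str, FrameLabels] = {}
    truth_bin, pred_bin = [], []
    f1s, seg_f1s = [], []
    for row, trial, tiers in cohort.iter_trials(rows):
        _, labels = predict_labels(model, trial)
        if postprocess is not None:
            labels = postprocess_labels(labels, postprocess)
        preds[row["path"]] = labels
        truth_bin.append(tiers.binary_labels())
        pred_bin.append(labels)
        f1s.append(sample_f1(tiers, labels))
        seg_f1s.append(
            segment_f1_at_k(
                labels_to_segments(tiers.binary(), 1), labels_to_segments(labels, 1)
            )
        )
    summary = {
        "subject_id": rows.iloc[0]["subject_id"],
        "model_percent_tf": percent_time_frozen_pooled(pred_bin),
        "expert_percent_tf": percent_time_frozen_pooled(truth_bin),
        "model_n_fog": sum(count_fog_episodes(p) for p in pred_bin),
        "expert_n_fog": sum(count_fog_episodes(t) for t in truth_bin),
        "sample_f1": float(np.mean(f1s)),
        "segment_f1_at_50": float(np.mean(seg_f1s)),
        "n_trials": len(rows),
    }
    return summary, preds


def run_experiment(
    cohort: Cohort,
    train_subset: ModelSubset | None,
    eval_subset: ModelSubset | None = None,
    config: DetectorConfig | None = None,
    loso: bool = True,
    epochs: int | None = None,
    postprocess: PostprocessConfig | None = None,
) -> ExperimentResult:
    """Train and evaluate a detector under a condition design.

    With ``loso=True`` (the evaluation protocol for unseen subjects) one
    model per fold is trained on the training-subset trials of the remaining
    subjects and evaluated on the held-out subject's evaluation trials.  With
    ``loso=False`` a single model is trained on the full training subset and
    evaluated per subject on its own data (a sanity mode, not a
    generalization estimate).

    Folds whose training trials contain no positive labels are skipped with
    a warning and recorded in ``skipped_subjects``.
    """
    config = config or DetectorConfig()
    manifest = cohort.manifest
    train_manifest = build_subset(manifest, train_subset) if train_subset else manifest
    eval_manifest = build_subset(manifest, eval_subset) if eval_subset else manifest

    rows_out, predictions, skipped = [], {}, []

    def _fit(train_rows: pd.DataFrame) -> FOGDetector | None:
        has_pos = any(
            cohort.get(r["path"])[1].binary().any() for _, r in train_rows.iterrows()
        )
        if not has_pos:
            return None
        model = build_detector(config)
        train_detector(model, train_rows, cohort=cohort, epochs=epochs)
        return model

    if loso:
        if manifest["subject_id"].nunique() < 3:
            raise ValueError("LOSO experiments require at least 3 subjects")
        for train_subjects, test_subject in loso_folds(manifest):
            eval_rows = eval_manifest[eval_manifest["subject_id"] == test_subject]
            if eval_rows.empty:
                skipped.append(test_subject)
                continue
            train_rows = train_manifest[train_manifest["subject_id"].isin(train_subjects)]
            model = _fit(train_rows)
            if model is None:
                warnings.warn(f"fold {test_subject}: no positive training labels, skipped")
                skipped.append(test_subject)
                continue
            summary, preds = _evaluate_subject(model, cohort, eval_rows, postprocess)
            rows_out.append(summary)
            predictions.update(preds)
    else:
        model = _fit(train_manifest)
        if model is None:
            raise ValueError("training subset contains no positive labels")
        for subject in sorted(eval_manifest["subject_id"].unique()):
            eval_rows = eval_manifest[eval_manifest["subject_id"] == subject]
            summary, preds = _evaluate_subject(model, cohort, eval_rows, postprocess)
            rows_out.append(summary)
            predictions.update(preds)

    per_subject = pd.DataFrame(rows_out)
    return ExperimentResult(
        train_subset=train_subset.value if train_subset else "all",
        per_subject=per_subject,
        predictions=predictions,
        skipped_subjects=skipped,
    )


# ---------------------------------------------------------------------------
# statistical comparison


@dataclass
class ComparisonResult:
    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    t: float
    p: float
    levene_p: float
    shapiro_p: float
    n_pairs: int
    degenerate: bool = False


def compare_models(
    result_a: ExperimentResult,
    result_b: ExperimentResult,
    metric: str = "sample_f1",
) -> ComparisonResult:
    """Paired two-sided t-test on per-subject metric values, with Levene and
    Shapiro-Wilk diagnostics.  Pairs are subjects evaluated in both results.

    A zero-variance nonzero difference is reported as degenerate rather than
    coerced into a t statistic.
    """
    if metric not in ("sample_f1", "segment_f1_at_50", "model_percent_tf", "model_n_fog"):
        raise ValueError(f"unsupported metric {metric!r}")
    a = result_a.per_subject.set_index("subject_id")[metric]
    b = result_b.per_subject.set_index("subject_id")[metric]
    common = sorted(set(a.index) & set(b.index))
    if len(common) < 3:
        raise ValueError("paired comparison requires at least 3 common subjects")
    va = a.loc[common].to_numpy(dtype=float)
    vb = b.loc[common].to_numpy(dtype=float)
    d = va - vb
    n = d.size
    levene_p = float(stats.levene(va, vb).pvalue)
    if np.allclose(d, d[0]):
        shapiro_p = np.nan
        if d[0] == 0:
            return ComparisonResult(metric, va, vb, 0.0, 1.0, levene_p, shapiro_p, n)
        return ComparisonResult(metric, va, vb, np.nan, np.nan, levene_p, shapiro_p, n,
                                degenerate=True)
    shapiro_p = float(stats.shapiro(d).pvalue)
    t_res = stats.ttest_rel(va, vb)
    return ComparisonResult(metric, va, vb, float(t_res.statistic), float(t_res.pvalue),
                            levene_p, shapiro_p, n)


# ---------------------------------------------------------------------------
# stop and FOG-related error analyses


def count_stop_false_positives(
    truth_tiers: Sequence[FrameLabels],
    predictions: Sequence[FrameLabels],
) -> tuple[int, int]:
    """Count stops containing any predicted-FOG sample.

    Returns (#stops detected as FOG, total #stops) over aligned trial lists.
    The strictest reading is used: a single overlapping predicted-FOG sample
    marks the stop as a false positive.
    """
    if len(truth_tiers) != len(predictions):
        raise ValueError("truth and prediction lists must align")
    n_fp = n_stops = 0
    for tiers, pred in zip(truth_tiers, predictions):
        pred_pos = pred.binary() if isinstance(pred, FrameLabels) else np.asarray(pred)
        for seg in labels_to_segments(tiers, LABEL_STOP):
            n_stops += 1
            if pred_pos[seg.start : seg.end].any():
                n_fp += 1
    if n_stops == 0:
        warnings.warn("no stop intervals in the supplied trials")
    return n_fp, n_stops


def error_attribution(
    truth_tiers: Sequence[FrameLabels],
    predictions: Sequence[FrameLabels],
) -> float:
    """Percentage of false-positive samples lying inside FOG-related intervals.

    False positives are predicted-FOG samples the experts did not annotate as
    FOG; the fraction of them falling in tier-2 (shuffling / festination)
    runs attributes errors to FOG-related movement.  Raises when there are no
    false positives.
    """
    if len(truth_tiers) != len(predictions):
        raise ValueError("truth and prediction lists must align")
    n_fp = n_fp_related = 0
    for tiers, pred in zip(truth_tiers, predictions):
        pred_pos = pred.binary() if isinstance(pred, FrameLabels) else np.asarray(pred)
        fp = (pred_pos == 1) & (tiers.binary() == 0)
        n_fp += int(fp.sum())
        n_fp_related += int((fp & (tiers.labels == LABEL_FOG_RELATED)).sum())
    if n_fp == 0:
        raise ValueError("no false-positive samples; attribution undefined")
    return 100.0 * n_fp_related / n_fp
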