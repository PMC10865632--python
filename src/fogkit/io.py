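"""On-disk dialect for trials, annotations, and cohort manifests.

* Trial signal file: CSV, one row per sample, the 30 named signal columns in
  site-major order (``pelvis_acc_x`` ... ``talus_right_gyr_z``), plus an
  optional ``label`` column carrying the four-class annotation tier.
* Sidecar: a JSON file next to the CSV (same stem, ``.json``) holding the
  trial metadata and the sampling rate.
* Annotation interval file: CSV with columns ``start_s,end_s,label``
  (seconds, half-open), convertible to and from per-sample labels.
* Dataset manifest: CSV listing trial files plus their metadata columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    FrameLabels,
    IMUTrial,
    Segment,
    SENSOR_SITES,
    StopCondition,
    TrialMetadata,
    labels_to_segments,
    signal_columns,
)

__all__ = [
    "write_trial",
    "read_trial",
    "frame_labels_to_intervals",
    "intervals_to_frame_labels",
    "write_intervals",
    "read_intervals",
    "write_manifest",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "path",
    "subject_id",
    "trial_id",
    "task",
    "medication",
    "dual_task",
    "stop_condition",
    "duration_s",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trial(trial: IMUTrial, labels: FrameLabels | None, path: str | Path) -> Path:
    """Write a trial to ``path`` (CSV) with a JSON metadata sidecar."""
    path = Path(path)
    if labels is not None and len(labels) != trial.n_samples:
        raise ValueError(
            f"label length {len(labels)} does not match trial length {trial.n_samples}"
        )
    df = pd.DataFrame(trial.signal, columns=trial.columns)
    if labels is not None:
        df["label"] = labels.labels
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")
    meta = trial.metadata
    sidecar = {
        "subject_id": meta.subject_id,
        "trial_id": meta.trial_id,
        "task": meta.task.value,
        "medication": meta.medication.value,
        "dual_task": bool(meta.dual_task),
        "stop_condition": meta.stop_condition.value,
        "sample_rate_hz": trial.sample_rate_hz,
        "sensors": list(trial.sensors),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_trial(path: str | Path) -> tuple[IMUTrial, FrameLabels | None]:
    """Read a trial CSV + JSON sidecar written by :func:`write_trial`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    sensors = tuple(sidecar.get("sensors", SENSOR_SITES))
    unknown = [s for s in sensors if s not in SENSOR_SITES]
    if unknown:
        raise ValueError(f"unknown sensor names in sidecar: {unknown}")
    df = pd.read_csv(path)
    expected = signal_columns(sensors)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing signal columns: {missing}")
    metadata = TrialMetadata(
        subject_id=str(sidecar["subject_id"]),
        trial_id=str(sidecar["trial_id"]),
        task=sidecar["task"],
        medication=sidecar["medication"],
        dual_task=bool(sidecar["dual_task"]),
        stop_condition=sidecar["stop_condition"],
    )
    trial = IMUTrial(
        signal=df[expected].to_numpy(dtype=np.float64),
        metadata=metadata,
        sample_rate_hz=float(sidecar["sample_rate_hz"]),
        sensors=sensors,
    )
    labels = None
    if "label" in df.columns:
        labels = FrameLabels(df["label"].to_numpy(), sample_rate_hz=trial.sample_rate_hz)
    return trial, labels


# ---------------------------------------------------------------------------
# interval files


def frame_labels_to_intervals(labels: FrameLabels) -> pd.DataFrame:
    """Express non-background runs as half-open [start_s, end_s) rows."""
    rows = []
    for cls in (1, 2, 3):
        for seg in labels_to_segments(labels, cls):
            rows.append(
                {
                    "start_s": seg.start / labels.sample_rate_hz,
                    "end_s": seg.end / labels.sample_rate_hz,
                    "label": cls,
                }
            )
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    return df.sort_values(["start_s", "label"], ignore_index=True)


def intervals_to_frame_labels(
    intervals: pd.DataFrame, duration_s: float, sample_rate_hz: float = 64.0
) -> FrameLabels:
    """Rasterize half-open second-valued intervals onto a sample grid."""
    n = int(round(duration_s * sample_rate_hz))
    segments = []
    for _, row in intervals.iterrows():
        start = int(round(float(row["start_s"]) * sample_rate_hz))
        end = int(round(float(row["end_s"]) * sample_rate_hz))
        if end > start:
            segments.append(Segment(start, min(end, n), int(row["label"])))
    out = FrameLabels(np.zeros(n, dtype=np.int64), sample_rate_hz)
    for seg in segments:
        out.labels[seg.start : seg.end] = seg.label
    return out


def write_intervals(labels: FrameLabels, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame_labels_to_intervals(labels).to_csv(path, index=False)
    return path


def read_intervals(path: str | Path, duration_s: float, sample_rate_hz: float = 64.0) -> FrameLabels:
    return intervals_to_frame_labels(pd.read_csv(path), duration_s, sample_rate_hz)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    out = manifest.copy()
    # store paths relative to the manifest location when possible
    root = path.parent.resolve()
    rel = []
    for p in out["path"]:
        p = Path(p)
        try:
            rel.append(str(p.resolve().relative_to(root)))
        except ValueError:
            rel.append(str(p))
    out["path"] = rel
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    root = path.parent.resolve()
    df["path"] = [str((root / p).resolve()) if not Path(p).is_absolute() else p for p in df["path"]]
    dup = df.duplicated(subset=["subject_id", "trial_id"])
    if dup.any():
        raise ValueError("duplicate (subject_id, trial_id) pairs in manifest")
    return df


def manifest_row(path: str | Path, trial: IMUTrial) -> dict:
    meta = trial.metadata
    return {
        "path": str(path),
        "subject_id": meta.subject_id,
        "trial_id": meta.trial_id,
        "task": meta.task.value,
        "medication": meta.medication.value,
        "dual_task": bool(meta.dual_task),
        "stop_condition": meta.stop_condition.value,
        "duration_s": trial.duration_s,
    }
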