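"""Synthetic IMU cohort generator for freezing-of-gait experiments.

The generator emulates the statistical structure of a lab-based FOG-provoking
protocol recorded with five inertial sensors (pelvis, both tibiae, both tali)
at 64 Hz:

* quasi-periodic gait at a configurable cadence in the lower-limb channels,
  with a harmonic mix and per-channel gains/phases;
* three FOG manifestations: **trembling** (band-limited 8-13 Hz leg
  oscillation replacing locomotor content), **shuffling** (elevated cadence at
  strongly reduced amplitude), and **akinesia** (near-zero lower-limb
  movement, preceded by an abrupt sub-half-second trembling burst);
* volitional / imposed **stops** (near-zero lower-limb movement preceded by a
  smooth cadence decay of at least half a second) - the smooth-vs-abrupt
  onset is the learnable cue that separates a stop from akinetic freezing;
* FOG-related events (non-paroxysmal shuffling / festination) on label
  tier 2, kinematically similar to shuffling FOG but annotated negative;
* a full protocol of 32 trials per subject: per medication state, three
  clinical trials (two timed-up-and-go, one 360-degree turning-in-place) with
  and without a dual task, plus five stopping trials for each of the
  self-generated and imposed stop conditions.

Episode durations are drawn log-normal with support clipped to
[0.05 s, 63.62 s] and parameters chosen so the mean is ~3.01 s with roughly
40% of episodes shorter than one second.  Between-subject severity is a
log-normal multiplier on the episode rate, so percent time frozen varies
across subjects from near zero to tens of percent.

This is a phenomenological signal model, not a biomechanical one: it gives a
sequence-labeling model learnable class structure with the documented
spectral and variance signatures, which is what the evaluation layer needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fog_io
from .datamodel import (
    FrameLabels,
    IMUTrial,
    LABEL_FOG,
    LABEL_FOG_RELATED,
    LABEL_STOP,
    Medication,
    SENSOR_SITES,
    StopCondition,
    Task,
    TrialMetadata,
    labels_to_segments,
)

__all__ = [
    "Protocol",
    "Manifestation",
    "SimConfig",
    "Cohort",
    "SimulationError",
    "simulate_trial",
    "simulate_cohort",
    "cohort_summary",
    "sample_episode_durations",
]

FS = 64.0  # protocol sampling rate, Hz


class SimulationError(RuntimeError):
    """Raised when a requested event cannot be hosted by a trial."""


class Protocol(str, Enum):
    FULL_32 = "FULL_32"
    CLINICAL_ONLY = "CLINICAL_ONLY"
    STOP_ONLY = "STOP_ONLY"
    CUSTOM = "CUSTOM"


class Manifestation(str, Enum):
    TREMBLING = "trembling"
    SHUFFLING = "shuffling"
    AKINESIA = "akinesia"


# Log-normal episode-duration parameters solved for mean 3.01 s with ~42% of
# episodes below 1 s: exp(mu + sigma^2/2) = 3.01 and Phi(-mu/sigma) = 0.42.
_EP_MU = 0.2596
_EP_SIGMA = 1.2980


@dataclass
class SimConfig:
    """Cohort-level generator settings; defaults mirror the study protocol."""

    seed: int = 0
    n_subjects: int = 12
    protocol: Protocol = Protocol.FULL_32
    sample_rate_hz: float = FS
    gait_cadence_hz: float = 1.8  # steps per second
    fog_rate_per_min: float = 2.2
    manifestation_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    episode_mu: float = _EP_MU
    episode_sigma: float = _EP_SIGMA
    episode_min_s: float = 0.05
    episode_max_s: float = 63.62
    stop_duration_s: tuple[float, float] = (2.0, 6.0)
    noise_sd: float = 0.1
    subject_severity_spread: float = 0.8  # sd of log severity multiplier
    fog_related_rate_per_min: float = 1.0
    dual_task_multiplier: float = 1.5
    tug_duration_s: tuple[float, float] = (15.0, 60.0)
    turn_duration_s: float = 60.0

    def __post_init__(self) -> None:
        self.protocol = Protocol(self.protocol)
        mix = np.asarray(self.manifestation_mix, dtype=float)
        if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("manifestation_mix must be 3 probabilities summing to 1")
        if not (self.episode_min_s < np.exp(self.episode_mu + self.episode_sigma**2 / 2) < self.episode_max_s):
            raise ValueError("episode duration support must satisfy min < mean < max")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def sample_episode_durations(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw FOG episode durations (seconds) from the clipped log-normal model."""
    d = rng.lognormal(config.episode_mu, config.episode_sigma, size=n)
    return np.clip(d, config.episode_min_s, config.episode_max_s)


# ---------------------------------------------------------------------------
# channel geometry: fixed per-channel gains and phases (site-major, 30 ch)

_N_CH = 6 * len(SENSOR_SITES)


def _channel_gains() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.arange(_N_CH, dtype=float)
    gait = 1.2 + 0.8 * ((idx * 0.37) % 1.0)
    tremor = np.empty(_N_CH)
    for i in range(_N_CH):
        is_gyro = (i % 6) >= 3
        tremor[i] = 1.4 if is_gyro else 0.8
    phases = 2 * np.pi * ((idx * 0.13) % 1.0)
    # pelvis (site 0) moves much less than the lower limbs
    gait[:6] *= 0.3
    tremor[:6] *= 0.1
    return gait, tremor, phases


_GAIT_GAIN, _TREMOR_GAIN, _CH_PHASE = _channel_gains()
_GRAVITY = 9.81
_LOWER_LIMB_CH = np.arange(6, _N_CH)  # tibia + talus channels


@dataclass(frozen=True)
class _Event:
    start: int
    end: int
    kind: str  # trembling | shuffling | akinesia | stop | fog_related
    freq_hz: float = 0.0


def _free_slot(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    T: int,
    margin: int,
    tries: int = 60,
) -> int | None:
    """Uniformly search for a start index keeping ``margin`` samples clearance."""
    lo, hi = margin, T - margin - length
    if hi < lo:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi + 1))
        if all(s + length + margin <= a or s >= b + margin for a, b in occupied):
            return s
    return None


def simulate_trial(
    config: SimConfig,
    metadata: TrialMetadata,
    seed: int,
    severity: float = 1.0,
) -> tuple[IMUTrial, FrameLabels]:
    """Generate one labeled trial.

    Returns the 30-channel signal and the four-class ground-truth tier
    (FOG=1, FOG-related=2, stop=3).  Labels align exactly with the generating
    regimes.  Deterministic for a given (config, metadata, seed, severity).
    """
    rng = np.random.default_rng(seed)
    fs = config.sample_rate_hz

    if metadata.task is Task.TUG:
        duration_s = float(rng.uniform(*config.tug_duration_s))
    else:
        duration_s = float(config.turn_duration_s)
    T = int(round(duration_s * fs))
    margin = int(round(1.0 * fs))

    events: list[_Event] = []
    occupied: list[tuple[int, int]] = []

    # --- stop interval (placed first: it is requested, not random) ---------
    if metadata.is_stopping:
        stop_len = int(round(rng.uniform(*config.stop_duration_s) * fs))
        ramp_len = int(round(rng.uniform(0.6, 1.2) * fs))
        lo = margin + ramp_len
        hi = T - margin - stop_len
        if hi < lo:
            raise SimulationError(
                f"trial of {duration_s:.1f}s too short to host the requested stop"
            )
        if metadata.stop_condition is StopCondition.IMPOSED:
            stop_start = int(np.clip(0.45 * T, lo, hi))  # cued at a fixed point
        else:
            stop_start = int(rng.integers(lo, hi + 1))
        events.append(_Event(stop_start, stop_start + stop_len, "stop"))
        occupied.append((stop_start - ramp_len, stop_start + stop_len))
    else:
        ramp_len = 0

    # --- FOG episodes ------------------------------------------------------
    rate = config.fog_rate_per_min * severity
    if metadata.dual_task:
        rate *= config.dual_task_multiplier
    n_ep = rng.poisson(rate * duration_s / 60.0)
    kinds = rng.choice(
        [m.value for m in Manifestation], size=n_ep, p=config.manifestation_mix
    )
    durations = sample_episode_durations(config, rng, n_ep)
    for kind, dur in zip(kinds, durations):
        length = max(3, int(round(dur * fs)))
        length = min(length, T - 2 * margin)
        if length < 3:
            continue
        start = _free_slot(rng, occupied, length, T, margin)
        if start is None:
            continue
        events.append(_Event(start, start + length, kind, freq_hz=float(rng.uniform(8.5, 12.5))))
        occupied.append((start, start + length))

    # --- FOG-related (tier 2) shuffling precursors -------------------------
    n_rel = rng.poisson(config.fog_related_rate_per_min * duration_s / 60.0)
    for _ in range(n_rel):
        length = int(round(rng.uniform(0.5, 3.0) * fs))
        start = _free_slot(rng, occupied, length, T, margin)
        if start is None:
            continue
        events.append(_Event(start, start + length, "fog_related"))
        occupied.append((start, start + length))

    # --- envelopes ----------------------------------------------------------
    amp = np.ones(T)  # gait amplitude envelope
    freq = np.full(T, config.gait_cadence_hz)  # instantaneous cadence
    tremor = np.zeros(T)  # tremor envelope
    tremor_phase = np.zeros(T)  # per-sample tremor phase
    labels = np.zeros(T, dtype=np.int64)

    burst_len = int(round(0.3 * fs))  # abrupt onset burst of akinetic FOG
    for ev in events:
        sl = slice(ev.start, ev.end)
        if ev.kind == "stop":
            labels[sl] = LABEL_STOP
            amp[sl] = 0.0
            # smooth >= 0.5 s cadence decay before the stop: the cue that
            # distinguishes a volitional stop from akinetic freezing
            ramp = slice(ev.start - ramp_len, ev.start)
            amp[ramp] = np.minimum(amp[ramp], np.linspace(1.0, 0.0, ramp_len))
            resume = slice(ev.end, min(ev.end + int(0.5 * fs), T))
            n_res = resume.stop - resume.start
            if n_res > 0:
                amp[resume] = np.minimum(amp[resume], np.linspace(0.0, 1.0, n_res))
        elif ev.kind == "trembling":
            labels[sl] = LABEL_FOG
            amp[sl] = 0.0
            tremor[sl] = 1.0
            t_rel = np.arange(ev.end - ev.start) / fs
            tremor_phase[sl] = 2 * np.pi * ev.freq_hz * t_rel
        elif ev.kind == "akinesia":
            labels[sl] = LABEL_FOG
            amp[sl] = 0.0
            b_end = min(ev.start + burst_len, ev.end)
            tremor[ev.start : b_end] = 1.0
            t_rel = np.arange(b_end - ev.start) / fs
            tremor_phase[ev.start : b_end] = 2 * np.pi * ev.freq_hz * t_rel
        elif ev.kind == "shuffling":
            labels[sl] = LABEL_FOG
            amp[sl] = 0.25
            freq[sl] = config.gait_cadence_hz * 1.6
        elif ev.kind == "fog_related":
            labels[sl] = LABEL_FOG_RELATED
            amp[sl] = 0.4
            freq[sl] = config.gait_cadence_hz * 1.4

    # --- synthesis ----------------------------------------------------------
    phase = 2 * np.pi * np.cumsum(freq) / fs
    gait1 = amp[:, None] * np.sin(phase[:, None] + _CH_PHASE[None, :])
    gait2 = 0.35 * amp[:, None] * np.sin(2 * phase[:, None] + 1.7 * _CH_PHASE[None, :])
    signal = (gait1 + gait2) * _GAIT_GAIN[None, :]
    signal += (tremor * np.sin(tremor_phase))[:, None] * _TREMOR_GAIN[None, :]

    # gravity on accelerometer z channels; turning rate on the pelvis yaw gyro
    acc_z_cols = [i for i in range(_N_CH) if i % 6 == 2]
    signal[:, acc_z_cols] += _GRAVITY
    if metadata.task is Task.TURN360:
        alt = np.sign(np.sin(2 * np.pi * np.arange(T) / (4.2 * fs)) + 1e-12)
        signal[:, 5] += 150.0 * amp * alt  # pelvis_gyr_z, deg/s

    signal += rng.normal(0.0, config.noise_sd, size=(T, _N_CH))

    trial = IMUTrial(signal=signal, metadata=metadata, sample_rate_hz=fs)
    tiers = FrameLabels(labels, sample_rate_hz=fs)
    return trial, tiers


# ---------------------------------------------------------------------------
# protocol / cohort


def _protocol_blocks(protocol: Protocol) -> list[dict]:
    clinical, stopping = [], []
    for med in (Medication.OFF, Medication.ON):
        for dual in (False, True):
            for rep in (1, 2):
                clinical.append(dict(task=Task.TUG, medication=med, dual_task=dual,
                                     stop_condition=StopCondition.NONE, rep=rep))
            clinical.append(dict(task=Task.TURN360, medication=med, dual_task=dual,
                                 stop_condition=StopCondition.NONE, rep=1))
        for stop in (StopCondition.SELF_GENERATED, StopCondition.IMPOSED):
            for rep in (1, 2, 3, 4):
                stopping.append(dict(task=Task.TUG, medication=med, dual_task=False,
                                     stop_condition=stop, rep=rep))
            stopping.append(dict(task=Task.TURN360, medication=med, dual_task=False,
                                 stop_condition=stop, rep=1))
    if protocol is Protocol.FULL_32:
        return clinical + stopping
    if protocol is Protocol.CLINICAL_ONLY:
        return clinical
    if protocol is Protocol.STOP_ONLY:
        return stopping
    raise ValueError(f"unknown or custom protocol: {protocol}")


def _trial_id(spec: dict) -> str:
    med = spec["medication"].value
    task = spec["task"].value
    if spec["stop_condition"] is StopCondition.NONE:
        dt = "DT" if spec["dual_task"] else "ST"
        return f"{med}_{dt}_{task}_r{spec['rep']}"
    return f"{med}_{spec['stop_condition'].value}_{task}_r{spec['rep']}"


@dataclass
class Cohort:
    """A simulated dataset: a manifest plus (possibly in-memory) trial storage."""

    manifest: pd.DataFrame
    trials: dict[str, tuple[IMUTrial, FrameLabels]] = field(default_factory=dict)

    def get(self, path: str) -> tuple[IMUTrial, FrameLabels]:
        if path in self.trials:
            return self.trials[path]
        trial, labels = fog_io.read_trial(path)
        if labels is None:
            raise ValueError(f"trial {path} has no label column")
        return trial, labels

    def iter_trials(self, manifest: pd.DataFrame | None = None):
        rows = self.manifest if manifest is None else manifest
        for _, row in rows.iterrows():
            yield row, *self.get(row["path"])

    @property
    def subjects(self) -> list[str]:
        return sorted(self.manifest["subject_id"].unique())


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a labeled cohort under the configured protocol.

    With ``out_dir`` set, trial CSVs, sidecars, and ``manifest.csv`` are
    written to disk; otherwise trials are kept in memory keyed by pseudo-path.
    Per-subject FOG severity is a log-normal multiplier on the episode rate.
    """
    blocks = _protocol_blocks(config.protocol)
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    rows, store = [], {}
    out_path = Path(out_dir) if out_dir is not None else None

    for s_idx, s_seq in enumerate(subject_seqs):
        subject_id = f"S{s_idx + 1:02d}"
        s_rng = np.random.default_rng(s_seq)
        severity = float(np.exp(s_rng.normal(0.0, config.subject_severity_spread)))
        trial_seeds = s_seq.spawn(len(blocks))
        for spec, t_seq in zip(blocks, trial_seeds):
            metadata = TrialMetadata(
                subject_id=subject_id,
                trial_id=_trial_id(spec),
                task=spec["task"],
                medication=spec["medication"],
                dual_task=spec["dual_task"],
                stop_condition=spec["stop_condition"],
            )
            seed = int(t_seq.generate_state(1)[0])
            trial, tiers = simulate_trial(config, metadata, seed, severity)
            if out_path is not None:
                path = out_path / subject_id / f"{metadata.trial_id}.csv"
                fog_io.write_trial(trial, tiers, path)
                key = str(path)
            else:
                key = f"mem://{subject_id}/{metadata.trial_id}"
                store[key] = (trial, tiers)
            rows.append(fog_io.manifest_row(key, trial))

    manifest = pd.DataFrame(rows, columns=fog_io.MANIFEST_COLUMNS)
    cohort = Cohort(manifest=manifest, trials=store)
    if out_path is not None:
        fog_io.write_manifest(manifest, out_path / "manifest.csv")
    return cohort


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-subject overview: duration, trial/episode counts, %TF, duration stats."""
    from .metrics import count_fog_episodes, percent_time_frozen_pooled

    rows = []
    for subject in cohort.subjects:
        sub = cohort.manifest[cohort.manifest["subject_id"] == subject]
        all_labels, ep_durs, n_fog_trials, n_fog = [], [], 0, 0
        for _, trial, tiers in cohort.iter_trials(sub):
            all_labels.append(tiers)
            segs = labels_to_segments(tiers, LABEL_FOG)
            n_fog += len(segs)
            n_fog_trials += bool(segs)
            ep_durs.extend(seg.duration_s(tiers.sample_rate_hz) for seg in segs)
        rows.append(
            {
                "subject_id": subject,
                "total_duration_min": sub["duration_s"].sum() / 60.0,
                "n_trials": len(sub),
                "n_fog_trials": n_fog_trials,
                "n_fog": n_fog,
                "percent_tf": percent_time_frozen_pooled(all_labels),
                "episode_mean_s": float(np.mean(ep_durs)) if ep_durs else np.nan,
                "episode_min_s": float(np.min(ep_durs)) if ep_durs else np.nan,
                "episode_max_s": float(np.max(ep_durs)) if ep_durs else np.nan,
            }
        )
    return pd.DataFrame(rows)
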