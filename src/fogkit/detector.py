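"""Two-block freezing-of-gait detector: temporal-convolutional initial
prediction plus multi-stage prediction refinement.

The initial block maps the raw multichannel IMU sequence (T x channels) to
per-sample class probabilities (T x 2, columns non-FOG / FOG) through a tower
of dilated residual convolutions with doubling dilations.  Each refinement
stage consumes the T x 2 probability sequence of the previous stage and
re-emits a smoothed T x 2 sequence, counteracting over-segmentation (long
episodes split into many short predicted episodes).

Training minimizes, summed over stages, a class-weighted cross-entropy plus
a truncated mean-squared difference of consecutive log-probabilities (the
smoothing penalty of multi-stage action-segmentation models).  Inference
processes whole trials - the network is fully convolutional, so no windowing
is needed.  Per-channel z-score normalization statistics are estimated from
the training trials only and stored with the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import FrameLabels, IMUTrial
from .nn import Adam, MultiStageTCN, softmax, softmax_backward

__all__ = [
    "InitialBlockConfig",
    "RefinementConfig",
    "TrainConfig",
    "DetectorConfig",
    "PredictionSequence",
    "FOGDetector",
    "build_detector",
    "train_detector",
    "predict_labels",
    "loso_folds",
]

MIN_RECEPTIVE_FIELD_S = 2.0


@dataclass
class InitialBlockConfig:
    n_layers: int = 8
    filters_per_layer: int = 64
    kernel_size: int = 3
    dropout: float = 0.1


@dataclass
class RefinementConfig:
    n_stages: int = 3
    layers_per_stage: int = 8
    filters: int = 64


@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 5e-4
    batch_size: int = 1
    class_weighting: str = "inverse_frequency"  # or "none"
    smoothing_loss_weight: float = 0.15
    smoothing_clamp: float = 16.0  # truncation of squared log-prob differences
    seed: int = 0


@dataclass
class DetectorConfig:
    in_channels: int = 30
    sample_rate_hz: float = 64.0
    initial_block: InitialBlockConfig = field(default_factory=InitialBlockConfig)
    refinement_block: RefinementConfig = field(default_factory=RefinementConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if isinstance(self.initial_block, dict):
            self.initial_block = InitialBlockConfig(**self.initial_block)
        if isinstance(self.refinement_block, dict):
            self.refinement_block = RefinementConfig(**self.refinement_block)
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        if self.refinement_block.n_stages < 1:
            raise ValueError("refinement_block.n_stages must be >= 1")
        rf = self.receptive_field
        min_rf = int(MIN_RECEPTIVE_FIELD_S * self.sample_rate_hz)
        if rf < min_rf:
            raise ValueError(
                f"initial-block receptive field is {rf} samples "
                f"({rf / self.sample_rate_hz:.2f} s); at least {min_rf} samples "
                f"({MIN_RECEPTIVE_FIELD_S:.0f} s) are required"
            )

    @property
    def receptive_field(self) -> int:
        """Receptive field of the initial block in samples (doubling dilations)."""
        ib = self.initial_block
        return 1 + (ib.kernel_size - 1) * sum(2**i for i in range(ib.n_layers))


@dataclass
class PredictionSequence:
    """Per-stage T x 2 class-probability sequences (columns: non-FOG, FOG)."""

    stage_probs: list[np.ndarray]

    @property
    def probs(self) -> np.ndarray:
        """Final-stage probabilities, shape (T, 2)."""
        return self.stage_probs[-1]


class FOGDetector:
    """Model handle: network, configuration, and normalization statistics."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        rng = np.random.default_rng(config.train.seed)
        ib, rb = config.initial_block, config.refinement_block
        self.net = MultiStageTCN(
            in_channels=config.in_channels,
            n_classes=2,
            initial_layers=ib.n_layers,
            initial_filters=ib.filters_per_layer,
            n_refinement_stages=rb.n_stages,
            refinement_layers=rb.layers_per_stage,
            refinement_filters=rb.filters,
            kernel_size=ib.kernel_size,
            dropout=ib.dropout,
            rng=rng,
        )
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    # -- persistence ---------------------------------------------------------

    def save(self, model_dir: str | Path) -> Path:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        (model_dir / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        arrays = self.net.state_arrays()
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(model_dir / "weights.npz", **arrays)
        return model_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "FOGDetector":
        model_dir = Path(model_dir)
        config = DetectorConfig(**json.loads((model_dir / "config.json").read_text()))
        model = cls(config)
        with np.load(model_dir / "weights.npz") as data:
            arrays = {k: data[k] for k in data.files}
        if "norm_mean" in arrays:
            model.norm_mean = arrays.pop("norm_mean")
            model.norm_std = arrays.pop("norm_std")
        model.net.load_state_arrays(arrays)
        return model

    # -- inference -----------------------------------------------------------

    def _normalize(self, signal: np.ndarray) -> np.ndarray:
        x = signal.T.astype(np.float32)
        if self.norm_mean is not None:
            x = (x - self.norm_mean[:, None]) / self.norm_std[:, None]
        return x

    def forward_probs(self, signal: np.ndarray) -> PredictionSequence:
        """Run the network on a (T, channels) signal; no training-mode noise."""
        if signal.shape[1] != self.config.in_channels:
            raise ValueError(
                f"signal has {signal.shape[1]} channels; the model expects "
                f"{self.config.in_channels} (site-major, accelerometer before gyro)"
            )
        logits_list = self.net.forward(self._normalize(signal), train=False)
        return PredictionSequence([softmax(lg).T.astype(np.float64) for lg in logits_list])


def build_detector(config: DetectorConfig | None = None) -> FOGDetector:
    """Construct a detector with seeded, deterministic initial parameters."""
    return FOGDetector(config or DetectorConfig())


# ---------------------------------------------------------------------------
# training


def _loss_and_grad(
    logits: np.ndarray,
    probs: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray,
    smooth_weight: float,
    smooth_clamp: float,
) -> tuple[float, np.ndarray]:
    """Cross-entropy + truncated smoothing loss for one stage.

    ``logits``/``probs`` are (2, T); ``y`` is the binary target.  Returns the
    scalar loss and dL/dlogits.
    """
    T = y.size
    w = class_weights[y]  # (T,)
    p_true = np.clip(probs[y, np.arange(T)], 1e-12, None)
    ce = float(np.sum(w * -np.log(p_true)) / T)
    onehot = np.zeros_like(probs)
    onehot[y, np.arange(T)] = 1.0
    dlogits = (probs - onehot) * (w / T)[None, :]

    if smooth_weight > 0.0 and T > 1:
        logp = np.log(np.clip(probs, 1e-12, None))
        d = logp[:, 1:] - logp[:, :-1]
        dsq = d * d
        clamped = np.minimum(dsq, smooth_clamp)
        n = clamped.size
        smooth = float(clamped.sum() / n)
        grad_d = 2.0 * d * (dsq < smooth_clamp) / n
        g = np.zeros_like(logp)
        g[:, 1:] += grad_d
        g[:, :-1] -= grad_d
        # d(log p)/d(logits) = I - p applied column-wise
        dlogits += smooth_weight * (g - probs * g.sum(axis=0, keepdims=True))
        ce += smooth_weight * smooth
    return ce, dlogits


def _as_dataset(
    data, cohort=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize supported inputs to a list of (signal (T,C), binary labels)."""
    out = []
    if isinstance(data, pd.DataFrame):
        if cohort is None:
            raise ValueError("a manifest DataFrame requires the cohort argument")
        for _, row in data.iterrows():
            trial, labels = cohort.get(row["path"])
            out.append((trial.signal, labels.binary()))
        return out
    for item in data:
        trial, labels = item
        signal = trial.signal if isinstance(trial, IMUTrial) else np.asarray(trial)
        y = labels.binary() if isinstance(labels, FrameLabels) else np.asarray(labels)
        out.append((signal, y))
    return out


def train_detector(
    model: FOGDetector,
    data,
    cohort=None,
    epochs: int | None = None,
) -> list[float]:
    """Train in place; returns the per-epoch mean loss history.

    ``data`` is either a manifest DataFrame (with ``cohort`` supplying trial
    access) or an iterable of (trial, labels) pairs.  Reproducible for a
    fixed (data, config, seed).
    """
    cfg = model.config.train
    dataset = _as_dataset(data, cohort)
    if not dataset:
        raise ValueError("empty training set")
    n_epochs = cfg.epochs if epochs is None else epochs

    # normalization statistics from the training set only (no test leakage)
    stacked_sum = np.zeros(model.config.in_channels)
    stacked_sq = np.zeros(model.config.in_channels)
    n_total = 0
    n_pos = 0
    for signal, y in dataset:
        stacked_sum += signal.sum(axis=0)
        stacked_sq += (signal**2).sum(axis=0)
        n_total += signal.shape[0]
        n_pos += int(y.sum())
    mean = stacked_sum / n_total
    var = stacked_sq / n_total - mean**2
    model.norm_mean = mean.astype(np.float32)
    model.norm_std = np.sqrt(np.maximum(var, 1e-8)).astype(np.float32) + np.float32(1e-6)

    if cfg.class_weighting == "inverse_frequency":
        if n_pos == 0 or n_pos == n_total:
            raise ValueError(
                "inverse-frequency weighting requires both classes in the training labels"
            )
        counts = np.array([n_total - n_pos, n_pos], dtype=np.float64)
        class_weights = (n_total / (2.0 * counts)).astype(np.float32)
    elif cfg.class_weighting == "none":
        class_weights = np.ones(2, dtype=np.float32)
    else:
        raise ValueError(f"unknown class_weighting {cfg.class_weighting!r}")

    inputs = [
        (model._normalize(signal), y.astype(np.int64)) for signal, y in dataset
    ]
    rng = np.random.default_rng(cfg.seed + 1)  # dropout + shuffling stream
    optimizer = Adam(model.net, lr=cfg.learning_rate)
    history: list[float] = []
    order = np.arange(len(inputs))
    for _ in range(n_epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for idx in order:
            x, y = inputs[idx]
            model.net.zero_grad()
            logits_list = model.net.forward(x, train=True, rng=rng)
            dlogits_list = []
            total = 0.0
            for logits, probs in zip(logits_list, model.net._probs):
                loss, dlogits = _loss_and_grad(
                    logits, probs, y, class_weights,
                    cfg.smoothing_loss_weight, cfg.smoothing_clamp,
                )
                total += loss
                dlogits_list.append(dlogits)
            model.net.backward(dlogits_list)
            optimizer.step()
            epoch_loss += total
        history.append(epoch_loss / len(inputs))
    return history


def predict_labels(model: FOGDetector, trial: IMUTrial | np.ndarray) -> tuple[PredictionSequence, FrameLabels]:
    """Predict per-sample FOG labels for a whole trial.

    Labels are the argmax of the final refinement stage; a tied probability
    of exactly 0.5 resolves to non-FOG.
    """
    signal = trial.signal if isinstance(trial, IMUTrial) else np.asarray(trial)
    rate = trial.sample_rate_hz if isinstance(trial, IMUTrial) else model.config.sample_rate_hz
    pred = model.forward_probs(signal)
    labels = (pred.probs[:, 1] > 0.5).astype(np.int64)
    return pred, FrameLabels(labels, sample_rate_hz=rate)


def loso_folds(manifest: pd.DataFrame) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out folds: (train_subjects, test_subject) per subject."""
    subjects = sorted(pd.unique(manifest["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least two subjects")
    return [([s for s in subjects if s != held_out], held_out) for held_out in subjects]
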