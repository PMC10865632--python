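"""Rule-based episode post-processing.

The rule merges predicted FOG episodes separated by at most ``gap_max``
samples into single episodes and then discards episodes shorter than
``min_len`` samples.  The defaults (21 samples each at 64 Hz, i.e. 0.33 s)
reflect the observation that the overwhelming majority of true episodes last
longer than a third of a second, while over-segmented model output tends to
split long episodes by very short gaps.

Merging runs before removal so that short fragments of a fragmented long
episode are rescued rather than deleted.  Both thresholds are configurable;
the boundary semantics are gap <= gap_max merged, length < min_len removed.
This rule set is an alternative to the learned refinement block.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import FrameLabels, LABEL_FOG, Segment, labels_to_segments, segments_to_labels

__all__ = [
    "PostprocessConfig",
    "merge_close_episodes",
    "remove_short_episodes",
    "postprocess_labels",
]


@dataclass(frozen=True)
class PostprocessConfig:
    gap_max_samples: int = 21
    min_len_samples: int = 21
    sample_rate_hz: float = 64.0

    def __post_init__(self) -> None:
        if self.gap_max_samples < 0 or self.min_len_samples < 0:
            raise ValueError("thresholds must be >= 0")

    @property
    def gap_max_s(self) -> float:
        return self.gap_max_samples / self.sample_rate_hz

    @property
    def min_len_s(self) -> float:
        return self.min_len_samples / self.sample_rate_hz


def _check_sorted(segments: list[Segment]) -> None:
    for prev, cur in zip(segments, segments[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"segments must be sorted and non-overlapping; "
                f"[{prev.start},{prev.end}) precedes [{cur.start},{cur.end})"
            )


def merge_close_episodes(segments: list[Segment], gap_max: int) -> list[Segment]:
    """Union consecutive episodes whose gap (next.start - prev.end) <= gap_max.

    Applied transitively left to right; input must be sorted, non-overlapping.
    """
    _check_sorted(segments)
    if not segments:
        return []
    merged = [segments[0]]
    for seg in segments[1:]:
        prev = merged[-1]
        if seg.start - prev.end <= gap_max:
            merged[-1] = Segment(prev.start, max(prev.end, seg.end), prev.label)
        else:
            merged.append(seg)
    return merged


def remove_short_episodes(segments: list[Segment], min_len: int) -> list[Segment]:
    """Drop episodes strictly shorter than ``min_len`` samples."""
    _check_sorted(segments)
    return [seg for seg in segments if seg.length >= min_len]


def postprocess_labels(labels: FrameLabels, config: PostprocessConfig | None = None) -> FrameLabels:
    """Apply merge-then-remove to the FOG class of a binary label vector.

    Idempotent: applying the pipeline twice equals applying it once.
    """
    config = config or PostprocessConfig()
    segments = labels_to_segments(labels, LABEL_FOG)
    segments = merge_close_episodes(segments, config.gap_max_samples)
    segments = remove_short_episodes(segments, config.min_len_samples)
    out = segments_to_labels(segments, len(labels))
    out.sample_rate_hz = labels.sample_rate_hz
    return out
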