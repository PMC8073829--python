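"""Segmentation of recordings into training windows.

Supports sliding windows (the pipeline default: stride 1 s, window 2 s),
fixed windows (sliding with stride == window), beat-aligned segments cut at
S1 onsets from a state annotation, and no segmentation (the whole record as
one segment).  Record-level decisions are recovered from segment-level
probabilities by :func:`aggregate_record`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigError, DataError, Recording, StateAnnotation, check_alignment

__all__ = [
    "SegmentSet",
    "sliding_segments",
    "fixed_segments",
    "beat_segments",
    "no_segments",
    "aggregate_record",
]


@dataclass
class SegmentSet:
    """Equal-length sample windows cut from one recording."""

    record_id: str
    segments: np.ndarray  # (n_segments, segment_length)
    window: float  # seconds
    stride: float | None  # seconds; None for beat/none modes
    offsets: np.ndarray  # start sample index per segment

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=np.float64))
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if self.segments.shape[0] != self.offsets.size:
            raise DataError("offsets must match segment count")
        if self.offsets.size > 1 and not np.all(np.diff(self.offsets) > 0):
            raise DataError("offsets must be strictly increasing")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def sliding_segments(rec: Recording, stride: float, window: float) -> SegmentSet:
    """Cut windows of ``window`` seconds every ``stride`` seconds.

    Trailing samples that cannot fill a whole window are discarded.  A
    recording shorter than one window yields a single right-zero-padded
    segment, so no record is ever dropped outright.
    """
    if window <= 0 or stride <= 0:
        raise ConfigError("window and stride must be > 0")
    if stride > window:
        raise ConfigError("stride must not exceed window")
    rate = rec.sampling_rate
    w = int(round(window * rate))
    s = int(round(stride * rate))
    x = rec.samples
    if x.size < w:
        seg = np.zeros((1, w))
        seg[0, : x.size] = x
        return SegmentSet(rec.record_id, seg, window, stride, np.array([0]))
    n = (x.size - w) // s + 1
    offsets = np.arange(n) * s
    segs = np.stack([x[o : o + w] for o in offsets])
    return SegmentSet(rec.record_id, segs, window, stride, offsets)


def fixed_segments(rec: Recording, window: float) -> SegmentSet:
    """Non-overlapping windows: sliding segmentation with stride == window."""
    return sliding_segments(rec, stride=window, window=window)


def no_segments(rec: Recording) -> SegmentSet:
    """The whole recording as a single segment."""
    return SegmentSet(
        rec.record_id, rec.samples[None, :], rec.duration, None, np.array([0])
    )


def beat_segments(rec: Recording, ann: StateAnnotation, target_len: int) -> SegmentSet:
    """One segment per complete S1-to-next-S1 heart cycle.

    Each cycle is linearly resampled to ``target_len`` samples so that
    variable-length beats batch together.  Incomplete leading/trailing cycles
    are dropped; an annotation without any complete cycle yields an empty set
    (with a warning) rather than an error.
    """
    if target_len < 2:
        raise ConfigError("target_len must be >= 2")
    check_alignment(rec, ann)
    onsets = ann.cycle_starts()
    if onsets.size < 2:
        warnings.warn(f"{rec.record_id}: no complete heart cycle in annotation")
        return SegmentSet(
            rec.record_id, np.zeros((0, target_len)), 0.0, None, np.zeros(0, dtype=int)
        )
    segs = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        cyc = rec.samples[a:b]
        pos = np.linspace(0, cyc.size - 1, target_len)
        segs.append(np.interp(pos, np.arange(cyc.size), cyc))
    return SegmentSet(
        rec.record_id,
        np.stack(segs),
        target_len / rec.sampling_rate,
        None,
        onsets[:-1],
    )


def aggregate_record(seg_probs: np.ndarray, method: str = "mean_prob") -> float:
    """Collapse per-segment abnormal-class probabilities to one record score.

    ``mean_prob`` averages the probabilities; ``majority`` returns the
    fraction of segments voting abnormal (probability > 0.5).
    """
    p = np.asarray(seg_probs, dtype=np.float64)
    if p.size == 0:
        raise DataError("cannot aggregate an empty segment set")
    if np.any((p < 0) | (p > 1)):
        raise DataError("probabilities must lie in [0, 1]")
    if method == "mean_prob":
        return float(np.mean(p))
    if method == "majority":
        return float(np.mean(p > 0.5))
    raise ConfigError(f"unknown aggregation method {method!r}")
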