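"""Shared containers and error types for the PCG pipeline.

A :class:`Recording` is a single labelled 1-D biosignal (heart sound audio or
single-lead ECG).  A :class:`StateAnnotation` assigns every sample of a PCG
recording to one of the four heart-cycle states S1, systole, S2, diastole,
coded 1..4 and cycling in that order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: state codes used by annotations, in cycle order
S1, SYSTOLE, S2, DIASTOLE = 1, 2, 3, 4
STATE_NAMES = {S1: "S1", SYSTOLE: "systole", S2: "S2", DIASTOLE: "diastole"}

PCG_LABELS = ("normal", "abnormal")
ECG_LABELS = ("normal", "af")


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariant."""


class SimulationError(RuntimeError):
    """Raised when a simulation request cannot be satisfied."""


class DataError(ValueError):
    """Raised for malformed or inconsistent data inputs."""


@dataclass
class Recording:
    """One labelled biosignal.

    Parameters
    ----------
    record_id : str
        Unique identifier.
    samples : ndarray
        Dimensionless amplitude sequence, length >= 1.
    sampling_rate : float
        Samples per second, > 0.
    label : str
        ``normal``/``abnormal`` for PCG, ``normal``/``af`` for ECG.
    modality : str
        ``pcg`` or ``ecg``.
    """

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    label: str
    modality: str = "pcg"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError(f"{self.record_id}: samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise DataError(f"{self.record_id}: sampling_rate must be > 0")
        if self.modality not in ("pcg", "ecg"):
            raise DataError(f"{self.record_id}: unknown modality {self.modality!r}")
        allowed = PCG_LABELS if self.modality == "pcg" else ECG_LABELS
        if self.label not in allowed:
            raise DataError(
                f"{self.record_id}: label {self.label!r} not in {allowed} for {self.modality}"
            )

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sampling_rate

    def replace_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        return Recording(
            record_id=self.record_id,
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            label=self.label,
            modality=self.modality,
        )


@dataclass
class StateAnnotation:
    """Per-sample heart-cycle state codes aligned to one recording."""

    record_id: str
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size < 1:
            raise DataError(f"{self.record_id}: states must be a non-empty 1-D array")
        bad = np.setdiff1d(np.unique(self.states), [S1, SYSTOLE, S2, DIASTOLE])
        if bad.size:
            raise DataError(f"{self.record_id}: invalid state codes {bad.tolist()}")

    def intervals(self) -> list[tuple[int, int, int]]:
        """Runs of constant state as ``(start, end, state)`` half-open pairs."""
        s = self.states
        edges = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [s.size]))
        return [(int(a), int(b), int(s[a])) for a, b in zip(starts, ends)]

    def cycle_starts(self) -> np.ndarray:
        """Sample indices where an S1 interval begins (cycle onsets)."""
        s = self.states
        onset = (s == S1) & np.concatenate(([True], s[:-1] != S1))
        return np.flatnonzero(onset)


def check_alignment(rec: Recording, ann: StateAnnotation) -> None:
    """Raise :class:`DataError` unless annotation covers the recording exactly."""
    if ann.states.size != rec.samples.size:
        raise DataError(
            f"{rec.record_id}: annotation length {ann.states.size} != "
            f"sample count {rec.samples.size}"
        )
    if ann.record_id != rec.record_id:
        raise DataError(f"annotation {ann.record_id!r} does not match recording {rec.record_id!r}")
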