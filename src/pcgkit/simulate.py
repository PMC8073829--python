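"""Seeded generator of synthetic heart-sound (PCG) and ECG recordings.

The generator emulates the statistical structure of public phonocardiogram
corpora so that every downstream stage (filtering, spike removal,
segmentation, feature extraction, model training) is testable offline:

* PCG recordings are periodic four-state heart cycles — S1, systole, S2,
  diastole — where S1/S2 are Gaussian-windowed band-limited noise bursts and
  the abnormal class carries a band-limited systolic murmur; white background
  noise is added at a configurable SNR.
* ECG recordings are per-beat template bumps (P, QRS, T as Gaussian
  components); the atrial-fibrillation class has irregular beat-to-beat
  intervals and no P bump.
* :func:`inject_spikes` adds short high-amplitude frictional transients used
  as fixtures for spike removal.

All randomness flows from one seeded generator per call; identical
``(config, seed)`` reproduce identical sample arrays bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .core import (
    DIASTOLE,
    S1,
    S2,
    SYSTOLE,
    ConfigError,
    Recording,
    SimulationError,
    StateAnnotation,
)

__all__ = [
    "SimConfig",
    "simulate_pcg",
    "simulate_ecg",
    "inject_spikes",
    "write_dataset",
    "read_dataset",
]

_MIN_STATE_DUR = 0.02  # s, floor for any drawn state duration
_MIN_DIASTOLE = 0.05  # s
_SPIKE_GAP = 0.5  # s, minimum spacing between injected spikes
_SPIKE_DUR = 0.010  # s, well under the 20 ms transient bound


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic PCG/ECG generator.

    Durations are seconds, rates Hz, SNRs decibels.  ``state_duration_means``
    gives the mean S1/systole/S2 durations; diastole takes the remainder of
    each heart cycle.  ``abnormality`` selects what distinguishes the
    abnormal PCG class: a systolic murmur (``"murmur"``, the default), an
    irregular rhythm with no murmur (``"timing"``), or a 50/50 mixture
    (``"mixed"``).  ``diastolic_murmur`` additionally places murmur noise in
    diastole for abnormal records.
    """

    sampling_rate: float = 1000.0
    duration_range: tuple[float, float] = (5.0, 120.0)
    heart_rate_mean: float = 75.0
    heart_rate_sd: float = 8.0
    state_duration_means: dict = field(
        default_factory=lambda: {"S1": 0.122, "systole": 0.30, "S2": 0.092}
    )
    state_duration_cv: float = 0.05
    s1_band: tuple[float, float] = (50.0, 150.0)
    s2_band: tuple[float, float] = (80.0, 200.0)
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_snr_db: float = 10.0
    murmur_cycle_fraction: float = 1.0
    murmur_position: str = "holo"  # holo | early | late (placement within systole)
    noise_snr_db: float = 20.0
    class_balance: float = 0.5
    abnormality: str = "murmur"
    diastolic_murmur: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ConfigError("duration_range must satisfy 0 < low <= high")
        if self.heart_rate_mean <= 0 or self.heart_rate_sd < 0:
            raise ConfigError("heart_rate_mean must be > 0 and heart_rate_sd >= 0")
        for key in ("S1", "systole", "S2"):
            if self.state_duration_means.get(key, 0) <= 0:
                raise ConfigError(f"state_duration_means[{key!r}] must be > 0")
        if not 0 <= self.state_duration_cv < 1:
            raise ConfigError("state_duration_cv must be in [0, 1)")
        nyq = self.sampling_rate / 2
        for name in ("s1_band", "s2_band", "murmur_band"):
            b = getattr(self, name)
            if not (0 < b[0] < b[1] < nyq):
                raise ConfigError(f"{name} must satisfy 0 < low < high < Nyquist")
        if not 0 <= self.class_balance <= 1:
            raise ConfigError("class_balance must be in [0, 1]")
        if not 0 < self.murmur_cycle_fraction <= 1:
            raise ConfigError("murmur_cycle_fraction must be in (0, 1]")
        if self.abnormality not in ("murmur", "timing", "mixed", "position"):
            raise ConfigError("abnormality must be 'murmur', 'timing', 'mixed' or 'position'")
        if self.murmur_position not in ("holo", "early", "late"):
            raise ConfigError("murmur_position must be 'holo', 'early' or 'late'")


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], rate: float) -> np.ndarray:
    """White noise shaped into ``band`` with a causal 2nd-order Butterworth."""
    if n <= 0:
        return np.zeros(0)
    x = rng.standard_normal(n)
    sos = sps.butter(2, band, btype="bandpass", fs=rate, output="sos")
    y = sps.sosfilt(sos, x)
    r = np.sqrt(np.mean(y**2))
    return y / r if r > 0 else y


def _gauss_window(n: int) -> np.ndarray:
    t = np.arange(n) - (n - 1) / 2
    sigma = max(n / 6.0, 1.0)
    return np.exp(-0.5 * (t / sigma) ** 2)


def _murmur_window(n: int, pos: str) -> np.ndarray:
    """Murmur placement within systole: whole interval, or an early/late burst."""
    if pos == "holo":
        return _gauss_window(n)
    centre = 0.25 * n if pos == "early" else 0.75 * n
    sigma = max(n / 8.0, 1.0)
    return np.exp(-0.5 * ((np.arange(n) - centre) / sigma) ** 2)


def _draw_cycle(rng: np.random.Generator, cfg: SimConfig, cycle_len: float) -> dict:
    cv = cfg.state_duration_cv
    durs = {}
    for key in ("S1", "systole", "S2"):
        mu = cfg.state_duration_means[key]
        durs[key] = max(rng.normal(mu, cv * mu), _MIN_STATE_DUR)
    durs["diastole"] = max(cycle_len - durs["S1"] - durs["systole"] - durs["S2"], _MIN_DIASTOLE)
    return durs


def _render_pcg(
    rng: np.random.Generator,
    cfg: SimConfig,
    duration: float,
    abnormal_kind: str | None,
    murmur_pos: str = "holo",
) -> tuple[np.ndarray, np.ndarray]:
    """Render one PCG waveform plus its per-sample state annotation.

    ``abnormal_kind`` is None (no murmur, regular rhythm), "murmur" or
    "timing"; ``murmur_pos`` places any murmur within systole.
    """
    rate = cfg.sampling_rate
    n_total = int(round(duration * rate))
    heart = np.zeros(n_total)
    murmur = np.zeros(n_total)
    states = np.zeros(n_total, dtype=np.int8)

    hr = float(np.clip(rng.normal(cfg.heart_rate_mean, cfg.heart_rate_sd), 40.0, 140.0))
    mean_cycle = 60.0 / hr
    cycle_cv = 0.25 if abnormal_kind == "timing" else cfg.state_duration_cv

    state_codes = {"S1": S1, "systole": SYSTOLE, "S2": S2, "diastole": DIASTOLE}
    pos = 0
    while pos < n_total:
        cycle_len = max(rng.normal(mean_cycle, cycle_cv * mean_cycle), 0.35)
        durs = _draw_cycle(rng, cfg, cycle_len)
        # intermittent murmurs (fraction < 1) defeat per-state summary
        # statistics while remaining visible to segment-level classifiers
        murmur_this_cycle = rng.random() < cfg.murmur_cycle_fraction
        for key in ("S1", "systole", "S2", "diastole"):
            n_state = int(round(durs[key] * rate))
            if n_state <= 0:
                n_state = 1
            a, b = pos, min(pos + n_state, n_total)
            if a >= n_total:
                break
            states[a:b] = state_codes[key]
            if key in ("S1", "S2"):
                amp = 1.0 if key == "S1" else 0.8
                band = cfg.s1_band if key == "S1" else cfg.s2_band
                burst = _band_noise(rng, n_state, band, rate)[: b - a]
                heart[a:b] += amp * _gauss_window(n_state)[: b - a] * burst
            elif abnormal_kind == "murmur" and murmur_this_cycle and (
                key == "systole" or (key == "diastole" and cfg.diastolic_murmur)
            ):
                mm = _band_noise(rng, n_state, cfg.murmur_band, rate)[: b - a]
                murmur[a:b] += _murmur_window(n_state, murmur_pos)[: b - a] * mm
            pos += n_state  # advances >= 1 sample per state, so the loop terminates

    heart_rms = np.sqrt(np.mean(heart**2))
    noise_rms = heart_rms * 10 ** (-cfg.noise_snr_db / 20)
    murmur_rms_target = noise_rms * 10 ** (cfg.murmur_snr_db / 20)
    m_rms = np.sqrt(np.mean(murmur[murmur != 0] ** 2)) if np.any(murmur != 0) else 0.0
    if m_rms > 0:
        murmur *= murmur_rms_target / m_rms
    x = heart + murmur + noise_rms * rng.standard_normal(n_total)
    return x, states


def simulate_pcg(config: SimConfig, n: int) -> list[tuple[Recording, StateAnnotation]]:
    """Generate ``n`` labelled PCG recordings with ground-truth annotations.

    Normal records contain S1/S2 bursts plus background noise; abnormal
    records additionally carry the configured abnormality (systolic murmur
    and/or irregular rhythm).  Deterministic under ``config.seed``.
    """
    config.validate()
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(n):
        label = "abnormal" if rng.random() < config.class_balance else "normal"
        pos = config.murmur_position
        if label == "abnormal":
            if config.abnormality == "mixed":
                kind = "murmur" if rng.random() < 0.5 else "timing"
            elif config.abnormality == "position":
                # pathological murmur: late-systolic (vs the innocent early one)
                kind, pos = "murmur", "late"
            else:
                kind = config.abnormality
        elif config.abnormality == "position":
            # "position" contrast: normals carry an innocent early-systolic
            # murmur of the same strength, so only the timing differs
            kind, pos = "murmur", "early"
        else:
            kind = None
        duration = rng.uniform(*config.duration_range)
        x, states = _render_pcg(rng, config, duration, kind, pos)
        rid = f"pcg{i:05d}"
        out.append(
            (
                Recording(rid, x, config.sampling_rate, label, "pcg"),
                StateAnnotation(rid, states),
            )
        )
    return out


def _render_ecg(
    rng: np.random.Generator, cfg: SimConfig, duration: float, af: bool
) -> tuple[np.ndarray, np.ndarray]:
    rate = cfg.sampling_rate
    n_total = int(round(duration * rate))
    t = np.arange(n_total) / rate
    x = np.zeros(n_total)

    mean_rr = 60.0 / cfg.heart_rate_mean
    rr_cv = 6 * cfg.state_duration_cv if af else cfg.state_duration_cv
    beats = []
    pos = mean_rr / 2
    while pos < duration:
        beats.append(pos)
        pos += max(rng.normal(mean_rr, rr_cv * mean_rr), 0.25)
    intervals = np.diff(beats)

    def bump(center: float, width: float, amp: float) -> None:
        lo = max(int((center - 4 * width) * rate), 0)
        hi = min(int((center + 4 * width) * rate), n_total)
        if hi > lo:
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / width) ** 2)

    for r in beats:
        if not af:
            bump(r - 0.16, 0.035, 0.15)  # P wave
        bump(r - 0.030, 0.015, -0.12)  # Q
        bump(r, 0.012, 1.0)  # R
        bump(r + 0.030, 0.015, -0.18)  # S
        bump(r + 0.30, 0.060, 0.30)  # T
    rms = np.sqrt(np.mean(x**2))
    noise_rms = rms * 10 ** (-cfg.noise_snr_db / 20)
    x = x + noise_rms * rng.standard_normal(n_total)
    return x, intervals


def simulate_ecg(
    config: SimConfig, n: int, return_intervals: bool = False
) -> list[Recording] | tuple[list[Recording], list[np.ndarray]]:
    """Generate ``n`` ECG-like recordings labelled ``normal`` or ``af``.

    AF records have irregular beat-to-beat intervals (interval CV six times
    the normal class's) and no P bump.  With ``return_intervals=True`` the
    generator's own beat-interval draws are returned alongside, so tests can
    compare interval variability without re-detecting beats.
    """
    config.validate()
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    recs, ivals = [], []
    for i in range(n):
        label = "af" if rng.random() < config.class_balance else "normal"
        duration = rng.uniform(*config.duration_range)
        x, intervals = _render_ecg(rng, config, duration, af=(label == "af"))
        recs.append(Recording(f"ecg{i:05d}", x, config.sampling_rate, label, "ecg"))
        ivals.append(intervals)
    if return_intervals:
        return recs, ivals
    return recs


def inject_spikes(
    rec: Recording, n_spikes: int, amplitude_factor: float, seed: int = 0
) -> Recording:
    """Copy of ``rec`` with short high-amplitude transients added.

    Spikes are 10 ms half-sine pulses of amplitude ``amplitude_factor`` times
    the recording's maximum absolute amplitude, placed at random positions at
    least 500 ms apart.  The input recording is untouched.
    """
    if n_spikes < 0:
        raise ConfigError("n_spikes must be >= 0")
    if amplitude_factor <= 0:
        raise ConfigError("amplitude_factor must be > 0")
    out = rec.replace_samples(rec.samples.copy())
    if n_spikes == 0:
        return out
    rate = rec.sampling_rate
    spike_len = max(int(round(_SPIKE_DUR * rate)), 1)
    gap = int(round(_SPIKE_GAP * rate))
    n_total = rec.samples.size
    span_needed = (n_spikes - 1) * gap + spike_len
    if span_needed > n_total:
        raise SimulationError(
            f"cannot place {n_spikes} spikes {_SPIKE_GAP} s apart in a "
            f"{rec.duration:.2f} s recording"
        )
    rng = np.random.default_rng(seed)
    slack = n_total - span_needed
    extras = np.sort(rng.uniform(0, slack, n_spikes))
    starts = (np.arange(n_spikes) * gap + extras).astype(int)
    maa = np.max(np.abs(rec.samples))
    pulse = np.sin(np.pi * np.arange(spike_len) / max(spike_len - 1, 1))
    for s in starts:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.samples[s : s + spike_len] += sign * amplitude_factor * maa * pulse
    return out


# ---------------------------------------------------------------------------
# dataset I/O: 16-bit PCM WAV + CSV manifest + CSV annotations
# ---------------------------------------------------------------------------

def write_dataset(
    records: list[Recording],
    out_dir: str | Path,
    annotations: list[StateAnnotation] | None = None,
) -> None:
    """Write recordings as 16-bit PCM WAV plus sidecar CSV manifests.

    Each waveform is peak-normalized to 0.95 full scale before quantization.
    Annotations (if given) are stored as half-open 0-based sample intervals
    ``(record_id, sample_index_start, state, sample_index_end)``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        peak = np.max(np.abs(rec.samples))
        scale = 0.95 / peak if peak > 0 else 1.0
        pcm = np.round(rec.samples * scale * 32767).astype(np.int16)
        wavfile.write(out / f"{rec.record_id}.wav", int(round(rec.sampling_rate)), pcm)
        rows.append(
            {
                "record_id": rec.record_id,
                "label": rec.label,
                "modality": rec.modality,
                "sampling_rate": rec.sampling_rate,
                "duration": rec.duration,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if annotations is not None:
        arows = []
        for ann in annotations:
            for a, b, st in ann.intervals():
                arows.append(
                    {
                        "record_id": ann.record_id,
                        "sample_index_start": a,
                        "state": st,
                        "sample_index_end": b,
                    }
                )
        pd.DataFrame(arows).to_csv(out / "annotations.csv", index=False)


def read_dataset(
    in_dir: str | Path,
) -> tuple[list[Recording], dict[str, StateAnnotation]]:
    """Read a dataset written by :func:`write_dataset`.

    Returns the recordings (float samples in [-1, 1]) and a possibly empty
    mapping of record_id to annotation.
    """
    ind = Path(in_dir)
    manifest = pd.read_csv(ind / "manifest.csv")
    recs = []
    for row in manifest.itertuples():
        rate, pcm = wavfile.read(ind / f"{row.record_id}.wav")
        recs.append(
            Recording(
                row.record_id,
                pcm.astype(np.float64) / 32767.0,
                float(rate),
                row.label,
                row.modality,
            )
        )
    anns: dict[str, StateAnnotation] = {}
    ann_path = ind / "annotations.csv"
    if ann_path.exists():
        table = pd.read_csv(ann_path)
        for rid, grp in table.groupby("record_id"):
            n = int(grp["sample_index_end"].max())
            states = np.zeros(n, dtype=np.int8)
            for r in grp.itertuples():
                states[r.sample_index_start : r.sample_index_end] = r.state
            anns[str(rid)] = StateAnnotation(str(rid), states)
    return recs, anns
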