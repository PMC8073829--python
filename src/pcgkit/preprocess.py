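"""PCG preprocessing: downsampling, 25-400 Hz band filtering, spike removal.

The band filter keeps the 25-400 Hz range where the clinically relevant
heart-sound energy lives, removing baseline drift and high-frequency noise.
It is applied zero-phase (forward-backward) so S1/S2 timing is preserved for
segmentation.

Spike removal is the classic windowed maximum-absolute-amplitude (MAA)
procedure: split the signal into 500 ms windows, and while any window's MAA
exceeds three times the median of all window MAAs, zero the offending spike
between the zero crossings bracketing its peak, then re-examine.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core import ConfigError, DataError, Recording

log = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "resample", "bandpass", "remove_spikes", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters (rates in Hz, windows in seconds)."""

    target_rate: float = 1000.0
    low_cut: float = 25.0
    high_cut: float = 400.0
    filter_order: int = 4
    spike_window: float = 0.5
    spike_threshold: float = 3.0
    max_spike_iterations: int = 100
    allow_upsample: bool = False

    def validate(self) -> None:
        if not 0 < self.low_cut < self.high_cut < self.target_rate / 2:
            raise ConfigError("need 0 < low_cut < high_cut < target_rate/2")
        if self.spike_window <= 0:
            raise ConfigError("spike_window must be > 0")
        if self.spike_threshold <= 1:
            raise ConfigError("spike_threshold must be > 1")
        if self.filter_order < 1 or self.max_spike_iterations < 1:
            raise ConfigError("filter_order and max_spike_iterations must be >= 1")


def resample(rec: Recording, target_rate: float, allow_upsample: bool = False) -> Recording:
    """Resample to ``target_rate`` with polyphase anti-aliasing filtering.

    Upsampling is refused by default: the pipeline only ever reduces rates,
    and silent upsampling usually signals a mis-configured target.
    """
    if target_rate <= 0:
        raise ConfigError("target_rate must be > 0")
    if target_rate == rec.sampling_rate:
        return rec.replace_samples(rec.samples.copy())
    if target_rate > rec.sampling_rate and not allow_upsample:
        raise DataError(
            f"{rec.record_id}: refusing to upsample {rec.sampling_rate} -> {target_rate} Hz "
            "(pass allow_upsample=True to override)"
        )
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10000)
    y = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return rec.replace_samples(y, sampling_rate=target_rate)


def _design_bandpass(cfg: PreprocessConfig, rate: float) -> np.ndarray:
    return sps.butter(
        cfg.filter_order, [cfg.low_cut, cfg.high_cut], btype="bandpass", fs=rate, output="sos"
    )


def bandpass(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase Butterworth band-pass keeping ``low_cut``-``high_cut`` Hz."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if rec.sampling_rate < 2 * cfg.high_cut:
        raise DataError(
            f"{rec.record_id}: sampling rate {rec.sampling_rate} Hz below Nyquist "
            f"requirement 2x{cfg.high_cut} Hz"
        )
    sos = _design_bandpass(cfg, rec.sampling_rate)
    y = sps.sosfiltfilt(sos, rec.samples)
    return rec.replace_samples(y)


def _window_maas(x: np.ndarray, win: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window maximum absolute amplitudes and window start indices.

    Windows are consecutive and non-overlapping; a final partial window is
    kept.
    """
    starts = np.arange(0, x.size, win)
    maas = np.array([np.max(np.abs(x[s : s + win])) for s in starts])
    return maas, starts

def _zero_crossings(x: np.ndarray) -> np.ndarray:
    """Indices i where the signal crosses zero between i-1 and i, or x[i]==0."""
    zero = x == 0
    flip = np.zeros_like(zero)
    flip[1:] = np.signbit(x[1:]) != np.signbit(x[:-1])
    return np.flatnonzero(zero | flip)


def remove_spikes(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Iteratively zero high-amplitude transients.

    Each iteration finds the 500 ms window whose MAA most exceeds three times
    the median window MAA, locates the MAA sample (the spike top), and zeroes
    from the last zero crossing strictly before the top to the first strictly
    after (falling back to the window edges when no crossing exists).  MAAs
    are recomputed after every zeroing.  Identity on spike-free inputs.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    x = rec.samples.copy()
    win = max(int(round(cfg.spike_window * rec.sampling_rate)), 1)
    n_zeroed = 0
    for iteration in range(cfg.max_spike_iterations):
        maas, starts = _window_maas(x, win)
        med = np.median(maas)
        if not np.any(maas > cfg.spike_threshold * med):
            if n_zeroed:
                log.info("%s: zeroed %d spike(s) in %d iteration(s)",
                         rec.record_id, n_zeroed, iteration)
            break
        w = int(np.argmax(maas))
        a = int(starts[w])
        b = min(a + win, x.size)
        seg = x[a:b]
        top = int(np.argmax(np.abs(seg)))
        zc = _zero_crossings(seg)
        before = zc[zc < top]
        after = zc[zc > top]
        start = int(before[-1]) if before.size else 0
        end = int(after[0]) if after.size else b - a - 1
        seg[start : end + 1] = 0.0
        n_zeroed += 1
    return rec.replace_samples(x)


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None, spike_removal: bool = True) -> Recording:
    """Full preprocessing chain: resample -> band-pass -> spike removal."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = rec
    if rec.sampling_rate > cfg.target_rate:
        out = resample(out, cfg.target_rate)
    out = bandpass(out, cfg)
    if spike_removal:
        out = remove_spikes(out, cfg)
    if not np.all(np.isfinite(out.samples)):
        raise DataError(f"{rec.record_id}: non-finite samples after preprocessing")
    return out
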