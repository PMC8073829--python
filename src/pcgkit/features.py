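"""Feature extraction for heart-sound classification.

Two families of representations are produced:

* **Envelope stacks** for the neural classifier: the preprocessed waveform
  plus three smooth envelopes — homomorphic (exp of a low-pass-filtered log
  magnitude), Hilbert (analytic-signal magnitude) and an autocorrelation-based
  power-spectral-density band envelope — decimated to a common low channel
  rate and standardized per channel.
* A **124-dimensional engineered vector** for classical baselines: 36 time
  domain features (state/cycle durations, duty ratios, per-state amplitudes),
  36 frequency domain features (median Hamming-windowed DFT band powers per
  state over 9 bands) and 52 MFCC summary features (13 coefficients x 4
  moments).

Everything in this module is deterministic: no operation consumes a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps
from scipy import stats as sstats

from .core import ConfigError, DataError, Recording, StateAnnotation, check_alignment
from .core import S1, S2, SYSTOLE, DIASTOLE

__all__ = [
    "EnvelopeConfig",
    "EnvelopeStack",
    "FeatureVector",
    "FEATURE_NAMES",
    "homomorphic_envelope",
    "hilbert_envelope",
    "ac_psd",
    "psd_envelope",
    "envelope_stack",
    "mfcc_features",
    "time_domain_features",
    "freq_domain_features",
    "engineered_vector",
]

_EPS = 1e-12

#: frequency bands (Hz) for the per-state spectral features; they tile the
#: 25-400 Hz passband
FREQ_BANDS = (
    (25, 45), (45, 65), (65, 85), (85, 105), (105, 125),
    (125, 150), (150, 200), (200, 300), (300, 400),
)

_STATE_ORDER = ((S1, "s1"), (SYSTOLE, "systole"), (S2, "s2"), (DIASTOLE, "diastole"))


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def hilbert_envelope(x: np.ndarray, rate: float | None = None) -> np.ndarray:
    """Magnitude of the analytic signal ``x + j H[x]``.

    The Hilbert transform is computed with the standard ``-j sgn(omega)``
    frequency-domain multiplier.  Output is non-negative, same length as the
    input, and bounds ``|x|`` from above pointwise.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DataError("empty input")
    return np.abs(sps.hilbert(x))


def homomorphic_envelope(x: np.ndarray, rate: float, lpf_cutoff: float = 8.0) -> np.ndarray:
    """Homomorphic envelope: ``exp(lowpass(log(|analytic(x)| + eps)))``.

    The log converts the multiplicative envelope/carrier structure of the
    heart sound into an additive one, a first-order zero-phase low-pass at
    ``lpf_cutoff`` keeps the slow envelope, and the exponential maps back.
    Strictly positive, length-preserving.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DataError("empty input")
    if not lpf_cutoff < rate / 2:
        raise ConfigError("lpf_cutoff must be below Nyquist")
    mag = np.abs(sps.hilbert(x))
    logmag = np.log(mag + _EPS)
    sos = sps.butter(1, lpf_cutoff, btype="lowpass", fs=rate, output="sos")
    smooth = sps.sosfiltfilt(sos, logmag)
    return np.exp(smooth)


def ac_psd(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Autocorrelation-method power spectral density of one frame.

    Computes the biased autocorrelation estimate r(m) = (1/N) sum_n x[n]
    x[n+m] for |m| <= M (default M = N-1) and returns its discrete-time
    Fourier transform sampled at L = 2M+1 uniform frequencies, i.e.
    ``psd[k] = sum_{m=-M}^{M} r(m) exp(-j 2 pi k m / L)``.  At full lag this
    equals the periodogram ``|X(omega)|^2 / N`` on the same grid
    (Wiener-Khinchin).  Frequencies are ``k / L`` cycles per sample.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 1:
        raise DataError("empty frame")
    m = n - 1 if max_lag is None else int(max_lag)
    if not 0 <= m <= n - 1:
        raise ConfigError("max_lag must be in [0, N-1]")
    r_full = np.correlate(x, x, mode="full") / n  # lags -(N-1) .. N-1
    c = r_full[n - 1 - m : n + m]  # lags -M .. M
    seq = np.concatenate([c[m:], c[:m]])  # lags 0..M, -M..-1
    return np.fft.fft(seq).real


def psd_envelope(
    x: np.ndarray,
    rate: float,
    frame: float = 0.05,
    overlap: float = 0.5,
    band: tuple[float, float] = (40.0, 60.0),
) -> np.ndarray:
    """Band-limited PSD envelope via the autocorrelation (indirect) method.

    The signal is cut into overlapping frames; each frame's AC-method PSD is
    averaged over ``band`` to give one envelope value per frame, and the
    frame-rate sequence is linearly interpolated back to the input length.
    """
    x = np.asarray(x, dtype=np.float64)
    nf = int(round(frame * rate))
    if nf < 8:
        raise ConfigError("frame must contain at least 8 samples")
    if not 0 <= overlap < 1:
        raise ConfigError("overlap must be in [0, 1)")
    if not 0 <= band[0] < band[1] <= rate / 2:
        raise ConfigError("band must lie within (0, Nyquist)")
    hop = max(int(round(nf * (1 - overlap))), 1)
    if x.size < nf:
        pad = np.zeros(nf)
        pad[: x.size] = x
        x_frames, centers = pad[None, :], np.array([x.size / 2])
    else:
        starts = np.arange(0, x.size - nf + 1, hop)
        x_frames = np.stack([x[s : s + nf] for s in starts])
        centers = starts + nf / 2
    L = 2 * nf - 1
    freqs = np.arange(L) / L * rate
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):  # band narrower than the frequency resolution
        sel = np.array([np.argmin(np.abs(freqs[: L // 2 + 1] - np.mean(band)))])
    vals = np.array([np.mean(ac_psd(f)[sel]) for f in x_frames])
    vals = np.maximum(vals, 0.0)  # finite-precision guard; PSD is non-negative
    return np.interp(np.arange(x.size), centers, vals)


@dataclass(frozen=True)
class EnvelopeConfig:
    """Parameters of the 4-channel envelope stack."""

    channel_rate: float = 50.0
    homomorphic_lpf: float = 8.0
    psd_frame: float = 0.05
    psd_overlap: float = 0.5
    psd_band: tuple[float, float] = (40.0, 60.0)

    def validate(self) -> None:
        if self.channel_rate <= 0:
            raise ConfigError("channel_rate must be > 0")
        if self.homomorphic_lpf <= 0:
            raise ConfigError("homomorphic_lpf must be > 0")
        if self.psd_frame <= 0:
            raise ConfigError("psd_frame must be > 0")


@dataclass
class EnvelopeStack:
    """Fixed-rate multi-channel input for the neural classifier.

    Channels are ordered (raw, homomorphic, hilbert, psd), share one length,
    and are standardized to zero mean / unit variance (constant channels map
    to zeros).
    """

    record_id: str
    channels: np.ndarray  # (4, length)
    channel_rate: float
    offset: int = 0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise DataError("channels must be a (4, length) array")

    @property
    def length(self) -> int:
        return self.channels.shape[1]


def _standardize(ch: np.ndarray) -> np.ndarray:
    mean = np.mean(ch)
    sd = np.std(ch)
    if sd <= 1e-9 * (abs(mean) + 1.0):  # constant channel -> zeros
        return np.zeros_like(ch)
    return (ch - mean) / sd


def _decimate(x: np.ndarray, rate: float, target: float) -> np.ndarray:
    from fractions import Fraction

    if rate == target:
        return x.copy()
    frac = Fraction(target / rate).limit_denominator(10000)
    # line padding keeps constant/slowly-varying channels free of edge ringing
    return sps.resample_poly(x, frac.numerator, frac.denominator, padtype="line")


def envelope_stack(
    x: np.ndarray,
    rate: float,
    cfg: EnvelopeConfig | None = None,
    record_id: str = "",
    offset: int = 0,
) -> EnvelopeStack:
    """Raw + homomorphic + Hilbert + PSD channels at the common channel rate."""
    cfg = cfg or EnvelopeConfig()
    cfg.validate()
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DataError("empty input")
    homo = homomorphic_envelope(x, rate, cfg.homomorphic_lpf)
    hil = hilbert_envelope(x)
    psd = psd_envelope(x, rate, cfg.psd_frame, cfg.psd_overlap, cfg.psd_band)
    chans = []
    for ch, is_env in ((x, False), (homo, True), (hil, True), (psd, True)):
        d = _decimate(ch, rate, cfg.channel_rate)
        if is_env:
            d = np.maximum(d, 0.0)  # decimation ringing must not break non-negativity
        chans.append(d)
    n = min(c.size for c in chans)
    stack = np.stack([_standardize(c[:n]) for c in chans])
    return EnvelopeStack(record_id, stack, cfg.channel_rate, offset)


# ---------------------------------------------------------------------------
# engineered features
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, rate: float) -> np.ndarray:
    pts = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2), n_filters + 2))
    bins = np.floor((nfft + 1) * pts / rate).astype(int)
    n_bins = nfft // 2 + 1
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        b = max(b, a + 1)  # degenerate-filter guard at coarse FFT resolution
        c = max(c, b + 1)
        left = np.arange(a, min(b, n_bins))
        fb[i, left] = (left - a) / (b - a)
        right = np.arange(b, min(c, n_bins))
        fb[i, right] = (c - right) / (c - b)
    return fb


def _moment_stats(frames: np.ndarray) -> np.ndarray:
    """Per-column mean, SD, skewness, kurtosis with zero-variance guards."""
    import warnings as _warnings

    mean = frames.mean(axis=0)
    sd = frames.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        skew = sstats.skew(frames, axis=0)
        kurt = sstats.kurtosis(frames, axis=0)
    skew = np.where(sd > 0, skew, 0.0)
    kurt = np.where(sd > 0, kurt, 0.0)
    return np.concatenate([mean, sd, skew, kurt])


def mfcc_features(
    x: np.ndarray,
    rate: float,
    n_coeff: int = 13,
    n_filters: int = 26,
    frame: float = 0.025,
    hop: float = 0.010,
) -> np.ndarray:
    """52 MFCC summary features: 13 coefficients x (mean, SD, skew, kurtosis).

    MFCCs use Hamming-windowed 25 ms frames with a 10 ms hop, a 26-filter mel
    bank and an orthonormal DCT-II; the four moments are taken over frames.
    """
    x = np.asarray(x, dtype=np.float64)
    nf = int(round(frame * rate))
    nh = max(int(round(hop * rate)), 1)
    if x.size < nf:
        raise DataError(f"input shorter than one {frame*1e3:.0f} ms analysis frame")
    nfft = int(2 ** np.ceil(np.log2(max(nf, 256))))
    win = np.hamming(nf)
    fb = _mel_filterbank(n_filters, nfft, rate)
    starts = np.arange(0, x.size - nf + 1, nh)
    frames = np.stack([x[s : s + nf] for s in starts]) * win
    spec = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2
    mel = np.log(spec @ fb.T + _EPS)
    coeffs = sfft.dct(mel, type=2, norm="ortho", axis=1)[:, :n_coeff]
    return _moment_stats(coeffs)


def _cycles(ann: StateAnnotation) -> list[list[tuple[int, int, int]]]:
    """Complete cycles as lists of (start, end, state) runs."""
    onsets = ann.cycle_starts()
    runs = ann.intervals()
    cycles = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        cyc = [(max(s, a), min(e, b), st) for s, e, st in runs if s < b and e > a]
        cycles.append(cyc)
    return cycles


def _require_cycles(ann: StateAnnotation) -> list:
    cycles = _cycles(ann)
    if len(cycles) < 2:
        raise DataError(
            f"{ann.record_id}: need at least 2 complete heart cycles, found {len(cycles)}"
        )
    return cycles


def _mean_sd(v: np.ndarray) -> tuple[float, float]:
    return float(np.mean(v)), float(np.std(v, ddof=1))


def time_domain_features(rec: Recording, ann: StateAnnotation) -> np.ndarray:
    """36 time-domain features over complete heart cycles.

    10 duration statistics (mean+SD of cycle and the four state durations),
    10 duty-ratio statistics, 12 amplitude statistics (per-state mean
    absolute amplitude and S1/systole, S2/diastole ratios), and 4
    whole-signal statistics (skewness, kurtosis, zero-crossing rate, RMS).
    """
    check_alignment(rec, ann)
    cycles = _require_cycles(ann)
    rate = rec.sampling_rate
    x = rec.samples

    dur = {name: [] for _, name in _STATE_ORDER}
    amp = {name: [] for _, name in _STATE_ORDER}
    cyc_dur = []
    for cyc in cycles:
        cyc_dur.append((cyc[-1][1] - cyc[0][0]) / rate)
        for code, name in _STATE_ORDER:
            n_samp = sum(e - s for s, e, st in cyc if st == code)
            dur[name].append(n_samp / rate)
            vals = np.concatenate([np.abs(x[s:e]) for s, e, st in cyc if st == code] or [np.zeros(1)])
            amp[name].append(float(np.mean(vals)))

    cyc_dur = np.array(cyc_dur)
    feats: list[float] = list(_mean_sd(cyc_dur))
    for _, name in _STATE_ORDER:
        feats.extend(_mean_sd(np.array(dur[name])))
    for _, name in _STATE_ORDER:
        feats.extend(_mean_sd(np.array(dur[name]) / cyc_dur))
    sys_d, dia_d = np.array(dur["systole"]), np.array(dur["diastole"])
    feats.extend(_mean_sd(sys_d / np.maximum(dia_d, _EPS)))
    for _, name in _STATE_ORDER:
        feats.extend(_mean_sd(np.array(amp[name])))
    a_s1, a_sys = np.array(amp["s1"]), np.array(amp["systole"])
    a_s2, a_dia = np.array(amp["s2"]), np.array(amp["diastole"])
    feats.extend(_mean_sd(a_s1 / np.maximum(a_sys, _EPS)))
    feats.extend(_mean_sd(a_s2 / np.maximum(a_dia, _EPS)))

    sd = np.std(x)
    feats.append(float(sstats.skew(x)) if sd > 0 else 0.0)
    feats.append(float(sstats.kurtosis(x)) if sd > 0 else 0.0)
    feats.append(float(np.mean(np.signbit(x[1:]) != np.signbit(x[:-1]))))  # zero-crossing rate
    feats.append(float(np.sqrt(np.mean(x**2))))
    return np.array(feats)


def freq_domain_features(rec: Recording, ann: StateAnnotation) -> np.ndarray:
    """36 frequency-domain features: per state, the median over occurrences of
    Hamming-windowed DFT mean band power in 9 bands tiling 25-400 Hz."""
    check_alignment(rec, ann)
    _require_cycles(ann)
    rate = rec.sampling_rate
    x = rec.samples
    occs: dict[int, list[np.ndarray]] = {code: [] for code, _ in _STATE_ORDER}
    for s, e, st in ann.intervals():
        if st in occs and e - s >= 4:
            occs[st].append(x[s:e])
    feats = []
    for code, _name in _STATE_ORDER:
        if not occs[code]:
            raise DataError(f"{rec.record_id}: no occurrences of state {code}")
        powers = np.zeros((len(occs[code]), len(FREQ_BANDS)))
        for i, seg in enumerate(occs[code]):
            w = np.hamming(seg.size)
            nfft = max(512, sfft.next_fast_len(seg.size))
            spec = np.abs(np.fft.rfft(seg * w, nfft)) ** 2
            freqs = np.fft.rfftfreq(nfft, 1 / rate)
            for j, (lo, hi) in enumerate(FREQ_BANDS):
                sel = (freqs >= lo) & (freqs < hi)
                powers[i, j] = np.mean(spec[sel]) if np.any(sel) else 0.0
        feats.extend(np.median(powers, axis=0))
    return np.array(feats)


def _feature_names() -> list[str]:
    names = []
    for part in ["cycle"] + [n for _, n in _STATE_ORDER]:
        names += [f"dur_{part}_mean", f"dur_{part}_sd"]
    for part in [n for _, n in _STATE_ORDER] + ["systole_over_diastole"]:
        names += [f"duty_{part}_mean", f"duty_{part}_sd"]
    for part in [n for _, n in _STATE_ORDER]:
        names += [f"amp_{part}_mean", f"amp_{part}_sd"]
    for part in ["s1_over_systole", "s2_over_diastole"]:
        names += [f"ampratio_{part}_mean", f"ampratio_{part}_sd"]
    names += ["signal_skewness", "signal_kurtosis", "signal_zcr", "signal_rms"]
    for _, state in _STATE_ORDER:
        for lo, hi in FREQ_BANDS:
            names.append(f"power_{state}_{lo}_{hi}hz")
    for stat in ["mean", "sd", "skew", "kurt"]:
        for c in range(13):
            names.append(f"mfcc{c}_{stat}")
    return names


#: canonical ordered names of the 124 engineered features
FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())


@dataclass
class FeatureVector:
    """The 124-dimensional engineered vector [time(36) | frequency(36) | mfcc(52)]."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise DataError(f"expected {len(self.names)} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature values must be finite")


def engineered_vector(rec: Recording, ann: StateAnnotation) -> FeatureVector:
    """Concatenated [time | frequency | MFCC] engineered features."""
    t = time_domain_features(rec, ann)
    f = freq_domain_features(rec, ann)
    m = mfcc_features(rec.samples, rec.sampling_rate)
    return FeatureVector(np.concatenate([t, f, m]))
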