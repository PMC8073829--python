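"""Envelope and engineered-feature contracts, incl. the Wiener-Khinchin oracle."""
import numpy as np
import pytest
from scipy.signal import hilbert as scipy_hilbert

from pcgkit import ConfigError, DataError, Recording, SimConfig, simulate_pcg
from pcgkit.features import (
    FEATURE_NAMES,
    EnvelopeConfig,
    ac_psd,
    engineered_vector,
    envelope_stack,
    freq_domain_features,
    hilbert_envelope,
    homomorphic_envelope,
    mfcc_features,
    psd_envelope,
    time_domain_features,
)
from pcgkit.preprocess import bandpass


class TestHilbert:
    def test_transform_identity_cos_to_sin(self):
        t = np.arange(2000) / 1000.0
        x = np.cos(2 * np.pi * 50 * t)
        h = np.imag(scipy_hilbert(x))
        assert np.max(np.abs(h[100:-100] - np.sin(2 * np.pi * 50 * t)[100:-100])) < 0.01

    def test_unit_tone_envelope(self):
        t = np.arange(2000) / 1000.0
        env = hilbert_envelope(np.cos(2 * np.pi * 50 * t))
        assert np.max(np.abs(env[100:-100] - 1.0)) < 0.01

    def test_impulse_peak_location(self):
        x = np.zeros(1001)
        x[500] = 1.0
        assert np.argmax(hilbert_envelope(x)) == 500

    def test_analytic_magnitude_bounds_signal(self):
        rng = np.random.default_rng(3)
        x = bandpass(Recording("n", rng.standard_normal(4000), 1000.0, "normal")).samples
        assert np.all(hilbert_envelope(x) >= np.abs(x) - 1e-9)


class TestHomomorphic:
    def test_constant_envelope_tone(self):
        t = np.arange(2000) / 1000.0
        env = homomorphic_envelope(2 * np.cos(2 * np.pi * 100 * t), 1000.0)
        core = env[250:-250]
        assert np.all(np.abs(core - 2.0) < 0.1)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(3000)
        e1 = homomorphic_envelope(x, 1000.0)
        e3 = homomorphic_envelope(3 * x, 1000.0)
        core = slice(250, -250)
        assert np.max(np.abs(e3[core] / e1[core] - 3.0)) < 0.03

    def test_burst_peak_near_centre(self):
        t = np.arange(2000) / 1000.0
        centre = 1.0
        burst = np.exp(-0.5 * ((t - centre) / 0.05) ** 2) * np.sin(2 * np.pi * 120 * t)
        env = homomorphic_envelope(burst, 1000.0)
        assert abs(np.argmax(env) / 1000.0 - centre) <= 0.010

    def test_all_zero_input_guarded(self):
        env = homomorphic_envelope(np.zeros(500), 1000.0)
        assert np.all(env > 0) and np.all(env < 1e-9)


class TestAcPsd:
    def test_wiener_khinchin_equals_periodogram(self):
        """AC-method PSD at full lag == |X|^2/N on the 2N-1 frequency grid."""
        rng = np.random.default_rng(1)
        for n in (32, 50, 101):
            x = rng.standard_normal(n)
            psd = ac_psd(x)
            periodogram = np.abs(np.fft.fft(x, 2 * n - 1)) ** 2 / n
            rel = np.max(np.abs(psd - periodogram)) / np.max(periodogram)
            assert rel < 1e-6

    def test_band_concentration_of_pure_tone(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        inband = psd_envelope(x, 1000.0, band=(40, 60))
        outband = psd_envelope(x, 1000.0, band=(200, 300))
        assert np.mean(inband) >= 100 * np.mean(outband)

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(psd_envelope(np.zeros(1000), 1000.0), 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            psd_envelope(np.ones(1000), 1000.0, band=(400, 600))


class TestEnvelopeStack:
    def test_shapes_and_rate(self):
        rng = np.random.default_rng(2)
        st = envelope_stack(rng.standard_normal(2000), 1000.0)
        assert st.channels.shape == (4, 100)
        assert st.channel_rate == 50.0

    def test_constant_input_standardizes_to_zero(self):
        st = envelope_stack(np.ones(2000), 1000.0)
        assert np.allclose(st.channels[0], 0.0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        a = envelope_stack(x, 1000.0).channels
        b = envelope_stack(x, 1000.0).channels
        assert np.array_equal(a, b)

    def test_drift_invariance_after_highpass(self):
        """A 5 Hz, 0.5-amplitude drift dies in the 25 Hz high-pass, so the
        envelope stack of the preprocessed signal is essentially unchanged."""
        rng = np.random.default_rng(5)
        t = np.arange(4000) / 1000.0
        base = rng.standard_normal(4000)
        drift = 0.5 * np.sin(2 * np.pi * 5 * t)
        clean = bandpass(Recording("a", base, 1000.0, "normal")).samples
        drifted = bandpass(Recording("b", base + drift, 1000.0, "normal")).samples
        sa = envelope_stack(clean, 1000.0).channels
        sb = envelope_stack(drifted, 1000.0).channels
        assert np.max(np.abs(sa - sb)) < 0.05


class TestMfcc:
    def test_length_52(self):
        rng = np.random.default_rng(0)
        assert mfcc_features(rng.standard_normal(2000), 1000.0).shape == (52,)

    def test_frame_constant_signal_zero_sd(self):
        x = np.tile(np.sin(2 * np.pi * np.arange(10) / 10), 500)  # 10 ms periodic
        feats = mfcc_features(x, 1000.0)
        sds = feats[13:26]
        assert np.max(np.abs(sds)) < 1e-9

    def test_whole_frame_shift_preserves_means(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(3000)
        m1 = mfcc_features(x, 1000.0)[:13]
        m2 = mfcc_features(np.roll(x, 250), 1000.0)[:13]  # 10 whole hops
        # means over frame statistics are order-invariant; rolled content differs
        # only at the two boundary frames out of ~298
        assert np.max(np.abs(m1 - m2)) < 0.2

    def test_too_short_errors(self):
        with pytest.raises(DataError):
            mfcc_features(np.ones(10), 1000.0)


@pytest.fixture(scope="module")
def constant_timing_pair():
    cfg = SimConfig(seed=12, duration_range=(10.0, 10.0), state_duration_cv=0.0, heart_rate_sd=0.0)
    return simulate_pcg(cfg, 1)[0]


class TestTimeDomain:
    def test_length_and_finite(self, pcg_small):
        rec, ann = pcg_small[0]
        v = time_domain_features(rec, ann)
        assert v.shape == (36,)
        assert np.all(np.isfinite(v))

    def test_constant_durations_recovered(self, constant_timing_pair):
        rec, ann = constant_timing_pair
        v = dict(zip(FEATURE_NAMES, time_domain_features(rec, ann)))
        for state, mean in (("s1", 0.122), ("systole", 0.30), ("s2", 0.092)):
            assert abs(v[f"dur_{state}_mean"] - mean) <= 0.002  # one sample + rounding
            assert v[f"dur_{state}_sd"] <= 0.002
        assert v["dur_cycle_sd"] <= 0.002

    def test_amplitude_scaling(self, pcg_small):
        rec, ann = pcg_small[0]
        v1 = time_domain_features(rec, ann)
        v2 = time_domain_features(rec.replace_samples(2 * rec.samples), ann)
        names = FEATURE_NAMES
        for i, name in enumerate(names[:36]):
            if name.startswith("amp_") or name == "signal_rms":
                assert v2[i] == pytest.approx(2 * v1[i], rel=1e-9)
            elif name.startswith(("ampratio_", "duty_", "dur_")) or name in (
                "signal_skewness", "signal_kurtosis", "signal_zcr",
            ):
                assert v2[i] == pytest.approx(v1[i], abs=1e-9)

    def test_too_few_cycles_errors(self):
        from pcgkit import StateAnnotation

        rec = Recording("x", np.ones(1000), 1000.0, "normal")
        ann = StateAnnotation("x", np.r_[np.full(500, 1), np.full(500, 2)].astype(np.int8))
        with pytest.raises(DataError):
            time_domain_features(rec, ann)


class TestFreqDomain:
    def test_length(self, pcg_small):
        rec, ann = pcg_small[0]
        assert freq_domain_features(rec, ann).shape == (36,)

    def test_zero_signal_all_zero(self, pcg_small):
        rec, ann = pcg_small[0]
        z = freq_domain_features(rec.replace_samples(np.zeros_like(rec.samples)), ann)
        assert np.allclose(z, 0.0)

    def test_murmur_band_contrast(self):
        """Abnormal systole carries more 150-400 Hz power than normal, on average."""
        cfg_a = SimConfig(seed=21, duration_range=(6.0, 8.0), murmur_snr_db=20.0, class_balance=1.0)
        cfg_n = SimConfig(seed=22, duration_range=(6.0, 8.0), class_balance=0.0)
        ab = simulate_pcg(cfg_a, 50)
        nm = simulate_pcg(cfg_n, 50)
        idx = [FEATURE_NAMES.index(f"power_systole_{lo}_{hi}hz") for lo, hi in
               ((150, 200), (200, 300), (300, 400))]
        hi_power = lambda pair: freq_domain_features(*pair)[np.array(idx) - 36].sum()
        assert np.mean([hi_power(p) for p in ab]) > np.mean([hi_power(p) for p in nm])


class TestEngineeredVector:
    def test_length_and_names(self, pcg_small):
        rec, ann = pcg_small[0]
        v = engineered_vector(rec, ann)
        assert v.values.shape == (124,)
        assert v.names == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 124

    def test_finite_across_smoke_set(self, pcg_small):
        for rec, ann in pcg_small:
            assert np.all(np.isfinite(engineered_vector(rec, ann).values))
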