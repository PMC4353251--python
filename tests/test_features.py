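"""Feature extraction: periodogram, band powers, detectors, rolling features,
and the 37-column assembly contract."""

import copy

import numpy as np
import pytest

from pbci import synthgen
from pbci.features import (
    DEFAULT_BANDS,
    EEG_FEATURES,
    FEATURE_NAMES,
    LOG_POWER_FLOOR,
    PERIPHERAL_FEATURES,
    BandDefinition,
    FeatureFrame,
    assemble_features,
    band_power,
    blink_rate_feature,
    detect_blinks,
    detect_rwaves,
    ibi_feature,
    periodogram_1s,
    rolling_log_band_features,
)

FS = 200.0


class TestPeriodogram:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(200) / FS
        freqs, psd = periodogram_1s(np.sin(2 * np.pi * 10 * t))
        assert freqs[np.argmax(psd)] == 10.0

    def test_zero_window_gives_zero_psd(self):
        _, psd = periodogram_1s(np.zeros(200))
        np.testing.assert_array_equal(psd, 0.0)

    def test_parseval_against_time_domain_power(self):
        """Integrated PSD equals the window-compensated time-domain power."""
        from scipy.signal import get_window

        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        freqs, psd = periodogram_1s(x)
        w = get_window("hann", 200)
        time_power = np.sum((w * x) ** 2) / np.sum(w**2)
        assert np.sum(psd) * (freqs[1] - freqs[0]) == pytest.approx(
            time_power, rel=1e-6
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            periodogram_1s(np.zeros(100))


class TestBandPower:
    def test_sinusoid_concentrates_in_its_band(self):
        t = np.arange(200) / FS
        freqs, psd = periodogram_1s(np.sin(2 * np.pi * 10 * t))
        powers = {b.name: band_power(freqs, psd, b) for b in DEFAULT_BANDS}
        for name, p in powers.items():
            if name != "alpha":
                assert powers["alpha"] > 100 * p

    def test_zero_signal_zero_everywhere(self):
        freqs, psd = periodogram_1s(np.zeros(200))
        for b in DEFAULT_BANDS:
            assert band_power(freqs, psd, b) == 0.0

    def test_disjoint_bands_additive(self):
        rng = np.random.default_rng(1)
        freqs, psd = periodogram_1s(rng.standard_normal(200))
        lo = BandDefinition("lo", 4.0, 7.0)
        hi = BandDefinition("hi", 8.0, 12.0)
        both = BandDefinition("both", 4.0, 12.0)
        assert band_power(freqs, psd, lo) + band_power(freqs, psd, hi) == pytest.approx(
            band_power(freqs, psd, both)
        )

    def test_empty_band_rejected(self):
        freqs, psd = periodogram_1s(np.zeros(200))
        with pytest.raises(ValueError):
            band_power(freqs, psd, BandDefinition("sub", 0.1, 0.4))


class TestRollingLogBandFeatures:
    def test_one_row_per_second(self):
        rng = np.random.default_rng(0)
        for dur in (30, 61, 120):
            x = rng.standard_normal(int(dur * FS))
            assert rolling_log_band_features(x).shape == (dur, len(DEFAULT_BANDS))

    def test_stationary_signal_recovers_constant_power(self):
        """Averaged estimates match the single-window oracle mean, with the
        10-window mean variance shrunk well below single-window variance."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(300 * FS))
        out = rolling_log_band_features(x)
        from pbci.features import _second_band_powers

        raw = _second_band_powers(x, DEFAULT_BANDS, FS)
        # log10 of the true mean power (log of single windows is Jensen-biased)
        assert np.allclose(out[10:].mean(axis=0), np.log10(raw.mean(axis=0)), atol=0.05)
        singles = np.log10(np.maximum(raw, LOG_POWER_FLOOR))
        assert (out[10:].var(axis=0) < 0.5 * singles.var(axis=0)).all()

    def test_all_zero_channel_hits_floor(self):
        out = rolling_log_band_features(np.zeros(int(30 * FS)))
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out, np.log10(LOG_POWER_FLOOR))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rolling_log_band_features(np.zeros(int(5 * FS)))


class TestBlinkDetection:
    def test_flat_signal_no_blinks(self):
        assert len(detect_blinks(np.zeros(12000))) == 0

    def test_injected_blinks_recovered_at_apex(self):
        rng = np.random.default_rng(2)
        n = int(60 * FS)
        v = 4 * rng.standard_normal(n)
        tmpl = synthgen.blink_template(FS)
        apex_offset = np.argmax(tmpl) / FS
        true_times = np.arange(1.0, 58.0, 3.0)
        for t in true_times:
            i = int(round(t * FS))
            v[i : i + len(tmpl)] += 250 * tmpl
        det = detect_blinks(v)
        assert len(det) == len(true_times)
        for t in true_times:
            assert np.min(np.abs(det - (t + apex_offset))) < 0.05

    def test_saccade_steps_not_detected_as_blinks(self):
        rng = np.random.default_rng(3)
        n = int(60 * FS)
        h = 4 * rng.standard_normal(n)
        step = synthgen._saccade_template(FS)
        for k, t in enumerate(np.arange(2.0, 55.0, 5.0)):
            i = int(round(t * FS))
            j = min(i + len(step), n)
            h[i:j] += (1 if k % 2 == 0 else -1) * 60 * step[: j - i]
        assert len(detect_blinks(h)) == 0


class TestBlinkRate:
    def test_steady_rate_recovered(self):
        times = np.arange(0.0, 120.0, 3.0)  # 20/min
        rate = blink_rate_feature(times, 120.0)
        assert np.allclose(rate[30:], 20.0)

    def test_zero_blinks_zero_rate(self):
        np.testing.assert_array_equal(blink_rate_feature(np.empty(0), 60.0), 0.0)

    def test_single_blink_trailing_window(self):
        """One blink at t=5 s counts for output seconds 5..34 and no others."""
        rate = blink_rate_feature(np.array([5.0]), 60.0)
        expected = np.zeros(60)
        expected[5:35] = 2.0
        np.testing.assert_array_equal(rate, expected)


class TestRWaveDetection:
    @staticmethod
    def _ecg(spacings_s, duration_s, noise_sd=10.0, amp=1000.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration_s * FS)
        ecg = noise_sd * rng.standard_normal(n)
        tmpl = synthgen.qrs_template(FS)
        apex = np.argmax(tmpl) / FS
        times, t = [], 0.05
        k = 0
        while t < duration_s - 0.2:
            a = amp(t) if callable(amp) else amp
            i = int(round(t * FS))
            j = min(i + len(tmpl), n)
            ecg[i:j] += a * tmpl[: j - i]
            times.append(t + apex)
            t += spacings_s[k % len(spacings_s)]
            k += 1
        return ecg, np.asarray(times)

    def test_constant_spacing_count_and_timing(self):
        ecg, true_times = self._ecg([0.8], 60.0)
        det = detect_rwaves(ecg)
        assert abs(len(det) - 75) <= 1
        for t in true_times:
            assert np.min(np.abs(det - t)) < 0.02

    def test_flat_signal_no_detections(self):
        assert len(detect_rwaves(np.zeros(int(60 * FS)))) == 0

    def test_refractory_spacing(self):
        ecg, _ = self._ecg([0.8], 60.0)
        det = detect_rwaves(ecg)
        assert (np.diff(det) >= 0.2).all()

    def test_adaptive_threshold_survives_amplitude_halving(self):
        ecg, true_times = self._ecg(
            [0.8], 60.0, amp=lambda t: 1000.0 if t < 30 else 500.0
        )
        det = detect_rwaves(ecg)
        recovered = sum(1 for t in true_times if np.min(np.abs(det - t)) < 0.05)
        assert recovered >= 0.95 * len(true_times)


class TestIBIFeature:
    def test_constant_rr_recovered(self):
        r = np.arange(0.4, 60.0, 0.8)
        out = ibi_feature(r, 60.0)
        np.testing.assert_allclose(out, 800.0)

    def test_alternating_rr_averages(self):
        gaps = [0.7, 0.9] * 50
        r = np.concatenate([[0.2], 0.2 + np.cumsum(gaps)])
        out = ibi_feature(r, 60.0)
        assert np.allclose(out[10:], 800.0, atol=20.0)

    def test_unit_conversion_to_bpm(self):
        r = np.arange(0.3, 60.0, 0.6)
        out = ibi_feature(r, 60.0)
        np.testing.assert_allclose(out, 600.0)
        np.testing.assert_allclose(60000.0 / out, 100.0)  # beats/min display

    def test_fewer_than_two_beats_rejected(self):
        with pytest.raises(ValueError):
            ibi_feature(np.array([1.0]), 60.0)


@pytest.fixture(scope="module")
def frames(annotated_session):
    return assemble_features(annotated_session)


class TestAssembly:

    def test_feature_block_structure(self, frames):
        frame, workload, session = frames[0]
        assert len(frame.names) == 37
        assert len(EEG_FEATURES) == 25
        eog_band_features = [
            n for n in PERIPHERAL_FEATURES if n not in ("blink_rate", "ibi")
        ]
        assert len(eog_band_features) + 1 == 11  # VEOG/HEOG bands + blink rate
        assert workload == "low" and session == "S1"

    def test_one_row_per_second(self, frames):
        for frame, _, _ in frames:
            assert frame.values.shape == (120, 37)

    def test_column_order_is_frozen_contract(self, frames):
        frame = frames[0][0]
        assert frame.names == FEATURE_NAMES
        assert FEATURE_NAMES[0] == "Fz_delta"
        assert FEATURE_NAMES[24] == "O2_gamma"
        assert FEATURE_NAMES[25] == "VEOG_delta"
        assert FEATURE_NAMES[-2:] == ("blink_rate", "ibi")

    def test_csv_round_trip_preserves_order(self, frames, tmp_path):
        frame = frames[0][0]
        path = tmp_path / "features.csv"
        frame.to_csv(path)
        back = FeatureFrame.from_csv(path)
        assert back.names == frame.names
        np.testing.assert_allclose(back.values, frame.values)

    def test_missing_channel_rejected(self, annotated_session):
        crippled = synthgen.Recording(
            sample_rate=annotated_session.sample_rate,
            channels=annotated_session.channels[:-1],
            samples=annotated_session.samples[:-1],
            annotations=annotated_session.annotations,
        )
        with pytest.raises(ValueError, match="ECG"):
            assemble_features(crippled)

    def test_workload_signatures_visible_in_features(self, profiles):
        """The generator's workload effects surface in the named features:
        higher Fz theta, lower Pz alpha, lower blink rate, lower IBI."""
        low, high = profiles
        rec = synthgen.generate_session(low, high, ("low", "high"), 120, seed=33)
        (f_low, _, _), (f_high, _, _) = assemble_features(rec)
        names = list(FEATURE_NAMES)
        for feat, sign in (
            ("Fz_theta", +1),
            ("Pz_alpha", -1),
            ("blink_rate", -1),
            ("ibi", -1),
        ):
            i = names.index(feat)
            diff = f_high.values[30:, i].mean() - f_low.values[30:, i].mean()
            assert np.sign(diff) == sign, feat
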