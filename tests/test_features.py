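"""The 30-feature vector: time-domain, Welch-harmonic and wavelet-packet."""

import numpy as np
import pytest
from scipy import signal as sps

from ppgrisk.features import (FEATURE_NAMES, HARMONIC_FEATURE_NAMES,
                              TIME_FEATURE_NAMES, WPD_FEATURE_NAMES,
                              harmonic_features, pulse_widths,
                              record_feature_vector, time_features, welch_psd,
                              wpd_energies)
from ppgrisk.fiducials import BeatFiducials
from ppgrisk.preprocess import CleanSignal, bandpass_filter, detect_onsets
from ppgrisk.simulate import (default_pulse_params, generate_harmonic_signal,
                              generate_pulse_train)

FS = 500.0


def fiducials_from(t_P=150.0, t_D=472.0, t_next=1000.0, y_D=0.442,
                   y_A=800.0, y_B=-900.0, y_E=300.0):
    return BeatFiducials(
        t_N=0.0, t_P=t_P, t_D=t_D, t_A=40.0, t_B=120.0, t_E=380.0, t_F=470.0,
        t_next_N=t_next, y_N=0.0, y_P=1.0, y_D=y_D, y_A=y_A, y_B=y_B, y_E=y_E,
        d_from_fallback=False,
    )


def triangle_beat(base_ms=400.0, total_ms=1000.0):
    n = int(total_ms / 1000 * FS)
    t = np.arange(n) * 1000.0 / FS
    apex = base_ms / 2
    beat = np.clip(1 - np.abs(t - apex) / apex, 0.0, 1.0)
    return beat


class TestTimeFeatures:
    def test_interval_arithmetic(self):
        f = fiducials_from()
        beat = triangle_beat()
        tf = time_features(f, beat, FS, 167.4)
        assert tf.Tp == 150.0
        assert tf.Td == 472.0
        assert tf.HR == pytest.approx(60.0)
        assert tf.T_RD == pytest.approx(150.0 / 850.0)
        assert tf.Rslop == pytest.approx(1.0 / 150.0)
        assert tf.Dslop == pytest.approx(1.0 / 850.0)

    def test_stiffness_index_from_height_and_transit(self):
        f = fiducials_from(t_P=212.0, t_D=472.0)
        tf = time_features(f, triangle_beat(), FS, 167.4)
        assert tf.SI == pytest.approx(1.674 / 0.260, rel=1e-6)

    def test_reflection_index_is_amplitude_ratio(self):
        tf = time_features(fiducials_from(y_D=0.442), triangle_beat(), FS, None)
        assert tf.RI == pytest.approx(0.442)
        assert tf.SI is None  # no height given

    def test_signed_apg_ratios(self):
        tf = time_features(fiducials_from(), triangle_beat(), FS, None)
        assert tf.VDab == pytest.approx(800.0 / -900.0)
        assert tf.VDae == pytest.approx(800.0 / 300.0)
        assert tf.VDab < 0

    def test_missing_d_flags_dependents(self):
        f = fiducials_from()
        f.t_D = None
        f.y_D = None
        tf = time_features(f, triangle_beat(), FS, 167.4)
        assert tf.Td is None and tf.RI is None and tf.SI is None
        assert tf.Tp == 150.0


class TestPulseWidths:
    def test_symmetric_triangle_half_width(self):
        beat = triangle_beat(400.0)
        f = fiducials_from(t_P=200.0)
        f.y_P = 1.0
        assert pulse_widths(beat, f, 0.5, FS) == pytest.approx(200.0, abs=3.0)

    def test_width_ordering_on_unimodal_beats(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            apex = rng.uniform(100, 400)
            sig = rng.uniform(30, apex / 2.6)  # beat starts near zero
            t = np.arange(400) * 1000.0 / FS
            beat = np.exp(-0.5 * ((t - apex) / sig) ** 2)
            f = fiducials_from(t_P=apex, t_next=800.0)
            w25 = pulse_widths(beat, f, 0.25, FS)
            w50 = pulse_widths(beat, f, 0.50, FS)
            w75 = pulse_widths(beat, f, 0.75, FS)
            assert w25 >= w50 >= w75 > 0

    def test_uncrossed_level_flagged_missing(self):
        beat = 0.5 + 0.5 * triangle_beat()  # never falls below 0.5
        f = fiducials_from(t_P=200.0)
        assert pulse_widths(beat, f, 0.25, FS) is None


class TestWelch:
    def test_peak_at_sinusoid_frequency(self):
        t = np.arange(int(20 * FS)) / FS
        psd = welch_psd(CleanSignal(np.sin(2 * np.pi * 1.2 * t), FS))
        peak_hz = psd.frequencies[np.argmax(psd.psd_db)]
        assert abs(peak_hz - 1.2) <= psd.frequencies[1]

    def test_two_component_signal_has_two_peaks(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        psd = welch_psd(CleanSignal(x, FS))
        band = (psd.frequencies > 0.5) & (psd.frequencies < 3.5)
        p = psd.psd_db[band]
        freqs = psd.frequencies[band]
        maxima = freqs[np.flatnonzero((p[1:-1] >= p[:-2]) &
                                      (p[1:-1] >= p[2:])) + 1]
        assert np.any(np.abs(maxima - 1.0) < 0.2)
        assert np.any(np.abs(maxima - 3.0) < 0.2)

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(11)
        psd = welch_psd(CleanSignal(rng.normal(size=int(40 * FS)), FS))
        assert psd.segment_count >= 6
        band = (psd.frequencies >= 1.0) & (psd.frequencies <= 20.0)
        assert np.std(psd.psd_db[band]) < 3.0

    def test_matches_scipy_up_to_constant(self):
        """Independent cross-check: same shape as scipy's Welch estimate."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=int(30 * FS))
        ours = welch_psd(CleanSignal(x, FS), standardize=False)
        f_sp, p_sp = sps.welch(x, fs=FS, window="hann", nperseg=4096,
                               noverlap=4096 - 1024, detrend=False)
        np.testing.assert_allclose(ours.frequencies, f_sp)
        band = slice(5, 2000)
        diff = ours.psd_db[band] - 10 * np.log10(p_sp[band])
        # equal up to the fixed normalization offset between conventions
        assert np.std(diff) < 0.2

    def test_segment_bookkeeping(self):
        x = CleanSignal(np.zeros(10000) + np.sin(np.arange(10000)), FS)
        psd = welch_psd(x)
        assert psd.segment_count == (10000 - 4096) // 1024 + 1
        with pytest.raises(ValueError):
            welch_psd(CleanSignal(np.sin(np.arange(2000.0)), FS))


class TestHarmonics:
    def test_equal_power_harmonics_give_unit_ratios(self):
        t = np.arange(int(20 * FS)) / FS
        x = sum(np.sin(2 * np.pi * k * 1.2 * t) for k in range(1, 7))
        harm = harmonic_features(welch_psd(CleanSignal(x, FS)), 72.0)
        # window scalloping perturbs individual peak readings by a few %
        np.testing.assert_allclose(harm.H, np.ones(5), atol=0.04)

    def test_fundamental_only_flags_missing(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        harm = harmonic_features(welch_psd(CleanSignal(x, FS)), 72.0)
        # higher harmonics are absent or at the (far lower) noise floor
        assert np.all(np.isnan(harm.H) | (harm.H < 0.6))

    def test_requested_ratio_recovery(self):
        targets = (0.852, 0.742, 0.580, 0.510, 0.450)
        x = generate_harmonic_signal(1.2, targets, 20.0, FS)
        harm = harmonic_features(welch_psd(CleanSignal(x, FS)), 72.0)
        np.testing.assert_allclose(harm.H, targets, atol=0.02)

    def test_nyquist_guard(self):
        t = np.arange(int(20 * FS)) / FS
        psd = welch_psd(CleanSignal(np.sin(2 * np.pi * 1.2 * t), FS))
        with pytest.raises(ValueError):
            harmonic_features(psd, 3000.0)


class TestWPD:
    def test_normalized_energies_sum_to_one(self):
        rng = np.random.default_rng(1)
        wpd = wpd_energies(CleanSignal(rng.normal(size=10000), FS))
        assert wpd.node_energies.size == 256
        total = wpd.node_energies.sum() / wpd.Eall_linear
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_lands_in_expected_band(self):
        t = np.arange(10000) / FS
        # 5 Hz falls in the 6th 0.977 Hz band (4.883-5.859 Hz); the iterated
        # sym6 filters leak into the adjacent bands, so the band is dominant
        # rather than exclusive
        wpd = wpd_energies(CleanSignal(np.sin(2 * np.pi * 5.0 * t), FS))
        assert int(np.argmax(wpd.node_energies)) == 5
        assert wpd.E[5] >= 0.55
        mid = wpd_energies(CleanSignal(np.sin(2 * np.pi * 5.37 * t), FS))
        assert mid.E[5] >= 0.80

    @pytest.mark.parametrize("n", [2 ** 12, 2 ** 13, 2 ** 14])
    def test_parseval_energy_conservation(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        wpd = wpd_energies(CleanSignal(x, FS))
        assert wpd.Eall_linear == pytest.approx(float(np.sum(x ** 2)),
                                                rel=0.01)

    def test_band_width(self):
        wpd = wpd_energies(CleanSignal(np.random.default_rng(0).normal(
            size=4096), FS))
        assert wpd.band_width_hz == pytest.approx(500.0 / 512.0)


class TestRecordVector:
    def test_feature_name_set(self, clean_signal, clean_onsets, subject):
        fv = record_feature_vector(clean_signal, clean_onsets, subject=subject)
        assert set(fv.values) == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 30
        assert len(TIME_FEATURE_NAMES) == 14
        assert len(HARMONIC_FEATURE_NAMES) == 5
        assert len(WPD_FEATURE_NAMES) == 11

    def test_deterministic(self, clean_signal, clean_onsets, subject):
        a = record_feature_vector(clean_signal, clean_onsets, subject=subject)
        b = record_feature_vector(clean_signal, clean_onsets, subject=subject)
        assert a.values == b.values

    def test_missing_d_propagates(self, subject):
        params = default_pulse_params(72.0, dia_amp=0.0, noise_snr_db=None,
                                      hr_jitter_ms=0.0, baseline_amp=0.0,
                                      sys_fall_ms=60.0)
        samples, _ = generate_pulse_train(params, 20.0, FS, seed=9)
        sig = bandpass_filter(samples, FS)
        fv = record_feature_vector(sig, detect_onsets(sig), subject=subject)
        # the fallback path still yields a diastolic surrogate, so the
        # D-dependent features are present rather than missing
        assert np.isfinite(fv.values["Tp"])
        assert set(fv.values) == set(FEATURE_NAMES)

    def test_energy_concentrated_below_10hz(self, clean_signal):
        wpd = wpd_energies(clean_signal)
        assert float(wpd.E.sum()) >= 0.99
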