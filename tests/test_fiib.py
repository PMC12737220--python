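"""FIIB estimators, baselines, CRB, convergence and complexity counting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarvitals import (SinusoidModel, add_awgn, convergence_count,
                         crb_frequency, dft_leakage, fiib, fiib_real,
                         fft_peak, music_freq, pick_heart_rate, two_tone)

FS, NS = 20.0, 200


class TestDftLeakage:
    def test_on_target_limit_is_ns(self):
        assert dft_leakage(0.31, 0.31, 128) == pytest.approx(128)
        assert dft_leakage(0.5, 0.5 + 3.0, 64) == pytest.approx(64)  # integer d

    def test_zeros_at_bin_offsets(self):
        f_hat = 0.2
        for k in (1, 2, 5, 63):
            assert abs(dft_leakage(f_hat, f_hat + k / 128, 128)) < 1e-9

    @given(st.floats(0, 0.999), st.floats(0, 0.999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kernel_magnitude_bounded_by_ns(self, f_hat, f):
        assert abs(dft_leakage(f_hat, f, 64)) <= 64 + 1e-9

    def test_matches_explicit_geometric_sum(self):
        k = np.arange(50)
        f_hat, f = 0.123, 0.371
        explicit = np.sum(np.exp(2j * np.pi * k * (f_hat - f)))
        assert dft_leakage(f_hat, f, 50) == pytest.approx(explicit)

    def test_single_sample_rejected_below_one(self):
        with pytest.raises(ValueError):
            dft_leakage(0.1, 0.2, 0)


class TestFiib:
    def test_noiseless_off_grid_tone_to_machine_precision(self):
        f = 0.31 + 0.3 / NS   # deliberately off the FFT grid
        x = 0.7 * np.exp(1j * (2 * np.pi * f * np.arange(NS) + 0.4))
        est = fiib(x, 1, 10)
        assert abs(est.frequencies[0] - f) <= 1e-8
        assert abs(est.amplitudes[0] - 0.7 * np.exp(0.4j)) <= 1e-8 * 0.7

    def test_two_complex_tones_recovered(self):
        n = np.arange(NS)
        f1, f2 = 0.0525, 0.0625
        x = np.exp(2j * np.pi * f1 * n) + 0.8 * np.exp(2j * np.pi * f2 * n)
        est = fiib(x, 2, 10)
        assert np.allclose(np.sort(est.frequencies), [f1, f2], atol=1e-9)

    def test_surplus_components_have_small_amplitude(self):
        x = np.exp(2j * np.pi * 0.13 * np.arange(NS))
        est = fiib(x, 3, 10)
        amps = np.abs(est.amplitudes)
        assert np.sort(amps)[:-1].max() < 1e-6 * amps.max()


class TestFiibReal:
    def test_odd_component_count_rejected(self):
        with pytest.raises(ValueError):
            fiib_real(np.sin(np.arange(64.0)), 3)

    def test_complex_input_rejected(self):
        with pytest.raises(ValueError):
            fiib_real(np.exp(1j * np.arange(64.0)), 4)

    def test_conjugate_pair_structure_is_exact(self, benchmark_signal):
        est = fiib_real(add_awgn(benchmark_signal, 15, 1), 4, fs=FS)
        L = est.frequencies.size
        for l in range(L // 2):
            assert est.frequencies[L - 1 - l] == 1.0 - est.frequencies[l]
            assert est.amplitudes[L - 1 - l] == np.conj(est.amplitudes[l])

    @pytest.mark.parametrize("seed", range(10))
    def test_equivalent_to_full_band_on_real_input(self, seed):
        """Both variants are algebraically identical on real signals."""
        rng = np.random.default_rng(seed)
        f1 = rng.uniform(0.05, 0.2)
        f2 = f1 + rng.uniform(1.5, 3.0) / NS
        x = two_tone(rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5),
                     f1 * FS, f2 * FS, FS, NS)
        x = add_awgn(x, 15, rng)
        full = fiib(x.astype(complex), 4, 10)
        real = fiib_real(x, 4, 10)
        assert np.max(np.abs(np.sort(full.frequencies)
                             - np.sort(real.frequencies))) <= 1e-9
        order_f = np.argsort(full.frequencies)
        order_r = np.argsort(real.frequencies)
        assert np.max(np.abs(full.amplitudes[order_f]
                             - real.amplitudes[order_r])) <= 1e-8

    def test_halves_the_leakage_evaluations(self, benchmark_signal):
        """Per fine iteration the real variant needs at most half the
        leakage-kernel evaluations of the full-band variant (L=4, NS=200)."""
        full = fiib(benchmark_signal.astype(complex), 4, 10)
        real = fiib_real(benchmark_signal, 4, 10)
        assert real.leakage_evals_per_iteration <= 0.5 * full.leakage_evals_per_iteration


class TestBaselines:
    def test_fft_peak_exact_on_grid(self):
        x = two_tone(1.0, 0.0, 1.2, 2.0, FS, NS)
        assert fft_peak(x, band=(0.5, 3.0), n_peaks=1, fs=FS)[0] == pytest.approx(1.2)

    def test_fft_merges_sub_resolution_pair(self):
        x = two_tone(1.0, 0.8, 1.05, 1.05 + 0.6 * FS / NS, FS, NS)
        x = add_awgn(x, 20, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peaks = fft_peak(x, band=(0.8, 1.5), n_peaks=2, fs=FS)
        assert peaks.size == 1

    def test_music_single_tone_within_grid_error(self):
        x = two_tone(1.0, 0.0, 1.21, 3.0, FS, NS)
        x = add_awgn(x, 40, 0)
        f = music_freq(x, 1, fs=FS)
        assert abs(f[0] - 1.21) <= 0.02   # grid step 0.001 * fs

    def test_music_resolves_two_bin_spacing(self):
        x = add_awgn(two_tone(1.0, 0.8, 1.05, 1.25, FS, NS), 25, 1)
        f = music_freq(x, 2, fs=FS)
        assert f.size == 2
        assert np.allclose(f, [1.05, 1.25], atol=0.05)

    def test_music_fails_below_resolution_limit(self):
        x = add_awgn(two_tone(1.0, 0.8, 1.05, 1.11, FS, NS), 20, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = music_freq(x, 2, fs=FS)
        # a single resolved component, or two within a bin of each other
        assert f.size < 2 or abs(f[1] - f[0]) < FS / NS


class TestCRB:
    def test_inverse_snr_scaling(self):
        double = 10 * np.log10(2)
        assert crb_frequency(10.0 + double, NS, FS) == pytest.approx(
            crb_frequency(10.0, NS, FS) / 2, rel=1e-9)

    def test_closed_form_value(self):
        snr = 10 ** 2.5
        expected = 6 * FS**2 / ((2 * np.pi) ** 2 * snr * NS * (NS**2 - 1))
        assert crb_frequency(25.0, NS, FS) == pytest.approx(expected)

    def test_monotone_decreasing_in_length(self):
        vals = [crb_frequency(10.0, n, FS) for n in (100, 200, 400, 800)]
        assert np.all(np.diff(vals) < 0)


class TestConvergence:
    def test_noiseless_tone_converges_within_three_iterations(self):
        x = two_tone(1.0, 0.0, 1.233, 3.0, FS, NS)
        assert convergence_count(x, "fiib_real") <= 3

    def test_variant_iteration_counts_agree(self):
        rng = np.random.default_rng(0)
        clean = two_tone(1.0, 0.8, 1.05, 1.11, FS, NS)
        diffs = []
        for _ in range(50):
            x = add_awgn(clean, 10, rng)
            diffs.append(convergence_count(x, "fiib")
                         - convergence_count(x, "fiib_real"))
        assert abs(np.mean(diffs)) <= 0.5

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            convergence_count(np.ones(64), "nope")


class TestPickHeartRate:
    def _estimate(self, comps):
        freqs = np.array([f / FS for f, _ in comps])
        amps = np.array([a for _, a in comps], dtype=complex)
        from radarvitals import FrequencyEstimate
        return FrequencyEstimate(frequencies=freqs, amplitudes=amps, fs=FS)

    def test_strongest_in_band_component_wins(self):
        est = self._estimate([(1.233, 1.0), (1.042, 0.3)])
        assert pick_heart_rate(est) == pytest.approx(73.98)

    def test_single_component_maps_to_bpm(self):
        est = self._estimate([(1.0, 0.5)])
        assert pick_heart_rate(est) == pytest.approx(60.0)

    def test_out_of_band_estimate_falls_back_with_warning(self):
        est = self._estimate([(0.3, 1.0), (2.8, 0.4)])
        with pytest.warns(UserWarning):
            bpm = pick_heart_rate(est)
        assert bpm > 0

    def test_empty_estimate_rejected(self):
        from radarvitals import FrequencyEstimate
        est = FrequencyEstimate(frequencies=np.array([]),
                                amplitudes=np.array([]), fs=FS)
        with pytest.raises(ValueError):
            pick_heart_rate(est)


class TestStatisticalBehaviour:
    def test_no_error_floor_versus_fft(self):
        """At 25 dB the super-resolution estimate beats the grid-limited FFT
        MSE by at least two orders of magnitude."""
        rng = np.random.default_rng(1)
        clean = two_tone(1.0, 0.8, 1.05, 1.25, FS, NS)
        se_fiib, se_fft = [], []
        for _ in range(200):
            x = add_awgn(clean, 25, rng)
            f = np.sort(fiib_real(x, 4, fs=FS).positive_components()[0])
            se_fiib.append((f[0] - 1.05) ** 2)
            p = fft_peak(x, band=(0.0, 10.0), n_peaks=2, fs=FS)
            se_fft.append((p[0] - 1.05) ** 2)
        assert np.mean(se_fiib) * 100 <= np.mean(se_fft)

    def test_mse_slope_parallels_crb(self):
        """log-MSE vs SNR over 5-25 dB declines within 15 % of the CRB
        slope (one decade per 10 dB)."""
        snrs = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        clean = two_tone(1.0, 0.8, 1.05, 1.25, FS, NS)
        mses = []
        for snr in snrs:
            rng = np.random.default_rng(int(snr))
            se = [(np.sort(fiib_real(add_awgn(clean, snr, rng), 4,
                                     fs=FS).positive_components()[0])[0]
                   - 1.05) ** 2 for _ in range(150)]
            mses.append(np.mean(se))
        slope = np.polyfit(snrs, np.log10(mses), 1)[0]
        assert abs(slope - (-0.1)) <= 0.015


class TestSinusoidModel:
    def test_fit_recovers_components_and_reports(self, benchmark_signal):
        res = SinusoidModel(benchmark_signal, fs=FS).fit(4)
        f = np.sort(res.frequencies_hz[res.estimate.frequencies < 0.5])
        assert np.allclose(f, [1.05, 1.25], atol=1e-6)
        assert res.rsquared() > 0.999999
        text = res.summary()
        assert "1.05" in text and "R^2" in text

    def test_heart_rate_from_fit(self, benchmark_signal):
        res = SinusoidModel(benchmark_signal, fs=FS).fit(4)
        assert res.heart_rate() == pytest.approx(63.0, abs=0.01)

    def test_residuals_are_small_for_exact_model(self):
        x = two_tone(1.0, 0.0, 1.2, 3.0, FS, NS)
        res = SinusoidModel(x, fs=FS).fit(2)
        assert np.max(np.abs(res.resid())) < 1e-6
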