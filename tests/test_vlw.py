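"""VLW cascade: phase extraction, VMD, LMD, correlation gating, wavelets."""

import warnings

import numpy as np
import pytest
from scipy.constants import c as C0

from radarvitals import SinusoidModel, VitalProfile, add_awgn, chest_displacement
from radarvitals.vlw import (VitalSignal, correlation_select, extract_phase,
                             lmd_decompose, select_heartbeat_mode,
                             vlw_pipeline, vmd_decompose, wavelet_denoise)
from conftest import synthetic_phase

RATE = 20.0


def _tone(freq, n=512, amp=1.0, rate=RATE):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / rate)


class TestExtractPhase:
    def test_displacement_maps_to_radians_through_wavelength(self):
        """0.5 mm displacement at 77 GHz -> 4 pi 5e-4 / lambda = 1.61 rad."""
        lam = C0 / 77e9
        t = np.arange(512) / RATE
        disp = 0.5e-3 * np.sin(2 * np.pi * 1.0 * t)
        series = np.exp(1j * 4 * np.pi * disp / lam)
        out = extract_phase(series, RATE)
        # half peak-to-peak: immune to the demeaning offset of the
        # non-integer period count
        assert np.ptp(out.values) / 2 == pytest.approx(
            4 * np.pi * 0.5e-3 / lam, rel=1e-3)

    def test_constant_input_gives_zero_phase(self):
        out = extract_phase(np.full(100, 2.0 + 1.0j), RATE)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_unwrap_bounds_successive_jumps(self):
        rng = np.random.default_rng(0)
        series = np.exp(1j * np.cumsum(rng.normal(scale=2.0, size=400)))
        out = extract_phase(series, RATE)
        assert np.max(np.abs(np.diff(out.values))) <= np.pi + 1e-12

    def test_zero_magnitude_samples_flagged_and_interpolated(self):
        series = np.exp(1j * np.linspace(0, 3, 50))
        series[10] = 0.0
        out = extract_phase(series, RATE)
        assert out.flags and np.all(np.isfinite(out.values))


class TestVMD:
    def test_two_separated_tones_recovered(self):
        x = _tone(0.3) + _tone(1.2, amp=0.5)
        x = add_awgn(x, 30, 0)
        modes = vmd_decompose(x, RATE)
        centres = modes.center_frequencies
        assert np.min(np.abs(centres - 0.3)) < 0.05
        assert np.min(np.abs(centres - 1.2)) < 0.05

    def test_zero_signal_gives_zero_modes(self):
        modes = vmd_decompose(np.zeros(128), RATE)
        assert all(not np.any(m) for m in modes.modes)

    def test_centres_sorted_ascending(self):
        x = _tone(0.4) + _tone(1.5, amp=0.7) + _tone(3.0, amp=0.3)
        modes = vmd_decompose(x, RATE)
        assert np.all(np.diff(modes.center_frequencies) >= 0)

    def test_reconstruction_residual_within_tolerance(self):
        x = _tone(0.3) + _tone(1.2, amp=0.5)
        modes = vmd_decompose(x, RATE)
        resid = np.linalg.norm(x - np.sum(modes.modes, axis=0))
        assert resid / np.linalg.norm(x) <= 0.05

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            vmd_decompose(np.ones(32), RATE)


class TestModeSelection:
    def _modeset(self, freqs, amps=None):
        amps = amps or [1.0] * len(freqs)
        modes = [_tone(f, amp=a) for f, a in zip(freqs, amps)]
        from radarvitals.vlw import ModeSet
        return ModeSet(modes=modes, center_frequencies=np.array(freqs),
                       rate=RATE)

    def test_only_in_band_centre_wins(self):
        ms = self._modeset([0.3, 1.2, 3.1])
        assert np.allclose(select_heartbeat_mode(ms), ms.modes[1])

    def test_tie_broken_by_in_band_energy(self):
        ms = self._modeset([0.9, 1.5], amps=[1.0, 2.0])
        assert np.allclose(select_heartbeat_mode(ms), ms.modes[1])

    def test_no_in_band_mode_falls_back_with_warning(self):
        ms = self._modeset([0.2, 0.5, 3.0])
        with pytest.warns(UserWarning):
            picked = select_heartbeat_mode(ms)
        assert np.allclose(picked, ms.modes[1])  # centre nearest 1.4 Hz

    def test_synthetic_vital_mode_peaks_at_heartbeat(self):
        phase = synthetic_phase(snr_db=25, seed=1)
        modes = vmd_decompose(phase, RATE)
        picked = select_heartbeat_mode(modes)
        spec = np.abs(np.fft.rfft(picked))
        peak = np.argmax(spec) * RATE / picked.size
        assert abs(peak - 1.233) <= 0.05


class TestLMD:
    def test_pure_sinusoid_is_a_single_pf(self):
        s = _tone(1.3)
        pfs = lmd_decompose(s, RATE)
        assert len(pfs) == 1
        assert np.linalg.norm(pfs.modes[0] - s) / np.linalg.norm(s) < 0.05

    def test_two_component_signal_gives_multiple_pfs(self):
        x = _tone(1.2) + _tone(0.35, amp=0.6)
        pfs = lmd_decompose(x, RATE)
        assert len(pfs) >= 2

    def test_pfs_plus_residual_reconstruct_exactly(self):
        rng = np.random.default_rng(2)
        x = _tone(1.1) + 0.3 * rng.normal(size=512)
        pfs = lmd_decompose(x, RATE)
        recon = np.sum(pfs.modes, axis=0) + pfs.residual
        assert np.linalg.norm(x - recon) / np.linalg.norm(x) <= 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            lmd_decompose(np.ones(100), RATE)


class TestCorrelationSelect:
    def test_self_correlation_kept(self):
        x = _tone(1.0)
        kept, corrs = correlation_select([x], x)
        assert len(kept) == 1 and corrs[0] == pytest.approx(1.0)

    def test_orthogonal_tone_discarded(self):
        ref = _tone(1.0, n=400)   # whole periods at 20 Hz
        other = _tone(2.0, n=400)
        kept, corrs = correlation_select([other], ref)
        assert len(kept) == 0 and abs(corrs[0]) < 1e-9

    def test_threshold_is_strict(self):
        ref = _tone(1.0)
        pfs = [0.9 * ref, 0.34 * ref + _tone(2.0, amp=0.94),
               0.36 * ref + _tone(2.0, amp=0.933)]
        kept, corrs = correlation_select(pfs, ref, threshold=0.35)
        assert np.round(corrs, 2).tolist() == [1.0, 0.34, 0.36]
        assert len(kept) == 2

    def test_zero_variance_pf_gets_zero_correlation(self):
        ref = _tone(1.0)
        kept, corrs = correlation_select([np.zeros_like(ref)], ref)
        assert corrs[0] == 0.0 and not kept


class TestWaveletDenoise:
    def test_clean_sinusoid_nearly_unchanged(self):
        x = _tone(1.233)
        out = wavelet_denoise(x)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) <= 0.02

    def test_snr_improves_by_3_db_on_noisy_tone(self):
        clean = _tone(1.233)
        gains = []
        for seed in range(5):
            noisy = add_awgn(clean, 0.0, seed)
            out = wavelet_denoise(noisy)
            before = np.mean(clean**2) / np.mean((noisy - clean) ** 2)
            after = np.mean(clean**2) / np.mean((out - clean) ** 2)
            gains.append(10 * np.log10(after / before))
        assert np.mean(gains) >= 3.0

    def test_length_preserved(self):
        for n in (257, 500, 512):
            assert wavelet_denoise(np.random.default_rng(0).normal(size=n)).size == n


class TestVLWPipeline:
    def test_full_cascade_peaks_at_heartbeat(self):
        phase = synthetic_phase(snr_db=30, seed=3)
        out = vlw_pipeline(VitalSignal(values=phase, rate=RATE))
        spec = np.abs(np.fft.rfft(out.values))
        peak_hz = np.argmax(spec) * RATE / out.values.size
        assert abs(peak_hz - 1.233) <= RATE / out.values.size  # within 1 bin

    def test_clean_heart_only_input_preserved(self):
        phase = synthetic_phase(respiration=False)
        out = vlw_pipeline(VitalSignal(values=phase, rate=RATE))
        spec = np.abs(np.fft.rfft(out.values))
        peak_hz = np.argmax(spec) * RATE / out.values.size
        assert abs(peak_hz - 1.233) <= 0.05
        assert np.sum(out.values**2) >= 0.8 * np.sum(phase**2)

    def test_all_noise_input_survives_with_flags(self):
        rng = np.random.default_rng(0)
        sig = VitalSignal(values=rng.normal(size=512), rate=RATE)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = vlw_pipeline(sig)
        assert np.all(np.isfinite(out.values))

    def test_cascade_monotonically_sharpens_the_heartbeat(self):
        """Spectral ratio heartbeat-peak / strongest out-of-band peak is
        non-decreasing across raw -> VMD -> VMD+LMD -> VLW."""
        from radarvitals.vlw import (correlation_select, lmd_decompose,
                                     select_heartbeat_mode, vmd_decompose,
                                     wavelet_denoise)
        phase = synthetic_phase(snr_db=30, seed=5)
        heart = select_heartbeat_mode(vmd_decompose(phase, RATE))
        pfs = lmd_decompose(heart, RATE)
        kept, corrs = correlation_select(pfs, heart)
        kept = kept or [pfs.modes[int(np.argmax(corrs))]]
        lmd_out = np.sum(kept, axis=0)
        vlw_out = np.sum([wavelet_denoise(p) for p in kept], axis=0)

        def ratio(sig):
            spec = np.abs(np.fft.rfft(sig * np.hanning(sig.size)))
            freqs = np.fft.rfftfreq(sig.size, 1 / RATE)
            near = np.abs(freqs - 1.233) <= 0.15
            out_band = ~near & (freqs > 0.1)
            return spec[near].max() / spec[out_band].max()

        ratios = [ratio(s) for s in (phase, heart, lmd_out, vlw_out)]
        assert all(b >= a * 0.999 for a, b in zip(ratios, ratios[1:]))

    def test_vlw_beats_vmd_only_on_hr_error(self):
        """Across seeded noisy recordings, mean HR MAE of the full cascade
        stays at or below the VMD-only shortcut (both followed by FIIB)."""
        err_vlw, err_vmd = [], []
        for seed in range(20):
            phase = synthetic_phase(snr_db=30, seed=100 + seed)
            sig = VitalSignal(values=phase, rate=RATE)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = vlw_pipeline(sig)
                vmd_only = select_heartbeat_mode(
                    vmd_decompose(phase, RATE))
                hr_full = SinusoidModel(full.values, fs=RATE).fit(4).heart_rate()
                hr_vmd = SinusoidModel(vmd_only, fs=RATE).fit(4).heart_rate()
            err_vlw.append(abs(hr_full - 60 * 1.233))
            err_vmd.append(abs(hr_vmd - 60 * 1.233))
        assert np.mean(err_vlw) <= np.mean(err_vmd)
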