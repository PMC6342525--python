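"""Synthetic LFP generator: determinism, waveforms, noise, event placement."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sleeplfp import extract_bouts
from sleeplfp.io import NREMS, WAKE
from sleeplfp.synth import (
    SynthParams,
    default_state_sequence,
    generate_recording,
    kappa_for_as_fraction,
    make_background,
    make_spindle_waveform,
    preset,
)


def _short_params(**kw) -> SynthParams:
    base = dict(state_sequence=[WAKE] * 2 + [NREMS] * 30 + [WAKE] * 2, fs=500.0)
    base.update(kw)
    return SynthParams(**base)


class TestSpindleWaveform:
    def test_amplitude_and_endpoints(self):
        w = make_spindle_waveform(0.5, 12.0, 100.0, 1000.0)
        assert np.max(np.abs(w)) == pytest.approx(100.0)
        assert w[0] == 0.0 and w[-1] == 0.0

    @pytest.mark.parametrize("freq", [10.0, 12.0, 14.5])
    def test_fft_peak_at_carrier(self, freq):
        fs = 1000.0
        w = make_spindle_waveform(0.5, freq, 50.0, fs)
        nfft = int(4 * fs)  # zero-pad to 0.25 Hz resolution
        mag = np.abs(np.fft.rfft(w, n=nfft))
        f = np.fft.rfftfreq(nfft, 1 / fs)
        assert f[np.argmax(mag)] == pytest.approx(freq, abs=0.25)

    def test_under_three_cycles_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            make_spindle_waveform(0.1, 12.0, 50.0, 1000.0)

    def test_hann_limit(self):
        # taper_fraction=1 degenerates to a full Hann bell: single max
        w = make_spindle_waveform(0.5, 12.0, 80.0, 1000.0, taper_fraction=1.0)
        env_peak = np.argmax(np.abs(w))
        assert abs(env_peak - w.size // 2) < w.size // 10


class TestBackground:
    def test_white_noise_uncorrelated(self):
        x = make_background(100.0, 1000.0, noise_exponent=0.0,
                            noise_amp_uv=10.0, seed=3)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_rms_normalization(self):
        for exp in (0.0, 1.0, 2.0):
            x = make_background(50.0, 500.0, exp, 7.5, seed=1)
            assert np.sqrt(np.mean(x**2)) == pytest.approx(7.5, rel=1e-6)

    def test_pink_noise_slope(self):
        # log-log PSD slope of 1/f noise should be near -1
        fs = 500.0
        x = make_background(200.0, fs, 1.0, 10.0, seed=5)
        from scipy.signal import welch
        f, p = welch(x, fs=fs, nperseg=4096)
        sel = (f > 1) & (f < 100)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert -1.3 < slope < -0.7

    def test_deterministic(self):
        a = make_background(10.0, 500.0, 1.0, 5.0, seed=11)
        b = make_background(10.0, 500.0, 1.0, 5.0, seed=11)
        np.testing.assert_array_equal(a, b)


class TestGenerateRecording:
    def test_same_seed_bit_identical(self):
        p = _short_params()
        r1, h1, g1 = generate_recording(p, 42)
        r2, h2, g2 = generate_recording(p, 42)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert h1.states == h2.states
        np.testing.assert_array_equal(g1.spindle_onsets_s, g2.spindle_onsets_s)

    def test_zero_rate_means_no_spindles(self):
        p = _short_params(spindle_rate_per_min=0.0)
        _, _, gt = generate_recording(p, 0)
        assert gt.n_spindles == 0

    def test_events_inside_nrems_bouts(self):
        p = _short_params(spindle_rate_per_min=10.0)
        _, hyp, gt = generate_recording(p, 7)
        bouts = extract_bouts(hyp, NREMS, 0.0)
        for on, off in zip(gt.spindle_onsets_s, gt.spindle_offsets_s):
            assert any(b.start_s <= on and off <= b.end_s for b in bouts)

    def test_poisson_counting(self):
        # 10/min over 10 min of NREMS, 30 seeds: mean count ~ Poisson(100)
        p = SynthParams(
            state_sequence=[NREMS] * 150, fs=200.0, spindle_rate_per_min=10.0,
            so_amp_uv=0.0, delta_amp_uv=0.0,  # placement limits off the table
        )
        counts = [generate_recording(p, s)[2].n_attempted for s in range(30)]
        skipped = [generate_recording(p, s)[2].n_skipped for s in range(3)]
        se = np.sqrt(100.0 / 30)
        assert abs(np.mean(counts) - 100.0) < 3 * se
        assert all(s < 5 for s in skipped)  # thinning is rare at this density

    def test_wake_segments_are_noise_only(self):
        p = _short_params(noise_amp_uv=5.0, spindle_rate_per_min=20.0)
        rec, hyp, _ = generate_recording(p, 1)
        wake = rec.channel(0)[: int(8 * p.fs)]
        # wake RMS stays at the noise floor, far below the SO amplitude
        assert np.sqrt(np.mean(wake**2)) < 3 * p.noise_amp_uv

    def test_sigma_power_at_noise_floor_without_spindles(self):
        from sleeplfp import normalize_spectrum, power_spectrum, band_power
        from sleeplfp.io import concatenate_state_segments

        quiet = _short_params(spindle_rate_per_min=0.0)
        rich = _short_params(spindle_rate_per_min=10.0)
        sigma = {}
        for name, p in [("quiet", quiet), ("rich", rich)]:
            rec, hyp, _ = generate_recording(p, 3)
            bouts = extract_bouts(hyp, NREMS, 20.0)
            segs = concatenate_state_segments(rec, bouts)
            ps = normalize_spectrum(power_spectrum(segs, p.fs))
            sigma[name] = band_power(ps, (10.0, 15.0))
        assert sigma["rich"] > 5 * sigma["quiet"]


class TestPhasePreference:
    def test_uniform_phases_pass_rayleigh(self):
        # kappa = 0: generated onset phases uniform on the SO cycle
        p = SynthParams(state_sequence=[NREMS] * 250, fs=200.0,
                        spindle_rate_per_min=12.0, phase_kappa=0.0)
        phases = np.concatenate(
            [generate_recording(p, s)[2].spindle_phases_deg for s in range(3)]
        )
        assert phases.size > 300
        rad = np.radians(phases)
        n = rad.size
        r = np.abs(np.mean(np.exp(1j * rad)))
        p_rayleigh = np.exp(-n * r**2)  # large-n Rayleigh approximation
        assert p_rayleigh > 0.01

    def test_concentrated_phases_hit_preference(self):
        p = SynthParams(state_sequence=[NREMS] * 250, fs=200.0,
                        spindle_rate_per_min=10.0,
                        phase_pref_deg=-90.0, phase_kappa=50.0)
        phases = np.concatenate(
            [generate_recording(p, s)[2].spindle_phases_deg for s in range(2)]
        )
        assert phases.size >= 50
        mean_deg = np.degrees(np.angle(np.mean(np.exp(1j * np.radians(phases)))))
        assert abs(mean_deg - (-90.0)) < 5.0

    def test_kappa_for_as_fraction(self):
        assert kappa_for_as_fraction(0.5) == 0.0
        k = kappa_for_as_fraction(0.7)
        vm = stats.vonmises(k, loc=-np.pi / 2)
        assert vm.cdf(0) - vm.cdf(-np.pi) == pytest.approx(0.7, abs=1e-6)


class TestPresets:
    def test_contrasts(self):
        wt, ko = preset("wt_s1"), preset("ko_s1")
        assert ko.spindle_amp_uv < wt.spindle_amp_uv
        assert ko.spindle_rate_per_min < wt.spindle_rate_per_min
        assert ko.delta_amp_uv > wt.delta_amp_uv
        assert ko.so_amp_uv < wt.so_amp_uv
        assert preset("wt_pfc").spindle_amp_uv < wt.spindle_amp_uv

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("xyz")

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SynthParams(spindle_freq_mean_hz=20.0)
        with pytest.raises(ValueError):
            SynthParams(so_freq_hz=3.0)
        with pytest.raises(ValueError):
            SynthParams(noise_amp_uv=-1.0)

    def test_default_state_sequence_mostly_nrems(self):
        seq = default_state_sequence(680.0)
        assert len(seq) == 170
        assert seq.count(NREMS) / len(seq) > 0.5
        with pytest.raises(ValueError):
            default_state_sequence(1.0)
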