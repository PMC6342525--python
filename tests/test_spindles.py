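"""Spindle detector: envelope, threshold, event rules, characterization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sleeplfp.filters import design_bandpass
from sleeplfp.io import Bout, NREMS
from sleeplfp.spindles import (
    SpindleEvent,
    compute_threshold,
    detect_events,
    detect_spindles,
    intra_spindle_frequency,
    sigma_envelope,
    sigma_filter,
    spindle_amplitude,
)
from sleeplfp.synth import make_spindle_waveform

FS = 1000.0


def burst_trace(duration_s: float, bursts: list[tuple[float, float, float]],
                noise_uv: float = 1.0, seed: int = 0,
                amp_uv: float = 60.0) -> np.ndarray:
    """White-noise trace with injected (onset, dur, freq) spindle bursts."""
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=noise_uv, size=int(duration_s * FS))
    for onset, dur, freq in bursts:
        w = make_spindle_waveform(dur, freq, amp_uv, FS)
        i = int(onset * FS)
        x[i : i + w.size] += w
    return x


class TestSigmaEnvelope:
    def test_pure_12hz_plateau_is_half_squared_amplitude(self):
        amp = 40.0
        t = np.arange(int(10 * FS)) / FS
        env = sigma_envelope(amp * np.sin(2 * np.pi * 12.0 * t), FS)
        mid = env[int(2 * FS) : int(8 * FS)]
        assert np.median(mid) == pytest.approx(amp**2 / 2, rel=0.05)

    def test_stop_band_rejection(self):
        t = np.arange(int(10 * FS)) / FS
        env = sigma_envelope(40.0 * np.sin(2 * np.pi * 4.0 * t), FS)
        # >= 40 dB power attenuation vs the 12 Hz plateau of 800 uV^2
        assert np.median(env[int(2 * FS) : int(8 * FS)]) < 800 * 1e-4

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(4)
        x = burst_trace(8.0, [(3.0, 0.6, 12.0)], noise_uv=5.0, seed=4)
        env = sigma_envelope(x, FS)
        # independent recomposition: FIR filtfilt -> square -> boxcar
        from scipy.signal import filtfilt
        taps = design_bandpass(FS, (9.0, 16.0))
        f = filtfilt(taps, [1.0], x, padlen=min(3 * len(taps), x.size - 1))
        sq = f**2
        n = int(0.1 * FS)
        padded = np.pad(sq, n // 2, mode="reflect")
        oracle = np.convolve(padded, np.ones(n) / n, mode="same")[
            n // 2 : n // 2 + sq.size
        ]
        np.testing.assert_allclose(env, oracle, atol=1e-10)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            sigma_filter(np.zeros(1000), fs=30.0)


class TestThreshold:
    def test_constant_envelope(self):
        assert compute_threshold(np.full(100, 7.0)) == pytest.approx(7.0)

    def test_two_level_envelope_hand_computed(self):
        env = np.array([0.0, 2.0] * 50)  # mean 1, population SD 1
        assert compute_threshold(env) == pytest.approx(2.5)

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float64, st.integers(2, 300),
                      elements=st.floats(0, 1e4, allow_nan=False)))
    def test_matches_direct_formula(self, env):
        expected = np.mean(env) + 1.5 * np.sqrt(np.mean((env - np.mean(env)) ** 2))
        assert compute_threshold(env) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_empty_envelope(self):
        with pytest.raises(ValueError, match="empty"):
            compute_threshold(np.empty(0))


class TestDetectEvents:
    def _bout(self, duration_s: float) -> list[Bout]:
        return [Bout(NREMS, 0.0, duration_s)]

    def test_zero_signal_no_events(self):
        n = int(30 * FS)
        events = detect_events(np.zeros(n), np.zeros(n), 0.1,
                               self._bout(30.0), FS)
        assert events == []

    def test_single_burst_recovered_with_accurate_onset(self):
        onset, dur = 14.7, 0.6
        x = burst_trace(30.0, [(onset, dur, 12.0)], noise_uv=2.0, seed=1)
        events = detect_spindles(x, FS, self._bout(30.0))
        assert len(events) == 1
        assert abs(events[0].onset_s - onset) < 0.05
        assert events[0].intra_freq_hz == pytest.approx(12.0, abs=0.25)

    def test_fusion_gap_rules(self):
        # carrier at 12.5 Hz: band-pass zero crossings every 40 ms, so
        # extension geometry is exact.  Runs end/start mid-half-cycle.
        n = int(2 * FS)
        t = np.arange(n) / FS
        filtered = np.sin(2 * np.pi * 12.5 * t)
        for gap_s, expected in [(0.005, 1), (0.050, 2)]:
            env = np.zeros(n)
            a1, b1 = 0.055, 0.355  # 0.3 s run spans 7 zero crossings
            a2 = b1 + gap_s
            b2 = a2 + 0.300
            env[int(a1 * FS) : int(b1 * FS)] = 1.0
            env[int(a2 * FS) : int(b2 * FS)] = 1.0
            events = detect_events(filtered, env, 0.5, self._bout(2.0), FS)
            assert len(events) == expected, f"gap {gap_s*1000:.0f} ms"

    def test_two_cycle_burst_rejected(self):
        # 2 cycles at 12 Hz (0.167 s) above threshold: under the 3-cycle rule
        x = burst_trace(30.0, [(15.0, 0.25, 12.0)], noise_uv=0.5, seed=2,
                        amp_uv=80.0)
        filtered = sigma_filter(x, FS)
        env = sigma_envelope(x, FS, filtered=filtered)
        events = detect_events(filtered, env, 500.0, self._bout(30.0), FS)
        # supra-threshold core of a 0.25 s tapered burst holds < 3 cycles
        assert events == []

    def test_fixed_duration_mode(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        filtered = np.sin(2 * np.pi * 12.5 * t)
        env = np.zeros(n)
        env[int(3.0 * FS) : int(3.1 * FS)] = 1.0  # 100 ms run
        assert detect_events(filtered, env, 0.5, self._bout(10.0), FS,
                             min_duration_s=0.24) == []
        env[int(5.0 * FS) : int(5.3 * FS)] = 1.0  # 300 ms run
        events = detect_events(filtered, env, 0.5, self._bout(10.0), FS,
                               min_duration_s=0.24)
        assert len(events) == 1

    def test_event_touching_bout_edge_discarded(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        filtered = np.sin(2 * np.pi * 12.5 * t)
        env = np.zeros(n)
        env[: int(0.5 * FS)] = 1.0  # run starts at the first bout sample
        assert detect_events(filtered, env, 0.5, self._bout(10.0), FS) == []

    def test_events_confined_to_own_bout(self):
        x = burst_trace(60.0, [(10.0, 0.6, 12.0), (40.0, 0.6, 12.0)],
                        noise_uv=2.0, seed=3)
        bouts = [Bout(NREMS, 0.0, 28.0), Bout(NREMS, 32.0, 60.0)]
        events = detect_spindles(x, FS, bouts)
        assert len(events) == 2
        assert events[0].bout_id == 0 and events[1].bout_id == 1

    def test_amplitude_scale_covariance(self):
        x = burst_trace(30.0, [(10.0, 0.6, 11.0), (20.0, 0.5, 13.0)],
                        noise_uv=2.0, seed=5)
        e1 = detect_spindles(x, FS, self._bout(30.0))
        e2 = detect_spindles(3.0 * x, FS, self._bout(30.0))
        assert [(e.onset_s, e.offset_s) for e in e1] == \
               [(e.onset_s, e.offset_s) for e in e2]
        for a, b in zip(e1, e2):
            assert b.amplitude_uv2 == pytest.approx(9.0 * a.amplitude_uv2, rel=1e-6)

    def test_post_fusion_separation_invariant(self):
        x = burst_trace(60.0, [(5.0 + 3.7 * k, 0.5, 12.0) for k in range(14)],
                        noise_uv=2.0, seed=6)
        events = detect_spindles(x, FS, self._bout(60.0))
        onsets = [e.onset_s for e in events]
        offsets = [e.offset_s for e in events]
        gaps = np.array(onsets[1:]) - np.array(offsets[:-1])
        assert np.all(gaps >= 0.010)


class TestCharacterization:
    def test_amplitude_of_constant_envelope(self):
        ev = SpindleEvent(onset_s=1.0, offset_s=2.0)
        assert spindle_amplitude(ev, np.full(int(3 * FS), 42.0), FS) == \
               pytest.approx(42.0)

    def test_amplitude_is_direct_mean(self):
        rng = np.random.default_rng(8)
        env = rng.uniform(0, 100, int(5 * FS))
        ev = SpindleEvent(onset_s=1.234, offset_s=2.345)
        a, b = int(round(1.234 * FS)), int(round(2.345 * FS))
        assert spindle_amplitude(ev, env, FS) == pytest.approx(env[a:b].mean())

    @pytest.mark.parametrize("freq", [10.0, 12.0, 14.5])
    def test_intra_frequency_recovers_carrier(self, freq):
        x = burst_trace(10.0, [(4.0, 0.6, freq)], noise_uv=0.5, seed=9)
        filtered = sigma_filter(x, FS)
        ev = SpindleEvent(onset_s=4.0, offset_s=4.6)
        assert intra_spindle_frequency(ev, filtered, FS) == \
               pytest.approx(freq, abs=0.25)

    def test_flat_in_band_spectrum_gives_no_peak(self):
        # an impulse has a flat magnitude spectrum: no distinguishable peak
        seg = np.zeros(int(0.5 * FS))
        seg[seg.size // 2] = 1.0
        ev = SpindleEvent(onset_s=0.0, offset_s=0.5)
        assert intra_spindle_frequency(ev, seg, FS) is None
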