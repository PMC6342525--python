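"""Synthetic NREMS LFP with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, not the biophysics that produces it.  NREMS segments are a sum of

* a slow-oscillation (SO) sinusoid at ``so_freq`` (phase 0 = positive peak
  at bout start),
* band-limited Gaussian "delta" activity (1.5-4 Hz) at RMS ``delta_amp``,
* 1/f^exponent background noise at RMS ``noise_amp``,
* injected spindles: Hann-enveloped sinusoids (9-16 Hz) whose onsets are
  drawn on the SO cycle from a von Mises distribution around
  ``phase_pref_deg`` with concentration ``phase_kappa`` (0 = uniform).

WAKE and REMS segments contain background noise only.  Every injected event
is reported in :class:`GroundTruth`; output is deterministic given the seed.
Amplitudes are in uV, but every downstream analysis is scale-covariant or
normalized, so the absolute scale carries no claim about mouse physiology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.signal.windows import tukey

from .io import NREMS, REMS, WAKE, Bout, Hypnogram, Recording, extract_bouts

logger = logging.getLogger(__name__)


@dataclass
class SynthParams:
    """Generator settings; defaults define the reference test conditions."""

    duration_s: float = 600.0
    fs: float = 1000.0
    epoch_len_s: float = 4.0
    # spindles
    spindle_rate_per_min: float = 8.0  # events per minute of NREMS
    spindle_freq_mean_hz: float = 11.0  # intra-frequency peak near 10-12 Hz
    spindle_freq_sd_hz: float = 1.0
    spindle_duration_mean_s: float = 0.6
    spindle_duration_sd_s: float = 0.12
    spindle_amp_uv: float = 60.0
    # slow oscillation / delta
    so_freq_hz: float = 0.8  # within the 0.5-1.5 Hz SO band
    so_amp_uv: float = 75.0
    delta_amp_uv: float = 25.0  # RMS of the 1.5-4 Hz component
    # background
    noise_exponent: float = 1.0  # 1/f slope of the PSD
    noise_amp_uv: float = 15.0  # RMS
    # spindle-SO phase preference
    phase_pref_deg: float = -90.0  # centre of the active state
    phase_kappa: float = 0.0  # 0 = uniform on the SO cycle
    # hypnogram
    state_sequence: list[str] | None = None
    bout_margin_s: float = 1.0  # keep events clear of bout edges
    min_event_gap_s: float = 0.5  # spacing between injected spindles

    def __post_init__(self) -> None:
        if not 9.0 <= self.spindle_freq_mean_hz <= 16.0:
            raise ValueError("spindle_freq_mean_hz must lie in [9, 16]")
        if not 0.5 <= self.so_freq_hz <= 1.5:
            raise ValueError("so_freq_hz must lie in the SO band [0.5, 1.5]")
        if not -180.0 < self.phase_pref_deg <= 180.0:
            raise ValueError("phase_pref_deg must lie in (-180, 180]")
        for name in ("spindle_amp_uv", "so_amp_uv", "delta_amp_uv", "noise_amp_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery scoring."""

    spindle_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_offsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_freqs_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_phases_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    so_trough_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    so_peak_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_attempted: int = 0
    n_skipped: int = 0

    @property
    def n_spindles(self) -> int:
        return self.spindle_onsets_s.size


def make_spindle_waveform(
    duration_s: float,
    freq_hz: float,
    amp_uv: float,
    fs: float,
    taper_fraction: float = 0.3,
) -> np.ndarray:
    """Sinusoid under a symmetric raised-cosine envelope: the waxing-waning
    spindle shape.

    The envelope is a Tukey window: cosine tapers over ``taper_fraction`` of
    the duration around a sustained core; ``taper_fraction=1`` degenerates to
    a full Hann bell.  The default keeps a plateau because detected spindles
    hold their sigma power through the event rather than peaking only at the
    midpoint.  The carrier is phased to peak at the envelope centre, so the
    waveform attains exactly ``amp_uv`` and is zero at both ends.  Durations
    below 3 cycles are refused — such events would be rejected by the
    detector's own duration rule by design.
    """
    if duration_s < 3.0 / freq_hz:
        raise ValueError(
            f"duration {duration_s} s is under 3 cycles at {freq_hz} Hz"
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    carrier = np.cos(2 * np.pi * freq_hz * (t - t[n // 2]))
    env = tukey(n, alpha=taper_fraction)
    env[0] = env[-1] = 0.0
    return amp_uv * env * carrier


def make_background(
    duration_s: float,
    fs: float,
    noise_exponent: float = 1.0,
    noise_amp_uv: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, RMS-scaled.

    Exponent 0 gives white noise.  Shaping is done in the frequency domain
    (the DC component is zeroed); the result is rescaled to RMS
    ``noise_amp_uv`` exactly.
    """
    if noise_exponent < 0:
        raise ValueError("noise_exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    if noise_amp_uv == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-noise_exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (noise_amp_uv / rms) if rms > 0 else x


def kappa_for_as_fraction(as_fraction: float, pref_deg: float = -90.0) -> float:
    """Von Mises concentration giving the target active-state probability.

    With the preference centred in the active state (default -90 deg), the
    AS probability is the von Mises mass of the half-circle around the mean;
    this inverts that relation.  0.5 maps to kappa = 0 (uniform).
    """
    if not 0.5 <= as_fraction < 1.0:
        raise ValueError("as_fraction must lie in [0.5, 1)")
    if as_fraction == 0.5:
        return 0.0
    mu = np.radians(pref_deg)

    def mass(kappa: float) -> float:
        vm = stats.vonmises(kappa, loc=mu)
        lo, hi = np.radians(-180.0), np.radians(0.0)
        return float(vm.cdf(hi) - vm.cdf(lo))

    return float(optimize.brentq(lambda k: mass(k) - as_fraction, 1e-9, 500.0))


def default_state_sequence(duration_s: float, epoch_len_s: float = 4.0) -> list[str]:
    """Repeating wake/NREMS/REMS pattern truncated to the duration.

    One cycle is 60 s WAKE, 240 s NREMS, 40 s REMS — long consolidated NREMS
    bouts (> 20 s) dominate, as in baseline mouse light-phase sleep.
    """
    n_epochs = int(duration_s // epoch_len_s)
    if n_epochs < 1:
        raise ValueError("duration shorter than one epoch")
    per = lambda secs: int(round(secs / epoch_len_s))
    cycle = [WAKE] * per(60) + [NREMS] * per(240) + [REMS] * per(40)
    reps = n_epochs // len(cycle) + 1
    return (cycle * reps)[:n_epochs]


def _so_phase_deg_at(t_rel: np.ndarray | float, so_freq: float) -> np.ndarray | float:
    """SO phase (0 deg = peak) at time relative to bout start."""
    deg = np.asarray(360.0 * so_freq * np.asarray(t_rel, dtype=float))
    return deg - 360.0 * np.ceil((deg - 180.0) / 360.0)


def generate_recording(
    params: SynthParams, seed: int
) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Generate one synthetic LFP channel plus hypnogram and ground truth.

    All randomness flows from one generator stream seeded with ``seed``, so
    identical calls are bit-identical.  Spindle counts follow a Poisson law
    at ``spindle_rate_per_min`` per NREMS bout; each spindle's onset phase is
    drawn first, then a concrete SO cycle is chosen uniformly among the
    cycles where the event fits inside the bout without colliding with an
    already placed event.  An event with no feasible cycle is skipped and
    counted in ``GroundTruth.n_skipped``.
    """
    rng = np.random.default_rng(seed)
    states = params.state_sequence or default_state_sequence(
        params.duration_s, params.epoch_len_s
    )
    hyp = Hypnogram(states=list(states), epoch_len_s=params.epoch_len_s)
    n = int(round(hyp.duration_s * params.fs))
    fs = params.fs

    signal = make_background(
        hyp.duration_s, fs, params.noise_exponent, params.noise_amp_uv, rng
    )

    gt = GroundTruth()
    sp_on: list[float] = []
    sp_off: list[float] = []
    sp_freq: list[float] = []
    sp_phase: list[float] = []
    so_troughs: list[float] = []
    so_peaks: list[float] = []

    bouts = extract_bouts(hyp, NREMS, min_duration_s=0.0)
    for bout in bouts:
        a = int(round(bout.start_s * fs))
        b = int(round(bout.end_s * fs))
        t_rel = np.arange(b - a) / fs
        # SO: cosine peaking at bout start (phase 0 deg)
        if params.so_amp_uv > 0:
            signal[a:b] += params.so_amp_uv * np.cos(
                2 * np.pi * params.so_freq_hz * t_rel
            )
            period = 1.0 / params.so_freq_hz
            k = np.arange(int(np.floor(bout.duration_s / period)) + 1)
            peaks = bout.start_s + k * period
            troughs = bout.start_s + (k + 0.5) * period
            so_peaks.extend(peaks[peaks < bout.end_s])
            so_troughs.extend(troughs[troughs < bout.end_s])
        # delta: band-limited noise, RMS delta_amp
        if params.delta_amp_uv > 0:
            signal[a:b] += _bandlimited_noise(
                b - a, fs, (1.5, 4.0), params.delta_amp_uv, rng
            )
        # spindles
        n_events = rng.poisson(
            params.spindle_rate_per_min * bout.duration_s / 60.0
        )
        gt.n_attempted += int(n_events)
        placed: list[tuple[float, float]] = []
        for _ in range(n_events):
            ok = _place_spindle(params, rng, bout, placed)
            if ok is None:
                gt.n_skipped += 1
                logger.debug("spindle skipped: no feasible placement")
                continue
            onset, dur, freq, phase = ok
            wav = make_spindle_waveform(dur, freq, params.spindle_amp_uv, fs)
            i0 = int(round(onset * fs))
            signal[i0 : i0 + wav.size] += wav
            placed.append((onset, onset + dur))
            sp_on.append(onset)
            sp_off.append(onset + dur)
            sp_freq.append(freq)
            sp_phase.append(phase)

    order = np.argsort(sp_on)
    gt.spindle_onsets_s = np.asarray(sp_on)[order]
    gt.spindle_offsets_s = np.asarray(sp_off)[order]
    gt.spindle_freqs_hz = np.asarray(sp_freq)[order]
    gt.spindle_phases_deg = np.asarray(sp_phase)[order]
    gt.so_trough_times_s = np.asarray(so_troughs)
    gt.so_peak_times_s = np.asarray(so_peaks)

    rec = Recording(signal[np.newaxis, :n], fs=fs, channel_labels=["synthLFP"])
    return rec, hyp, gt


def _bandlimited_noise(
    n: int,
    fs: float,
    band: tuple[float, float],
    rms_uv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (rms_uv / rms) if rms > 0 else x


def _place_spindle(
    params: SynthParams,
    rng: np.random.Generator,
    bout: Bout,
    placed: list[tuple[float, float]],
) -> tuple[float, float, float, float] | None:
    """Draw (onset, duration, frequency, phase) for one spindle, or None.

    The onset phase is drawn unconditionally (von Mises, or uniform for
    kappa = 0); the SO cycle realizing that phase is chosen uniformly among
    the collision-free cycles, which keeps the realized phase distribution
    exactly the drawn one.
    """
    if params.phase_kappa > 0:
        phase = float(
            np.degrees(
                stats.vonmises.rvs(
                    params.phase_kappa,
                    loc=np.radians(params.phase_pref_deg),
                    random_state=rng,
                )
            )
        )
    else:
        phase = float(rng.uniform(-180.0, 180.0))
    phase = phase - 360.0 * np.ceil((phase - 180.0) / 360.0)
    # keep carriers clear of the 9/16 Hz filter transition edges and give
    # every event >= 4 full cycles: injected events are detectable by design
    freq = float(
        np.clip(
            rng.normal(params.spindle_freq_mean_hz, params.spindle_freq_sd_hz),
            9.5,
            15.5,
        )
    )
    dur = float(
        np.clip(
            rng.normal(params.spindle_duration_mean_s, params.spindle_duration_sd_s),
            4.0 / freq,
            None,
        )
    )
    period = 1.0 / params.so_freq_hz
    first = (phase % 360.0) / 360.0 * period  # onset offset within a cycle
    lo = bout.start_s + params.bout_margin_s
    hi = bout.end_s - params.bout_margin_s - dur
    if hi <= lo:
        return None
    n_cycles = int(np.floor(bout.duration_s / period)) + 1
    onsets = bout.start_s + first + period * np.arange(n_cycles)
    feasible = [
        t
        for t in onsets
        if lo <= t <= hi
        and all(
            t + dur + params.min_event_gap_s <= s
            or t >= e + params.min_event_gap_s
            for s, e in placed
        )
    ]
    if not feasible:
        return None
    onset = float(feasible[rng.integers(len(feasible))])
    return onset, dur, freq, phase


# ---------------------------------------------------------------------------
# Genotype-like presets

_PRESETS: dict[str, dict] = {
    # spindle-rich somatosensory cortex, wild-type-like
    "wt_s1": dict(
        spindle_rate_per_min=8.0,
        spindle_amp_uv=60.0,
        so_amp_uv=75.0,
        delta_amp_uv=25.0,
    ),
    # spindle-poor, delta-enriched knockout-like signal
    "ko_s1": dict(
        spindle_rate_per_min=2.0,
        spindle_amp_uv=25.0,
        so_amp_uv=50.0,
        delta_amp_uv=45.0,
    ),
    # prefrontal-like: SO-dominated, weak spindles (no sigma "shoulder")
    "wt_pfc": dict(
        spindle_rate_per_min=3.0,
        spindle_amp_uv=20.0,
        so_amp_uv=85.0,
        delta_amp_uv=25.0,
    ),
}


def preset(name: str) -> SynthParams:
    """Named parameter sets expressing the genotype/area contrasts.

    ``wt_s1``: spindle-rich; ``ko_s1``: spindle-poor with delta power
    overrepresented relative to the SO; ``wt_pfc``: SO-dominated with weak
    spindle activity.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(SynthParams(), **_PRESETS[name])
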