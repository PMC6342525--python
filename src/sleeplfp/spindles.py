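"""Sleep-spindle detection from the sigma-band square-power envelope.

The detector works on one channel at a time, inside consolidated NREMS
bouts:

1. zero-phase FIR band-pass in an enlarged sigma band (9-16 Hz);
2. point-wise squaring, then a 100 ms moving average — the raw squared
   signal oscillates at twice the spindle frequency and would fragment
   events, so a smoothing window shorter than a spindle cycle count but
   longer than one oscillation period is required to read the envelope;
3. threshold = mean + 1.5 x SD (population SD) of the NREMS-restricted
   envelope, one threshold per signal;
4. supra-threshold runs must contain at least 3 full cycles of the
   band-passed signal; accepted runs are extended to the nearest zero
   crossings of the band-passed signal before the onset and after the
   offset;
5. events that overlap or are separated by < 10 ms are fused
   (transitively); events touching the first or last sample of their bout
   are discarded.

Per event, the amplitude is the mean of the squared-power envelope between
onset and offset (uV^2) and the intra-spindle frequency is the peak of the
magnitude FFT within 9-16 Hz, reported only when the peak is distinguishable
(local maximum with magnitude >= 2 x the median in-band magnitude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filters import design_bandpass, zero_phase
from .io import Bout, bout_sample_slice

logger = logging.getLogger(__name__)

SIGMA_BAND = (9.0, 16.0)


@dataclass
class SpindleEvent:
    """One detected spindle; times in seconds, half-open [onset, offset)."""

    onset_s: float
    offset_s: float
    amplitude_uv2: float = float("nan")
    intra_freq_hz: float | None = None
    channel: str = "ch0"
    bout_id: int = -1

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("spindle offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def sigma_filter(trace: np.ndarray, fs: float, band: tuple[float, float] = SIGMA_BAND) -> np.ndarray:
    """Zero-phase FIR band-pass of the raw trace in the (enlarged) sigma band."""
    return zero_phase(design_bandpass(fs, band), trace)


def sigma_envelope(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = SIGMA_BAND,
    smooth_ms: float = 100.0,
    filtered: np.ndarray | None = None,
) -> np.ndarray:
    """Squared sigma-band power envelope, same length as the input.

    Pass ``filtered`` to reuse an existing band-passed trace.  Smoothing is a
    centered boxcar of ``smooth_ms`` milliseconds; 0 disables it.
    """
    if filtered is None:
        filtered = sigma_filter(trace, fs, band)
    sq = filtered**2
    n_smooth = int(round(smooth_ms * 1e-3 * fs))
    if n_smooth <= 1:
        return sq
    kernel = np.ones(n_smooth) / n_smooth
    # reflect-pad so the envelope has no edge dip of half a kernel
    pad = n_smooth // 2
    padded = np.pad(sq, pad, mode="reflect")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + sq.size]
    return out


def compute_threshold(nrems_envelope: np.ndarray) -> float:
    """Detection threshold: mean + 1.5 x SD of the NREMS-restricted envelope.

    Population SD, no rounding.  The caller restricts the envelope to NREMS
    samples (concatenated over all bouts of the recording).
    """
    env = np.asarray(nrems_envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty NREMS envelope")
    return float(env.mean() + 1.5 * env.std(ddof=0))


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    """Indices i such that the sign of x changes between i-1 and i (zeros
    count as positive)."""
    s = np.where(x >= 0, 1, -1)
    return np.flatnonzero(s[1:] != s[:-1]) + 1


def _runs_above(env: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Half-open index ranges where env > threshold."""
    above = env > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(env.size)
    return list(zip(starts, stops))


def detect_events(
    filtered: np.ndarray,
    envelope: np.ndarray,
    threshold: float,
    bouts: Sequence[Bout],
    fs: float,
    min_cycles: int = 3,
    fuse_gap_s: float = 0.010,
    channel: str = "ch0",
    min_duration_s: float | None = None,
) -> list[SpindleEvent]:
    """Detect spindle events independently inside each bout.

    ``filtered`` and ``envelope`` are full-length arrays aligned to the
    recording time base.  ``min_cycles`` is counted via zero crossings of the
    band-passed signal inside the supra-threshold run; passing
    ``min_duration_s`` instead switches to a fixed minimum duration.
    Amplitude and intra-frequency are filled by the callers that have the
    required traces (see :func:`detect_spindles`).
    """
    events: list[SpindleEvent] = []
    for bout_id, bout in enumerate(sorted(bouts, key=lambda b: b.start_s)):
        sl = bout_sample_slice(bout, fs)
        f = filtered[sl]
        env = envelope[sl]
        zc = _zero_crossings(f)
        raw: list[tuple[int, int]] = []
        for a, b in _runs_above(env, threshold):
            if min_duration_s is not None:
                if (b - a) / fs < min_duration_s:
                    continue
            else:
                # k crossings bound k-1 half-cycles; >= min_cycles full cycles
                k = np.count_nonzero((zc >= a) & (zc <= b))
                if (k - 1) < 2 * min_cycles:
                    continue
            # extend to nearest band-pass zero crossing outside the run
            before = zc[zc <= a]
            after = zc[zc >= b]
            onset = int(before[-1]) if before.size else 0
            offset = int(after[0]) if after.size else f.size
            raw.append((onset, offset))
        # fuse overlapping or near-adjacent events, transitively
        raw.sort()
        fused: list[list[int]] = []
        gap = fuse_gap_s * fs
        for onset, offset in raw:
            if fused and onset - fused[-1][1] < gap:
                fused[-1][1] = max(fused[-1][1], offset)
            else:
                fused.append([onset, offset])
        for onset, offset in fused:
            if onset <= 0 or offset >= f.size:
                continue  # touches bout edge
            events.append(
                SpindleEvent(
                    onset_s=bout.start_s + onset / fs,
                    offset_s=bout.start_s + offset / fs,
                    channel=channel,
                    bout_id=bout_id,
                )
            )
    return events


def spindle_amplitude(event: SpindleEvent, envelope: np.ndarray, fs: float) -> float:
    """Mean sigma square-power (uV^2) over [onset, offset)."""
    a = int(round(event.onset_s * fs))
    b = int(round(event.offset_s * fs))
    if a < 0 or b > envelope.size:
        raise ValueError("event outside envelope extent")
    return float(envelope[a:b].mean())


def intra_spindle_frequency(
    event: SpindleEvent,
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = SIGMA_BAND,
    resolution_hz: float = 0.25,
    prominence_ratio: float = 2.0,
) -> float | None:
    """Peak frequency of the event's magnitude FFT within the sigma band.

    ``trace`` is normally the band-passed signal (less slow-wave leakage); a
    raw-trace mode is simply passing the raw signal.  The segment is
    mean-removed and zero-padded to at least ``1/resolution_hz`` seconds.
    Returns None when the in-band maximum is not a distinguishable peak,
    defined as a local maximum whose magnitude is at least
    ``prominence_ratio`` times the median in-band magnitude.
    """
    a = int(round(event.onset_s * fs))
    b = int(round(event.offset_s * fs))
    seg = np.asarray(trace[a:b], dtype=float)
    if seg.size < 2:
        return None
    seg = seg - seg.mean()
    nfft = max(seg.size, int(round(fs / resolution_hz)))
    mag = np.abs(np.fft.rfft(seg, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_mag = mag[in_band]
    band_freqs = freqs[in_band]
    k = int(np.argmax(band_mag))
    med = float(np.median(band_mag))
    if med > 0 and band_mag[k] < prominence_ratio * med:
        return None
    # local-maximum check against full-spectrum neighbours
    gk = int(np.flatnonzero(in_band)[k])
    left = mag[gk - 1] if gk > 0 else -np.inf
    right = mag[gk + 1] if gk + 1 < mag.size else -np.inf
    if not (mag[gk] >= left and mag[gk] >= right):
        return None
    return float(band_freqs[k])


def detect_spindles(
    trace: np.ndarray,
    fs: float,
    bouts: Sequence[Bout],
    band: tuple[float, float] = SIGMA_BAND,
    smooth_ms: float = 100.0,
    min_cycles: int = 3,
    fuse_gap_s: float = 0.010,
    channel: str = "ch0",
) -> list[SpindleEvent]:
    """Full spindle-detection pipeline on one channel.

    Filters, builds the envelope, computes the NREMS threshold, detects and
    characterizes events (amplitude in uV^2, intra-spindle frequency in Hz
    where distinguishable).
    """
    filtered = sigma_filter(trace, fs, band)
    envelope = sigma_envelope(trace, fs, band, smooth_ms, filtered=filtered)
    nrems = np.concatenate(
        [envelope[bout_sample_slice(b, fs)] for b in bouts]
    ) if bouts else np.empty(0)
    threshold = compute_threshold(nrems)
    events = detect_events(
        filtered, envelope, threshold, bouts, fs,
        min_cycles=min_cycles, fuse_gap_s=fuse_gap_s, channel=channel,
    )
    for ev in events:
        ev.amplitude_uv2 = spindle_amplitude(ev, envelope, fs)
        ev.intra_freq_hz = intra_spindle_frequency(ev, filtered, fs, band)
    logger.info("detected %d spindles on %s (threshold %.3g uV^2)",
                len(events), channel, threshold)
    return events
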