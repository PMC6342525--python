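"""Slow-oscillation (SO) detection as trough-to-peak half-wave pairs.

The signal is 2 Hz low-pass filtered (zero-phase FIR).  Zero crossings
delimit half-waves; every negative half-wave followed by a positive
half-wave yields a candidate with trough (x1, y1) and peak (x2, y2).  With
the per-recording mean trough Y1 and mean peak Y2 over all candidates, a
candidate is accepted as an SO when

1. the trough-to-peak time x2 - x1 lies in [0.5, 2] s (bounds inclusive),
2. its trough is deeper than 2/3 of the mean trough (y1 < 2/3 * Y1; both
   negative, "lower" meaning more negative),
3. its trough-to-peak amplitude reaches 2/3 of the mean amplitude
   (y2 - y1 >= 2/3 * (Y2 - Y1)).

All three criteria are ratios of amplitudes or absolute times, so the
selected set is invariant under rescaling of the trace.  The SO *period*
used for spindle overlap and phase extraction spans from the zero crossing
before the trough to the zero crossing after the peak, i.e. one full cycle
of the oscillation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filters import design_lowpass, zero_phase
from .io import Bout, bout_sample_slice

logger = logging.getLogger(__name__)

SO_LOWPASS_HZ = 2.0
TROUGH_TO_PEAK_RANGE_S = (0.5, 2.0)


@dataclass
class SOCandidate:
    """One trough-then-peak half-wave pair delimited by zero crossings."""

    x1_s: float  # trough time
    y1_uv: float  # trough value (negative)
    x2_s: float  # peak time
    y2_uv: float  # peak value (positive)
    zc_pre_s: float  # zero crossing before the trough
    zc_post_s: float  # zero crossing after the peak
    bout_id: int = -1


@dataclass
class SOEvent:
    """Accepted slow-oscillation cycle with its period extent."""

    x1_s: float
    y1_uv: float
    x2_s: float
    y2_uv: float
    period_start_s: float
    period_end_s: float
    bout_id: int = -1

    @property
    def duration_s(self) -> float:
        return self.period_end_s - self.period_start_s


@dataclass
class SOSummary:
    """Recording-level candidate statistics used by the selection criteria."""

    mean_trough_uv: float  # Y1
    mean_peak_uv: float  # Y2
    n_candidates: int
    n_selected: int


def lowpass_2hz(trace: np.ndarray, fs: float, cutoff_hz: float = SO_LOWPASS_HZ) -> np.ndarray:
    """Zero-phase 2 Hz low-pass of the raw trace, same length."""
    return zero_phase(design_lowpass(fs, cutoff_hz), trace)


def _sign_change_indices(x: np.ndarray) -> np.ndarray:
    s = np.where(x >= 0, 1, -1)
    return np.flatnonzero(s[1:] != s[:-1]) + 1


def find_candidates(
    filtered: np.ndarray,
    fs: float,
    bouts: Sequence[Bout],
) -> list[SOCandidate]:
    """Enumerate trough-then-peak candidates per bout.

    ``filtered`` is the full-length low-passed trace; candidates never span a
    bout boundary, and leading/trailing half-waves not delimited by zero
    crossings on both sides are ignored.
    """
    out: list[SOCandidate] = []
    for bout_id, bout in enumerate(sorted(bouts, key=lambda b: b.start_s)):
        sl = bout_sample_slice(bout, fs)
        x = filtered[sl]
        zc = _sign_change_indices(x)
        for i in range(len(zc) - 2):
            a, b, c = zc[i], zc[i + 1], zc[i + 2]
            neg = x[a:b]
            pos = x[b:c]
            # half-waves between sign changes are single-signed; keep only
            # the trough-then-peak ordering (negative followed by positive)
            if neg.size == 0 or pos.size == 0 or neg[0] >= 0 or pos[0] < 0:
                continue
            i1 = a + int(np.argmin(neg))
            i2 = b + int(np.argmax(pos))
            out.append(
                SOCandidate(
                    x1_s=bout.start_s + i1 / fs,
                    y1_uv=float(x[i1]),
                    x2_s=bout.start_s + i2 / fs,
                    y2_uv=float(x[i2]),
                    zc_pre_s=bout.start_s + a / fs,
                    zc_post_s=bout.start_s + c / fs,
                    bout_id=bout_id,
                )
            )
    return out


def select_so(
    candidates: Sequence[SOCandidate],
    trough_to_peak_range_s: tuple[float, float] = TROUGH_TO_PEAK_RANGE_S,
    amplitude_fraction: float = 2.0 / 3.0,
) -> tuple[list[SOEvent], SOSummary]:
    """Apply the three SO-selection constraints to the candidate list.

    The mean trough Y1 and mean peak Y2 are computed over *all* candidates
    of the recording's NREMS (a single per-recording statistic, not per
    bout).  Returns the accepted events plus the summary statistics.
    """
    if not candidates:
        logger.warning("no SO candidates; Y1/Y2 undefined")
        return [], SOSummary(float("nan"), float("nan"), 0, 0)
    y1s = np.array([c.y1_uv for c in candidates])
    y2s = np.array([c.y2_uv for c in candidates])
    Y1 = float(y1s.mean())
    Y2 = float(y2s.mean())
    lo, hi = trough_to_peak_range_s
    events: list[SOEvent] = []
    for c in candidates:
        dt = c.x2_s - c.x1_s
        if not (lo <= dt <= hi):
            continue
        if not (c.y1_uv < amplitude_fraction * Y1):
            continue
        if not (c.y2_uv - c.y1_uv >= amplitude_fraction * (Y2 - Y1)):
            continue
        events.append(
            SOEvent(
                x1_s=c.x1_s, y1_uv=c.y1_uv, x2_s=c.x2_s, y2_uv=c.y2_uv,
                period_start_s=c.zc_pre_s, period_end_s=c.zc_post_s,
                bout_id=c.bout_id,
            )
        )
    return events, SOSummary(Y1, Y2, len(candidates), len(events))


def detect_so(
    trace: np.ndarray,
    fs: float,
    bouts: Sequence[Bout],
) -> tuple[list[SOEvent], SOSummary, np.ndarray]:
    """Full SO pipeline: low-pass, candidate scan, selection.

    Returns the events, the candidate summary and the low-passed trace (the
    latter is reused by the phase-coupling stage).
    """
    filtered = lowpass_2hz(trace, fs)
    candidates = find_candidates(filtered, fs, bouts)
    events, summary = select_so(candidates)
    logger.info("SO detection: %d/%d candidates selected",
                summary.n_selected, summary.n_candidates)
    return events, summary, filtered
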