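"""Phase-locking of spindle onsets to the slow oscillation.

Phase is the angle of the analytic signal (Hilbert transform) of the 2 Hz
low-passed trace, computed over whole NREMS bouts so that edge distortion is
confined to bout margins.  The convention places 0 deg at the SO positive
peak and +/-180 deg at the trough, so the rising trough-to-peak segment
spans (-180, 0) — the cortical active state (AS) — and the falling segment
[0, 180] is the silent state (SS).  Recordings with inverted polarity can
flip the mapping with ``invert_polarity``.

Only spindles that lie (almost) entirely within detected SO periods take
part: a spindle is included when at least 95% of its duration is covered by
the union of SO periods, and it is paired with the single SO event of
maximal overlap (earlier event on ties).  Consecutive SO cycles produce
abutting periods, so the union — rather than a single period — is the
operative notion of "being inside the SO".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .io import Bout, bout_sample_slice
from .so import SOEvent
from .spindles import SpindleEvent

OVERLAP_MIN = 0.95


@dataclass
class CouplingResult:
    """Per-spindle SO phases plus the derived summaries."""

    phases_deg: np.ndarray
    included: list[SpindleEvent]
    paired_so: list[SOEvent]
    n_excluded: int
    hist_edges_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    hist_occurrence_pct: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def as_fraction(self) -> float:
        return as_ss_fractions(self.phases_deg)[0]

    @property
    def ss_fraction(self) -> float:
        return as_ss_fractions(self.phases_deg)[1]


def wrap_deg(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    out = np.asarray(deg, dtype=float)
    out = out - 360.0 * np.ceil((out - 180.0) / 360.0)
    return float(out) if out.ndim == 0 else out


def overlap_filter(
    spindles: Sequence[SpindleEvent],
    so_events: Sequence[SOEvent],
    min_overlap: float = OVERLAP_MIN,
) -> tuple[list[SpindleEvent], list[SOEvent], int]:
    """Keep spindles covered >= ``min_overlap`` of their duration by SO
    periods; pair each with the maximally overlapping SO event.

    Returns (included spindles, paired SO events, number excluded).
    """
    periods = sorted(so_events, key=lambda e: e.period_start_s)
    included: list[SpindleEvent] = []
    paired: list[SOEvent] = []
    n_excluded = 0
    for sp in spindles:
        total = 0.0
        best: SOEvent | None = None
        best_ov = 0.0
        for so in periods:
            ov = min(sp.offset_s, so.period_end_s) - max(sp.onset_s, so.period_start_s)
            if ov <= 0:
                continue
            total += ov
            if ov > best_ov:  # strict: ties keep the earlier event
                best_ov = ov
                best = so
        if best is not None and total / sp.duration_s >= min_overlap:
            included.append(sp)
            paired.append(best)
        else:
            n_excluded += 1
    return included, paired, n_excluded


def hilbert_phase_deg(filtered_bout: np.ndarray, invert_polarity: bool = False) -> np.ndarray:
    """Instantaneous phase (degrees, (-180, 180]) of a low-passed bout trace.

    0 deg at the positive peak, +/-180 deg at the trough.  With
    ``invert_polarity`` the trace sign is flipped before the transform.
    """
    x = np.asarray(filtered_bout, dtype=float)
    if invert_polarity:
        x = -x
    return wrap_deg(np.degrees(np.angle(hilbert(x))))


def so_phase_at(
    filtered: np.ndarray,
    fs: float,
    time_s: float,
    so_event: SOEvent,
    bout: Bout | None = None,
    invert_polarity: bool = False,
) -> float:
    """SO phase at one time point inside the event's period.

    ``filtered`` is the full-length low-passed trace; the Hilbert transform
    is taken over ``bout`` when given (preferred: long segments minimise
    edge effects), otherwise over the SO period alone.
    """
    if not (so_event.period_start_s <= time_s <= so_event.period_end_s):
        raise ValueError(
            f"time {time_s} s outside SO period "
            f"[{so_event.period_start_s}, {so_event.period_end_s}] s"
        )
    if bout is not None:
        a = int(round(bout.start_s * fs))
        b = int(round(bout.end_s * fs))
    else:
        a = int(round(so_event.period_start_s * fs))
        b = int(round(so_event.period_end_s * fs))
    phases = hilbert_phase_deg(filtered[a:b], invert_polarity)
    i = int(round(time_s * fs)) - a
    i = min(max(i, 0), phases.size - 1)
    return float(phases[i])


def phase_histogram(
    phases_deg: np.ndarray, bin_deg: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence (% of spindles) per phase bin; bins tile (-180, 180].

    Returns (edges, occurrence); edges have one more element than counts.
    An empty phase list yields zero-length occurrence, not an error.
    """
    if 360.0 % bin_deg:
        raise ValueError(f"bin width {bin_deg} deg must divide 360")
    n_bins = int(round(360.0 / bin_deg))
    edges = -180.0 + bin_deg * np.arange(n_bins + 1)
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        return edges, np.empty(0)
    # half-open (lo, hi] bins: right-inclusive digitize
    idx = np.digitize(phases, edges, right=True) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return edges, counts * (100.0 / phases.size)


def as_ss_fractions(phases_deg: np.ndarray) -> tuple[float, float]:
    """Fractions of phases in the active ((-180, 0)) and silent ([0, 180])
    states; boundary phases 0 and 180 deg count as silent."""
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases: AS/SS fractions undefined")
    as_frac = float(np.mean(phases < 0))
    return as_frac, 1.0 - as_frac


def couple(
    spindles: Sequence[SpindleEvent],
    so_events: Sequence[SOEvent],
    so_filtered: np.ndarray,
    fs: float,
    bouts: Sequence[Bout],
    bin_deg: float = 30.0,
    invert_polarity: bool = False,
) -> CouplingResult:
    """Full coupling stage: overlap filter, onset phases, histogram.

    The Hilbert phase is evaluated per bout on the low-passed trace
    ``so_filtered`` (full recording length).
    """
    included, paired, n_excluded = overlap_filter(spindles, so_events)
    bouts = sorted(bouts, key=lambda b: b.start_s)
    bout_phases: dict[int, np.ndarray] = {}
    phases = np.empty(len(included))
    for k, sp in enumerate(included):
        bid = next(
            (i for i, b in enumerate(bouts) if b.start_s <= sp.onset_s < b.end_s),
            None,
        )
        if bid is None:
            raise ValueError(f"spindle at {sp.onset_s} s lies in no bout")
        if bid not in bout_phases:
            bout_phases[bid] = hilbert_phase_deg(
                so_filtered[bout_sample_slice(bouts[bid], fs)], invert_polarity
            )
        i = int(round((sp.onset_s - bouts[bid].start_s) * fs))
        phases[k] = bout_phases[bid][min(i, bout_phases[bid].size - 1)]
    edges, occ = phase_histogram(phases, bin_deg)
    return CouplingResult(
        phases_deg=phases,
        included=list(included),
        paired_so=list(paired),
        n_excluded=n_excluded,
        hist_edges_deg=edges,
        hist_occurrence_pct=occ,
    )
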