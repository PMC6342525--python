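"""Zero-phase FIR filtering used by the spindle and slow-oscillation stages.

All filters are linear-phase FIR designs (Hamming window, ~53 dB stop-band
attenuation) applied forward-backward with :func:`scipy.signal.filtfilt`, so
event timing is not skewed by filter delay.  Tap counts are set from the
requested transition width (``numtaps ~ 3.3 * fs / transition``), the usual
Hamming-window rule of thumb.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def design_bandpass(fs: float, band: tuple[float, float], transition_hz: float = 2.0) -> np.ndarray:
    """Band-pass FIR taps for ``band`` (Hz) at sampling rate ``fs``."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if fs <= 2 * hi:
        raise ValueError(f"fs={fs} Hz too low for band upper edge {hi} Hz")
    numtaps = _odd(int(np.ceil(3.3 * fs / transition_hz)))
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def design_lowpass(fs: float, cutoff_hz: float, transition_hz: float = 1.0) -> np.ndarray:
    """Low-pass FIR taps with the given cutoff."""
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"fs={fs} Hz too low for a {cutoff_hz} Hz low-pass")
    numtaps = _odd(int(np.ceil(3.3 * fs / transition_hz)))
    return signal.firwin(numtaps, cutoff_hz, fs=fs)


def zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward application of FIR ``taps``; output length = input.

    The default reflect padding is capped at the signal length so short test
    traces remain filterable; edge samples are then less accurate, which is
    acceptable because bout margins are excluded by the event-edge rules.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short to filter")
    padlen = min(3 * len(taps), x.size - 1)
    return signal.filtfilt(taps, [1.0], x, padlen=padlen)
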