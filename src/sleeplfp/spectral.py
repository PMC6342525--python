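"""State-restricted power spectra, normalized band powers and the delta-power
time course.

The spectral estimate is deliberately plain: non-overlapping rectangular 4 s
windows tiled inside each bout (never spanning a bout boundary), per-window
mean subtraction, squared-magnitude FFT, averaged over all windows.  With 4 s
windows the frequency grid has 0.25 Hz resolution.  Spectra are normalized to
their 0-35 Hz sum and expressed in percent, which removes between-animal
amplitude differences; band powers are integrals of that normalized density.

Default band edges: slow oscillation (SO) 0.5-1.5 Hz, delta 1.5-4 Hz, sigma
10-15 Hz.  A bin sitting exactly on a shared edge is assigned to the lower
band only (bands are half-open ``(lo, hi]``), so the named bands partition
the frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Default frequency-band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "SO": (0.5, 1.5),
    "delta": (1.5, 4.0),
    "sigma": (10.0, 15.0),
}

#: Upper bound (Hz, inclusive) of the normalization range.
NORM_FMAX = 35.0


@dataclass
class PowerSpectrum:
    """Frequency grid plus spectral density averaged over windows.

    ``density`` is in uV^2 units for a raw spectrum and in percent of the
    0-35 Hz sum after :func:`normalize_spectrum` (``normalized`` flag).
    """

    freqs: np.ndarray
    density: np.ndarray
    n_windows: int
    normalized: bool = False

    def band_power(self, band: str | tuple[float, float]) -> float:
        edges = BANDS[band] if isinstance(band, str) else band
        return band_power(self, edges)


def power_spectrum(
    segments: Sequence[np.ndarray] | np.ndarray,
    fs: float,
    window_s: float = 4.0,
) -> PowerSpectrum:
    """Average squared-FFT spectrum over non-overlapping windows.

    Each segment is tiled with consecutive ``window_s`` windows; remainder
    samples at the end of a segment are dropped.  Each window has its mean
    subtracted (offset correction) before the FFT.  The one-sided density is
    scaled so that its sum equals the mean-square of the (mean-removed)
    window signal — a Parseval-consistent convention that makes the
    normalization step scale-free.
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 1:
        segments = [segments]
    nwin = int(round(window_s * fs))
    if nwin < 2:
        raise ValueError("window too short")
    windows = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.size < nwin:
            raise ValueError(
                f"segment of {seg.size} samples shorter than one "
                f"{window_s} s window ({nwin} samples)"
            )
        n_full = seg.size // nwin
        windows.extend(seg[i * nwin : (i + 1) * nwin] for i in range(n_full))
    if not windows:
        raise ValueError("no complete analysis window in any segment")

    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    for w in windows:
        w = w - w.mean()
        spec = np.abs(np.fft.rfft(w)) ** 2
        # one-sided scaling: sum over bins == mean(w**2)
        spec *= 2.0 / nwin**2
        spec[0] /= 2.0
        if nwin % 2 == 0:
            spec[-1] /= 2.0
        acc += spec
    return PowerSpectrum(freqs=freqs, density=acc / len(windows), n_windows=len(windows))


def normalize_spectrum(ps: PowerSpectrum, fmax: float = NORM_FMAX) -> PowerSpectrum:
    """Express density as percent of the total power between 0 and ``fmax``
    Hz (bounds inclusive)."""
    mask = (ps.freqs >= 0) & (ps.freqs <= fmax)
    total = ps.density[mask].sum()
    if total <= 0:
        raise ValueError("zero total power in 0-35 Hz; cannot normalize")
    return PowerSpectrum(
        freqs=ps.freqs.copy(),
        density=ps.density * (100.0 / total),
        n_windows=ps.n_windows,
        normalized=True,
    )


def band_power(ps: PowerSpectrum, edges: tuple[float, float]) -> float:
    """Integral (bin sum) of the density over the half-open band ``(lo, hi]``.

    The half-open convention assigns a bin lying exactly on a shared border
    (e.g. 1.5 Hz between the SO and delta bands) to the lower band only.
    """
    lo, hi = edges
    if hi <= lo:
        raise ValueError(f"inverted band edges {edges}")
    mask = (ps.freqs > lo) & (ps.freqs <= hi)
    return float(ps.density[mask].sum())


# ---------------------------------------------------------------------------
# Delta-power time course (chemogenetic analysis)


@dataclass
class DeltaTimecourse:
    """Delta power binned into equal-epoch-count quantiles of NREMS time.

    Values are normalized by the mean of the first two baseline bins, so a
    flat series maps to 1.0 everywhere.
    """

    baseline: np.ndarray
    post: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.baseline, self.post])


def _quantile_bin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` split, in order, into ``n_bins`` contiguous groups
    of equal count; remainder epochs go to the earliest bins."""
    n = values.size
    if n < n_bins:
        raise ValueError(f"{n} epochs cannot fill {n_bins} bins")
    base, extra = divmod(n, n_bins)
    out = np.empty(n_bins)
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < extra else 0)
        out[i] = values[start : start + size].mean()
        start += size
    return out


def delta_timecourse(
    baseline_epoch_power: np.ndarray,
    post_epoch_power: np.ndarray,
    n_base_bins: int = 12,
    n_post_bins: int = 36,
) -> DeltaTimecourse:
    """Bin per-epoch delta power into NREMS quantiles and normalize.

    Inputs are per-4 s-epoch delta band powers from consolidated NREMS, in
    temporal order, split at the intervention time.  Each side is partitioned
    into bins holding identical numbers of NREMS epochs (quantiles of NREMS
    time, not of clock time); every bin is then divided by the mean of the
    first two baseline bins.
    """
    base = _quantile_bin(np.asarray(baseline_epoch_power, dtype=float), n_base_bins)
    post = _quantile_bin(np.asarray(post_epoch_power, dtype=float), n_post_bins)
    ref = base[:2].mean()
    if ref <= 0:
        raise ValueError("non-positive baseline reference power")
    return DeltaTimecourse(baseline=base / ref, post=post / ref)


def epoch_band_power(
    segments: Sequence[np.ndarray],
    fs: float,
    edges: tuple[float, float] = BANDS["delta"],
    epoch_len_s: float = 4.0,
) -> np.ndarray:
    """Raw band power (area under the unnormalized spectrum) for each full
    epoch-length window of each segment, concatenated in temporal order."""
    out = []
    nwin = int(round(epoch_len_s * fs))
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        for i in range(seg.size // nwin):
            ps = power_spectrum(seg[i * nwin : (i + 1) * nwin], fs, epoch_len_s)
            out.append(band_power(ps, edges))
    return np.asarray(out)
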