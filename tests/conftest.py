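"""Shared fixtures: tiny synthetic recordings and format helpers.

All fixtures are generated programmatically; no data files ship with the
package.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleeplfp import extract_bouts
from sleeplfp.io import NREMS, WAKE, Hypnogram


def write_minimal_edf(path, data_uv: np.ndarray, fs: int, labels: list[str]) -> None:
    """Hand-rolled single-purpose EDF writer for reader round-trip tests.

    One-second data records, 16-bit little-endian samples, physical range
    +/-5000 uV.  Only what the EDF header requires, nothing more.
    """
    nch, nsamp = data_uv.shape
    spr = int(fs)
    nrec = nsamp // spr
    pmin, pmax = -5000.0, 5000.0
    dmin, dmax = -32768, 32767

    def field(s: str, n: int) -> bytes:
        return s.encode("ascii").ljust(n)[:n]

    hdr = b""
    hdr += field("0", 8) + field("X", 80) + field("X", 80)
    hdr += field("01.01.20", 8) + field("00.00.00", 8)
    hdr += field(str(256 * (1 + nch)), 8) + field("", 44)
    hdr += field(str(nrec), 8) + field("1", 8) + field(str(nch), 4)
    for lab in labels:
        hdr += field(lab, 16)
    for text, width in (("", 80), ("uV", 8), (str(pmin), 8), (str(pmax), 8),
                        (str(dmin), 8), (str(dmax), 8), ("", 80),
                        (str(spr), 8), ("", 32)):
        for _ in labels:
            hdr += field(text, width)
    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            for c in range(nch):
                seg = data_uv[c, r * spr : (r + 1) * spr]
                fh.write(np.round((seg - pmin) * scale + dmin).astype("<i2").tobytes())


def match_events(gt_on, gt_off, detected, min_overlap_frac: float = 0.5):
    """Greedy one-to-one matching of detected events to ground truth.

    A pair matches when the interval intersection is at least
    ``min_overlap_frac`` of the shorter interval.  Returns (n_matched,
    onset-error list in seconds).
    """
    used: set[int] = set()
    n_matched = 0
    onset_errors = []
    for on, off in zip(gt_on, gt_off):
        best, best_ov = None, 0.0
        for j, ev in enumerate(detected):
            if j in used:
                continue
            ov = min(off, ev.offset_s) - max(on, ev.onset_s)
            if ov > best_ov:
                best_ov, best = ov, j
        if best is not None and best_ov >= min_overlap_frac * min(
            off - on, detected[best].duration_s
        ):
            used.add(best)
            n_matched += 1
            onset_errors.append(abs(detected[best].onset_s - on))
    return n_matched, onset_errors


@pytest.fixture
def nrems_hypnogram():
    """One consolidated 120 s NREMS bout flanked by wake (4 s epochs)."""
    return Hypnogram([WAKE] * 3 + [NREMS] * 30 + [WAKE] * 3)


@pytest.fixture
def single_nrems_bout(nrems_hypnogram):
    return extract_bouts(nrems_hypnogram, NREMS, 20.0)
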