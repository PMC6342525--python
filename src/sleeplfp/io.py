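"""Data model and file I/O for recordings, hypnograms and detected events.

Recordings are continuous multi-channel extracellular signals in microvolts.
Hypnograms label fixed-length epochs (default 4 s) with a vigilance state;
consolidated bouts of a state are the unit on which every downstream analysis
operates.  Supported on-disk formats: European Data Format (EDF, read via
:mod:`mne`), delimited text with a JSON sidecar, and a raw binary matrix with
the same sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised vigilance-state codes.
WAKE = "WAKE"
NREMS = "NREMS"
REMS = "REMS"
ARTIFACT = "ARTIFACT"
STATES = (WAKE, NREMS, REMS, ARTIFACT)


@dataclass
class Recording:
    """Continuous multi-channel signal in microvolts.

    ``samples`` has shape (n_channels, n_samples); all channels share one
    sampling rate ``fs``.  Sample ``i`` maps to time ``start_time_s + i / fs``
    (0-based indices, half-open intervals throughout the package).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label_or_index: str | int) -> np.ndarray:
        """Return one channel as a 1-D array."""
        if isinstance(label_or_index, str):
            idx = self.channel_labels.index(label_or_index)
        else:
            idx = int(label_or_index)
        return self.samples[idx]


@dataclass
class Hypnogram:
    """Epoch-wise vigilance states; epochs are contiguous from time zero."""

    states: list[str]
    epoch_len_s: float = 4.0

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        bad = sorted(set(self.states) - set(STATES))
        if bad:
            raise ValueError(f"unknown state codes: {bad}")

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive same-state epochs, half-open [start, end)."""

    state: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from ``edf``, ``tsv`` or ``binary_matrix`` format.

    ``tsv`` files hold one column per channel and require a JSON sidecar
    ``<path>.json`` with at least ``{"fs": ..., "channel_labels": [...]}``.
    ``binary_matrix`` is raw little-endian values, channel-major, with the
    same sidecar plus ``n_channels`` and optional ``dtype`` (default
    float32).  ``format`` is inferred from the extension if omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".edf": "edf", ".tsv": "tsv", ".bin": "binary_matrix"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if format == "edf":
        return _read_edf(path)
    if format == "tsv":
        meta = _read_sidecar(path)
        df = pd.read_csv(path, sep="\t")
        samples = df.to_numpy(dtype=float).T
        labels = meta.get("channel_labels", list(df.columns))
        return Recording(samples, fs=float(meta["fs"]), channel_labels=list(labels))
    if format == "binary_matrix":
        meta = _read_sidecar(path)
        if "n_channels" not in meta:
            raise ValueError(f"sidecar for {path} lacks 'n_channels'")
        dtype = np.dtype(meta.get("dtype", "float32")).newbyteorder("<")
        flat = np.fromfile(path, dtype=dtype)
        nch = int(meta["n_channels"])
        if flat.size % nch:
            raise ValueError(
                f"{path}: {flat.size} values not divisible by {nch} channels"
            )
        samples = flat.reshape(nch, -1).astype(float)
        labels = meta.get("channel_labels", [])
        return Recording(samples, fs=float(meta["fs"]), channel_labels=list(labels))
    raise ValueError(f"unknown recording format {format!r}")


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar} (required for fs/channel metadata)"
        )
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required key 'fs'")
    return meta


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: heavy import, EDF-only dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    samples = raw.get_data() * 1e6  # mne yields volts; the package works in uV
    return Recording(samples, fs=fs, channel_labels=list(raw.ch_names))


def write_recording_tsv(rec: Recording, path: str | Path) -> None:
    """Write a recording as TSV (one column per channel) plus JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"fs": rec.fs, "channel_labels": rec.channel_labels, "units": "uV"},
            indent=2,
        )
    )


def read_hypnogram(path: str | Path, epoch_len_s: float = 4.0) -> Hypnogram:
    """Read a hypnogram TSV with columns ``epoch_index`` and ``state``.

    Epochs must be contiguous from index 0.  Unknown state strings are mapped
    to ARTIFACT with a logged warning, so a scorer's extra labels degrade to
    discarded epochs instead of crashing the pipeline.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"epoch_index", "state"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns epoch_index, state")
    idx = df["epoch_index"].to_numpy()
    if len(idx) == 0:
        raise ValueError(f"{path}: empty hypnogram")
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(
            f"{path}: epoch indices must be contiguous 0..{len(idx) - 1}"
        )
    states = []
    for s in df["state"].astype(str):
        code = s.strip().upper()
        if code not in STATES:
            logger.warning("unknown state %r mapped to ARTIFACT", s)
            code = ARTIFACT
        states.append(code)
    return Hypnogram(states=states, epoch_len_s=epoch_len_s)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(hyp.n_epochs), "state": hyp.states}
    ).to_csv(path, sep="\t", index=False)


def extract_bouts(
    hyp: Hypnogram, state: str, min_duration_s: float = 0.0
) -> list[Bout]:
    """Maximal runs of consecutive epochs in ``state``, strictly longer than
    ``min_duration_s``.

    The strict inequality implements the consolidated-sleep convention that a
    bout of exactly the minimum length is excluded (e.g. a 20 s NREMS run is
    not "> 20 s").
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    bouts: list[Bout] = []
    run_start = None
    for i, s in enumerate(hyp.states + ["__end__"]):
        if s == state and run_start is None:
            run_start = i
        elif s != state and run_start is not None:
            start_s = run_start * hyp.epoch_len_s
            end_s = i * hyp.epoch_len_s
            if end_s - start_s > min_duration_s:
                bouts.append(Bout(state=state, start_s=start_s, end_s=end_s))
            run_start = None
    return bouts


def bout_sample_slice(bout: Bout, fs: float) -> slice:
    """Half-open sample range of a bout at sampling rate ``fs``."""
    return slice(int(round(bout.start_s * fs)), int(round(bout.end_s * fs)))


def concatenate_state_segments(
    rec: Recording, bouts: Sequence[Bout], channel: str | int = 0
) -> list[np.ndarray]:
    """Per-bout signal slices of one channel, in temporal order.

    Segments are never stitched together: analysis windows must not span a
    bout boundary, so each bout stays a separate array.
    """
    trace = rec.channel(channel)
    segments = []
    for b in sorted(bouts, key=lambda b: b.start_s):
        sl = bout_sample_slice(b, rec.fs)
        if sl.start < 0 or sl.stop > rec.n_samples:
            raise ValueError(
                f"bout [{b.start_s}, {b.end_s}) s exceeds recording extent "
                f"({rec.duration_s:.3f} s)"
            )
        segments.append(trace[sl])
    return segments


# ---------------------------------------------------------------------------
# Event tables

SPINDLE_COLUMNS = [
    "channel",
    "bout_id",
    "onset_s",
    "offset_s",
    "duration_s",
    "amplitude_uv2",
    "intra_freq_hz",
]
SO_COLUMNS = [
    "bout_id",
    "x1_s",
    "y1_uv",
    "x2_s",
    "y2_uv",
    "period_start_s",
    "period_end_s",
]


def write_events(events: Iterable, path: str | Path) -> None:
    """Write spindle or SO events as a TSV table (one row per event).

    Column layout is chosen from the event type; an empty list writes a
    spindle-layout header-only file.  Times round-trip at microsecond
    precision.
    """
    events = list(events)
    from .spindles import SpindleEvent  # local import: avoid cycle
    from .so import SOEvent

    if events and isinstance(events[0], SOEvent):
        rows = [
            {
                "bout_id": e.bout_id,
                "x1_s": e.x1_s,
                "y1_uv": e.y1_uv,
                "x2_s": e.x2_s,
                "y2_uv": e.y2_uv,
                "period_start_s": e.period_start_s,
                "period_end_s": e.period_end_s,
            }
            for e in events
        ]
        df = pd.DataFrame(rows, columns=SO_COLUMNS)
    else:
        rows = [
            {
                "channel": e.channel,
                "bout_id": e.bout_id,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "duration_s": e.offset_s - e.onset_s,
                "amplitude_uv2": e.amplitude_uv2,
                "intra_freq_hz": e.intra_freq_hz,
            }
            for e in events
        ]
        df = pd.DataFrame(rows, columns=SPINDLE_COLUMNS)
        assert all(isinstance(e, SpindleEvent) for e in events)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_spindle_events(path: str | Path) -> list:
    from .spindles import SpindleEvent

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        f = r["intra_freq_hz"]
        out.append(
            SpindleEvent(
                onset_s=float(r["onset_s"]),
                offset_s=float(r["offset_s"]),
                amplitude_uv2=float(r["amplitude_uv2"]),
                intra_freq_hz=None if pd.isna(f) else float(f),
                channel=str(r["channel"]),
                bout_id=int(r["bout_id"]),
            )
        )
    return out


def read_so_events(path: str | Path) -> list:
    from .so import SOEvent

    df = pd.read_csv(path, sep="\t")
    return [
        SOEvent(
            x1_s=float(r["x1_s"]),
            y1_uv=float(r["y1_uv"]),
            x2_s=float(r["x2_s"]),
            y2_uv=float(r["y2_uv"]),
            period_start_s=float(r["period_start_s"]),
            period_end_s=float(r["period_end_s"]),
            bout_id=int(r["bout_id"]),
        )
        for _, r in df.iterrows()
    ]
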