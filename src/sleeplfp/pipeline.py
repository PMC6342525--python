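"""End-to-end orchestration of the NREMS LFP analysis for one recording.

``run_pipeline`` composes the stages — bout extraction, normalized spectrum
and band powers, spindle detection, SO detection, phase coupling — per
channel, writes every stage output (TSV tables plus a machine-readable
summary JSON) and is a pure function of its inputs: rerunning on the same
files yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling as coupling_mod
from . import io, spectral, spindles, so

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated, file-round-trippable pipeline settings."""

    recording: str
    hypnogram: str
    output_dir: str
    recording_format: str | None = None
    group: str = ""
    channels: list[str] | None = None  # None = all channels
    epoch_len_s: float = 4.0
    min_bout_s: float = 20.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in spectral.BANDS.items()}
    )
    spectrum_window_s: float = 4.0
    sigma_band: tuple[float, float] = spindles.SIGMA_BAND
    smooth_ms: float = 100.0
    min_cycles: int = 3
    fuse_gap_s: float = 0.010
    phase_bin_deg: float = 30.0
    invert_polarity: bool = False
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known: {sorted(known)}"
            )
        if raw.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        cfg = cls(**raw)
        cfg.bands = {k: tuple(v) for k, v in cfg.bands.items()}
        cfg.sigma_band = tuple(cfg.sigma_band)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        d["sigma_band"] = list(d["sigma_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write outputs under ``output_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Raises with a stage-tagged message on the first failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"group": config.group, "channels": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = stage("load")
    try:
        rec = io.read_recording(config.recording, config.recording_format)
        hyp = io.read_hypnogram(config.hypnogram, config.epoch_len_s)
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise RuntimeError(f"[load] {e}") from e

    bouts = io.extract_bouts(hyp, io.NREMS, config.min_bout_s)
    if not bouts:
        raise RuntimeError("[bouts] no NREMS bouts longer than "
                           f"{config.min_bout_s} s in hypnogram")
    summary["n_nrems_bouts"] = len(bouts)
    summary["nrems_s"] = sum(b.duration_s for b in bouts)
    logger.info("bouts: %d NREMS bouts, %.0f s (%.2f s elapsed)",
                len(bouts), summary["nrems_s"], time.perf_counter() - t0)

    labels = config.channels or rec.channel_labels
    for label in labels:
        trace = rec.channel(label)
        ch_sum: dict = {}

        stage(f"spectrum[{label}]")
        try:
            segs = io.concatenate_state_segments(rec, bouts, channel=label)
            ps = spectral.normalize_spectrum(
                spectral.power_spectrum(segs, rec.fs, config.spectrum_window_s)
            )
            pd.DataFrame({"freq_hz": ps.freqs, "density_pct": ps.density}).to_csv(
                out / f"spectrum_{label}.tsv", sep="\t", index=False,
                float_format="%.8g",
            )
            ch_sum["band_power_pct"] = {
                name: spectral.band_power(ps, edges)
                for name, edges in config.bands.items()
            }
            ch_sum["n_windows"] = ps.n_windows
        except Exception as e:
            raise RuntimeError(f"[spectrum:{label}] {e}") from e

        stage(f"spindles[{label}]")
        try:
            events = spindles.detect_spindles(
                trace, rec.fs, bouts,
                band=config.sigma_band, smooth_ms=config.smooth_ms,
                min_cycles=config.min_cycles, fuse_gap_s=config.fuse_gap_s,
                channel=str(label),
            )
            io.write_events(events, out / f"spindles_{label}.tsv")
            freqs = [e.intra_freq_hz for e in events if e.intra_freq_hz is not None]
            ch_sum["spindles"] = {
                "n": len(events),
                "density_per_min": 60.0 * len(events) / summary["nrems_s"],
                "amplitude_mean_uv2": float(
                    np.mean([e.amplitude_uv2 for e in events])
                ) if events else None,
                "intra_freq_mean_hz": float(np.mean(freqs)) if freqs else None,
            }
        except Exception as e:
            raise RuntimeError(f"[spindles:{label}] {e}") from e

        stage(f"so[{label}]")
        try:
            so_events, so_summary, so_filtered = so.detect_so(trace, rec.fs, bouts)
            io.write_events(so_events, out / f"so_{label}.tsv")
            ch_sum["so"] = {
                "n": len(so_events),
                "n_candidates": so_summary.n_candidates,
                "mean_trough_uv": so_summary.mean_trough_uv,
                "mean_peak_uv": so_summary.mean_peak_uv,
            }
        except Exception as e:
            raise RuntimeError(f"[so:{label}] {e}") from e

        stage(f"coupling[{label}]")
        try:
            cres = coupling_mod.couple(
                events, so_events, so_filtered, rec.fs, bouts,
                bin_deg=config.phase_bin_deg,
                invert_polarity=config.invert_polarity,
            )
            pd.DataFrame(
                {
                    "onset_s": [e.onset_s for e in cres.included],
                    "phase_deg": cres.phases_deg,
                    "paired_so_x1_s": [e.x1_s for e in cres.paired_so],
                }
            ).to_csv(out / f"coupling_{label}.tsv", sep="\t", index=False,
                     float_format="%.6f")
            ch_sum["coupling"] = {
                "n_included": cres.n_included,
                "n_excluded": cres.n_excluded,
                "as_fraction": cres.as_fraction if cres.n_included else None,
                "ss_fraction": cres.ss_fraction if cres.n_included else None,
                "histogram_edges_deg": cres.hist_edges_deg.tolist(),
                "histogram_pct": cres.hist_occurrence_pct.tolist(),
            }
        except Exception as e:
            raise RuntimeError(f"[coupling:{label}] {e}") from e

        summary["channels"][str(label)] = ch_sum

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
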