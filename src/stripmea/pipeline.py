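"""End-to-end pipeline: config, orchestration, artifact bundle, manifest.

One :func:`run_pipeline` call takes a recording (from disk, or simulated
with ground truth) through filtering, per-electrode spike detection, PCA
sorting, burst and network-burst analysis, and writes the complete artifact
bundle: event tables, cutouts, unit assignments, burst tables, per-electrode
summaries, a raster export and a manifest with checksums.  Identical config
and seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import report as _report
from .bursts import BurstParams, detect_bursts, detect_network_bursts, summarize_electrode
from .detect import DetectionParams, compute_snr, detect_spikes, estimate_noise
from .errors import ConfigurationError
from .io import FilterSpec, Recording, bandpass, read_recording, write_recording
from .simulate import SimulationConfig, simulate_recording, write_config_echo, write_ground_truth
from .sort import SortingParams, sort_electrode, summarize_units

log = logging.getLogger("stripmea")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source.

    Either ``input_path``/``metadata_path`` point at a recorded file pair, or
    ``simulation`` holds a :class:`SimulationConfig` — never both.
    """

    input_path: str | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    sorting: SortingParams = field(default_factory=SortingParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    frame_duration: float | None = None  # defaults to recording duration
    raster_window: tuple[float, float] = (0.0, 60.0)
    seed: int = 0
    apply_filter: bool = True
    zero_phase: bool = False

    def validate(self) -> None:
        has_file = self.input_path is not None
        has_sim = self.simulation is not None
        if has_file == has_sim:
            raise ConfigurationError(
                "exactly one of input_path and simulation must be given "
                f"(got input_path={self.input_path!r}, simulation={'set' if has_sim else 'unset'})"
            )
        if has_file and self.metadata_path is None:
            raise ConfigurationError("metadata_path required with input_path")
        if self.frame_duration is not None and self.frame_duration <= 0:
            raise ConfigurationError("frame_duration must be > 0")


def _build(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; nested blocks map onto the stage params."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("simulation", SimulationConfig),
        ("filter", FilterSpec),
        ("detection", DetectionParams),
        ("sorting", SortingParams),
        ("bursts", BurstParams),
    ):
        if key in kwargs and kwargs[key] is not None:
            block = dict(kwargs[key])
            for tup_key in ("template_ptp_range", "pattern_weights"):
                if tup_key in block:
                    block[tup_key] = tuple(block[tup_key])
            kwargs[key] = _build(cls, block)
    if "raster_window" in kwargs:
        kwargs["raster_window"] = tuple(kwargs["raster_window"])
    cfg = _build(PipelineConfig, kwargs)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    recording: Recording
    events_by_electrode: dict
    assignments: dict
    bursts_by_electrode: dict
    network_bursts_by_strip: dict
    summaries: list
    truth: pd.DataFrame | None
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run the full analysis chain and write the artifact bundle to ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        log.info("simulating recording: %s", config.simulation)
        recording, _units, truth = simulate_recording(config.simulation)
        write_ground_truth(truth, outdir / "ground_truth.csv")
        write_config_echo(config.simulation, outdir / "simulation_config.txt")
        write_recording(
            recording, outdir / "recording.bin", outdir / "recording.meta", dtype="float32"
        )
    else:
        recording = read_recording(config.input_path, config.metadata_path)
    frame_duration = config.frame_duration or recording.duration

    if config.apply_filter:
        recording = bandpass(recording, config.filter, zero_phase=config.zero_phase)
    log.info("recording: %d channels x %.1f s", recording.n_channels, recording.duration)

    fs = recording.sampling_rate
    events_by_electrode: dict[str, list] = {}
    noise_by_electrode: dict[str, float] = {}
    for (strip, electrode), trace in zip(recording.channel_map, recording.samples):
        noise_sd = estimate_noise(trace, config.detection.noise_estimator)
        noise_by_electrode[electrode] = noise_sd
        if noise_sd <= 0:
            events_by_electrode[electrode] = []
            continue
        events = detect_spikes(
            trace, noise_sd, config.detection, fs, electrode_id=electrode,
            start_time=recording.start_time,
        )
        compute_snr(events, noise_sd)
        events_by_electrode[electrode] = events
    n_events = sum(len(v) for v in events_by_electrode.values())
    log.info("detected %d events on %d channels", n_events, recording.n_channels)

    assignments = {}
    unit_tables = {}
    for electrode, events in events_by_electrode.items():
        ua = sort_electrode(events, config.sorting, fs, electrode_id=electrode)
        assignments[electrode] = ua
        unit_tables[electrode] = summarize_units(
            events, ua.unit_labels, frame_duration, config.bursts
        )
    log.info("sorted units: %s", {e: a.n_units for e, a in assignments.items()})

    bursts_by_electrode = {}
    spike_trains = {}
    for electrode, events in events_by_electrode.items():
        times = np.array([e.time for e in events], dtype=float)
        spike_trains[electrode] = times
        bursts_by_electrode[electrode] = detect_bursts(times, config.bursts)

    network_bursts_by_strip = {}
    for strip in sorted({s for s, _ in recording.channel_map}):
        strip_trains = {
            e: spike_trains[e]
            for s, e in recording.channel_map
            if s == strip
        }
        if sum(len(t) > 0 for t in strip_trains.values()) >= 2:
            network_bursts_by_strip[strip] = detect_network_bursts(
                strip_trains, config.bursts, frame_duration
            )
        else:
            network_bursts_by_strip[strip] = []

    summaries = []
    strip_of = {e: s for s, e in recording.channel_map}
    for electrode, events in events_by_electrode.items():
        summaries.append(
            summarize_electrode(
                events,
                unit_tables[electrode],
                bursts_by_electrode[electrode],
                frame_duration,
                electrode_id=electrode,
                strip_id=strip_of[electrode],
                params=config.bursts,
            )
        )

    # ---- write bundle ----
    ev_rows, cut_blocks, unit_rows = [], [], []
    for electrode, events in events_by_electrode.items():
        ua = assignments[electrode]
        for k, e in enumerate(events):
            ev_rows.append(
                {"electrode_id": electrode, "time_s": e.time,
                 "ptp_uv": e.ptp_amplitude, "snr": e.snr}
            )
            cut_blocks.append(e.cutout)
            score = ua.pca_scores[k] if ua.pca_scores.size else np.zeros(2)
            unit_rows.append(
                {"electrode_id": electrode, "event_index": k,
                 "unit_label": ua.unit_labels[k] if ua.unit_labels else "U1",
                 "pc1": float(score[0]),
                 "pc2": float(score[1]) if len(score) > 1 else 0.0}
            )
    pd.DataFrame(ev_rows, columns=["electrode_id", "time_s", "ptp_uv", "snr"]).to_csv(
        outdir / "events.csv", index=False
    )
    cutmat = (
        np.stack(cut_blocks).astype(np.float32)
        if cut_blocks
        else np.zeros((0, config.detection.cutout_samples(fs)), np.float32)
    )
    cutmat.tofile(outdir / "cutouts.f32")
    with open(outdir / "cutouts.index", "w") as fh:
        fh.write(f"n_events={cutmat.shape[0]}\nn_samples={cutmat.shape[1]}\ndtype=float32\n")
    pd.DataFrame(unit_rows, columns=["electrode_id", "event_index", "unit_label", "pc1", "pc2"]).to_csv(
        outdir / "unit_assignments.csv", index=False
    )
    burst_rows = [
        {"electrode_id": e, "start_s": b.start, "end_s": b.end, "n_spikes": b.n_spikes}
        for e, bl in bursts_by_electrode.items()
        for b in bl
    ]
    pd.DataFrame(burst_rows, columns=["electrode_id", "start_s", "end_s", "n_spikes"]).to_csv(
        outdir / "bursts.csv", index=False
    )
    nb_rows = [
        {"strip_id": s, "start_s": nb.start, "end_s": nb.end,
         "n_electrodes": nb.n_electrodes, "electrodes": ";".join(nb.electrodes)}
        for s, nbs in network_bursts_by_strip.items()
        for nb in nbs
    ]
    pd.DataFrame(
        nb_rows, columns=["strip_id", "start_s", "end_s", "n_electrodes", "electrodes"]
    ).to_csv(outdir / "network_bursts.csv", index=False)
    _report.summary_table(summaries).to_csv(outdir / "summary.csv", index=False)
    raster = _report.export_raster(spike_trains, config.raster_window)
    raster.to_csv(outdir / "raster.csv", index=False)

    counts = {
        "n_channels": recording.n_channels,
        "n_events": n_events,
        "n_units": int(sum(a.n_units for a in assignments.values())),
        "n_bursts": int(sum(len(b) for b in bursts_by_electrode.values())),
        "n_network_bursts": int(sum(len(v) for v in network_bursts_by_strip.values())),
    }
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "frame_duration_s": frame_duration,
        "pattern_thresholds": {
            "slow_rate_hz": config.bursts.slow_rate_hz,
            "burst_fraction": config.bursts.burst_fraction,
        },
        "counts": counts,
        "files": {},
    }
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("bundle written to %s: %s", outdir, counts)

    return PipelineResult(
        recording=recording,
        events_by_electrode=events_by_electrode,
        assignments=assignments,
        bursts_by_electrode=bursts_by_electrode,
        network_bursts_by_strip=network_bursts_by_strip,
        summaries=summaries,
        truth=truth,
        manifest=manifest,
    )
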