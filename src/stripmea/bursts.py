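"""Burst detection, network bursts, firing-pattern labels and per-electrode summaries.

A burst is a series of at least three consecutive spikes firing no more than
50 ms apart from each other; bursts here are the *maximal* runs of spikes
whose successive inter-spike intervals all satisfy the criterion (the 7-9
mean spikes per burst reported for these tissues requires extending runs
past the 3-spike trigger).

Network bursts are computed with a transparent binned-participation rule:
time is cut into short bins (25 ms default) and a network burst is a maximal
run of bins during which at least half of the active electrodes are either
inside a single-electrode burst or fire in the bin.  The rule and both
parameters are exposed because no standard exists for 3D tissue.

Firing-pattern labels follow a simple, configurable rule: a train is *Slow*
below 0.1 Hz mean rate, *Bursting* when at least half of its spikes fall
inside bursts, and *Irregular* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError

__all__ = [
    "BurstParams",
    "Burst",
    "NetworkBurst",
    "ElectrodeSummary",
    "detect_bursts",
    "burst_statistics",
    "detect_network_bursts",
    "classify_pattern",
    "summarize_electrode",
]


@dataclass(frozen=True)
class BurstParams:
    """Burst and network-burst detection parameters.

    max_isi_ms : maximal inter-spike interval inside a burst (50 ms).
    min_spikes : minimal run length to count as a burst (3).
    network_bin_ms : bin width for the network participation raster.
    network_fraction : fraction of active electrodes required per bin.
    slow_rate_hz / burst_fraction : pattern-classification thresholds.
    """

    max_isi_ms: float = 50.0
    min_spikes: int = 3
    network_bin_ms: float = 25.0
    network_fraction: float = 0.5
    slow_rate_hz: float = 0.1
    burst_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.max_isi_ms <= 0:
            raise ConfigurationError("max_isi_ms must be > 0")
        if self.min_spikes < 2:
            raise ConfigurationError("min_spikes must be >= 2")
        if not (0 < self.network_fraction <= 1):
            raise ConfigurationError("network_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Burst:
    """One maximal run of spikes with all internal ISIs within the criterion."""

    start: float  # first spike time, s
    end: float  # last spike time, s
    n_spikes: int
    first_index: int  # index of the first spike in the source train

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def intra_rate(self) -> float:
        """Spike rate inside the burst, Hz (n_spikes / duration)."""
        return self.n_spikes / self.duration if self.duration > 0 else float("inf")

    @property
    def spike_indices(self) -> range:
        return range(self.first_index, self.first_index + self.n_spikes)


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    electrodes: tuple[str, ...]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)


def detect_bursts(spike_times, params: BurstParams | None = None) -> list[Burst]:
    """Find all maximal runs of >= ``min_spikes`` spikes with ISIs <= ``max_isi_ms``.

    ``spike_times`` must be strictly increasing (seconds); violating that is a
    :class:`ContractError`, not silently tolerated, because downstream
    statistics assume ordered disjoint bursts.
    """
    params = params or BurstParams()
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ContractError("spike_times must be 1-D")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ContractError("spike_times must be strictly increasing")
    if t.size < params.min_spikes:
        return []
    ok = np.diff(t) <= params.max_isi_ms / 1000.0
    bursts: list[Burst] = []
    i = 0
    n_isi = ok.size
    while i < n_isi:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n_isi and ok[j]:
            j += 1
        n_run = j - i + 1  # spikes i .. j inclusive
        if n_run >= params.min_spikes:
            bursts.append(Burst(start=t[i], end=t[j], n_spikes=n_run, first_index=i))
        i = j + 1
    return bursts


def burst_statistics(bursts: list[Burst], frame_duration: float) -> dict:
    """Aggregate burst metrics over one recording frame.

    Zero-burst electrodes report rate 0.00 and 0.0 for every mean, matching
    how summary tables present silent channels.
    """
    if frame_duration <= 0:
        raise ConfigurationError("frame_duration must be > 0")
    n = len(bursts)
    if n == 0:
        return {
            "n_bursts": 0,
            "burst_rate_per_min": 0.0,
            "mean_burst_duration_s": 0.0,
            "mean_spikes_in_burst": 0.0,
            "mean_intra_burst_rate_hz": 0.0,
        }
    return {
        "n_bursts": n,
        "burst_rate_per_min": n / (frame_duration / 60.0),
        "mean_burst_duration_s": float(np.mean([b.duration for b in bursts])),
        "mean_spikes_in_burst": float(np.mean([b.n_spikes for b in bursts])),
        "mean_intra_burst_rate_hz": float(np.mean([b.intra_rate for b in bursts])),
    }


def detect_network_bursts(
    spike_trains: dict[str, np.ndarray],
    params: BurstParams | None = None,
    frame_duration: float | None = None,
) -> list[NetworkBurst]:
    """Detect synchronized bursting across the electrodes of one tissue.

    An electrode participates in a bin when the bin overlaps one of its
    single-electrode bursts or it fires at least one spike in the bin.  A
    network burst is a maximal run of bins in which the participating
    fraction of *active* electrodes (>= 1 spike in the frame) reaches
    ``network_fraction``.
    """
    params = params or BurstParams()
    active = {e: np.asarray(t, dtype=float) for e, t in spike_trains.items() if len(t) > 0}
    if len(active) < 2:
        warnings.warn("fewer than 2 active electrodes; no network bursts computed")
        return []
    if frame_duration is None:
        frame_duration = max(t[-1] for t in active.values()) + params.network_bin_ms / 1000.0
    bin_s = params.network_bin_ms / 1000.0
    n_bins = max(1, int(np.ceil(frame_duration / bin_s)))
    names = sorted(active)
    part = np.zeros((len(names), n_bins), dtype=bool)
    for row, name in enumerate(names):
        t = active[name]
        idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
        part[row, idx] = True
        for b in detect_bursts(t, params):
            lo = int(b.start / bin_s)
            hi = min(int(b.end / bin_s), n_bins - 1)
            part[row, lo : hi + 1] = True
    frac = part.mean(axis=0)
    hot = frac >= params.network_fraction
    events: list[NetworkBurst] = []
    i = 0
    while i < n_bins:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j < n_bins and hot[j]:
            j += 1
        participants = tuple(
            names[r] for r in range(len(names)) if part[r, i:j].any()
        )
        events.append(NetworkBurst(start=i * bin_s, end=j * bin_s, electrodes=participants))
        i = j
    return events


def classify_pattern(
    spike_times,
    bursts: list[Burst] | None = None,
    frame_duration: float = 1800.0,
    params: BurstParams | None = None,
) -> str:
    """Label a spike train as ``Slow``, ``Bursting`` or ``Irregular``.

    Slow: mean rate below ``slow_rate_hz``.  Bursting: at least
    ``burst_fraction`` of spikes inside bursts.  Irregular: everything else.
    The thresholds are heuristics (tables of these tissues label patterns
    without stating criteria) and are echoed in pipeline output metadata.
    """
    params = params or BurstParams()
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return ""
    if bursts is None:
        bursts = detect_bursts(t, params)
    rate = t.size / frame_duration
    if rate < params.slow_rate_hz:
        return "Slow"
    in_burst = sum(b.n_spikes for b in bursts)
    if in_burst / t.size >= params.burst_fraction:
        return "Bursting"
    return "Irregular"


@dataclass
class ElectrodeSummary:
    """One summary-table row: spike, burst and per-unit statistics for one electrode."""

    electrode_id: str
    strip_id: str = ""
    total_spikes: int = 0
    mean_frequency_hz: float = 0.0
    snr_mean: float = float("nan")
    mean_ptp_uv: float = float("nan")
    n_bursts: int = 0
    burst_rate_per_min: float = 0.0
    mean_burst_duration_s: float = 0.0
    mean_spikes_in_burst: float = 0.0
    mean_intra_burst_rate_hz: float = 0.0
    n_units: int = 0
    pattern: str = ""
    units: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_row(self) -> dict:
        row = {
            "strip_id": self.strip_id,
            "electrode_id": self.electrode_id,
            "mean_frequency_hz": self.mean_frequency_hz,
            "snr_mean": self.snr_mean,
            "mean_ptp_uv": self.mean_ptp_uv,
            "total_spikes": self.total_spikes,
            "n_bursts": self.n_bursts,
            "burst_rate_per_min": self.burst_rate_per_min,
            "mean_burst_duration_s": self.mean_burst_duration_s,
            "mean_spikes_in_burst": self.mean_spikes_in_burst,
            "mean_intra_burst_rate_hz": self.mean_intra_burst_rate_hz,
            "n_units": self.n_units,
            "pattern": self.pattern,
        }
        return row


def display_round(row: dict) -> dict:
    """Round a summary row the way per-electrode tables are printed.

    Electrode frequencies to 1 decimal, burst rates to 2 decimals, amplitudes
    and SNR to 1 decimal, burst-duration means to 1 decimal.  Raw (unrounded)
    values remain the computational truth; this is presentation only.
    """
    out = dict(row)
    for k, nd in (
        ("mean_frequency_hz", 1),
        ("snr_mean", 1),
        ("mean_ptp_uv", 1),
        ("burst_rate_per_min", 2),
        ("mean_burst_duration_s", 1),
        ("mean_spikes_in_burst", 1),
        ("mean_intra_burst_rate_hz", 1),
    ):
        if k in out and out[k] == out[k]:  # skip NaN
            out[k] = round(float(out[k]), nd)
    return out


def summarize_electrode(
    events,
    unit_table: pd.DataFrame | None,
    bursts: list[Burst],
    frame_duration: float,
    electrode_id: str = "",
    strip_id: str = "",
    params: BurstParams | None = None,
) -> ElectrodeSummary:
    """Build one per-electrode summary row from detection/sorting/burst output.

    ``events`` is the electrode's spike-event list (needs ``time``,
    ``ptp_amplitude`` and ``snr`` attributes); ``unit_table`` the per-unit
    statistics frame from the sorting stage (may be None/empty).
    """
    if frame_duration <= 0:
        raise ConfigurationError("frame_duration must be > 0")
    params = params or BurstParams()
    events = list(events)
    n = len(events)
    times = np.array([e.time for e in events], dtype=float)
    stats = burst_statistics(bursts, frame_duration)
    if n:
        snrs = np.array([e.snr for e in events], dtype=float)
        snr_mean = float(np.nanmean(snrs)) if np.isfinite(snrs).any() else float("nan")
        mean_ptp = float(np.mean([e.ptp_amplitude for e in events]))
        pattern = classify_pattern(times, bursts, frame_duration, params)
    else:
        snr_mean = float("nan")
        mean_ptp = float("nan")
        pattern = ""
    unit_table = unit_table if unit_table is not None else pd.DataFrame()
    return ElectrodeSummary(
        electrode_id=electrode_id,
        strip_id=strip_id,
        total_spikes=n,
        mean_frequency_hz=n / frame_duration,
        snr_mean=snr_mean,
        mean_ptp_uv=mean_ptp,
        n_bursts=stats["n_bursts"],
        burst_rate_per_min=stats["burst_rate_per_min"],
        mean_burst_duration_s=stats["mean_burst_duration_s"],
        mean_spikes_in_burst=stats["mean_spikes_in_burst"],
        mean_intra_burst_rate_hz=stats["mean_intra_burst_rate_hz"],
        n_units=0 if unit_table.empty else int(unit_table.shape[0]),
        pattern=pattern,
        units=unit_table,
    )
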