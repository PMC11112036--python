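"""Threshold-crossing spike detection, cutout extraction, amplitude and SNR.

The acquisition convention implemented here: voltage excursions beyond six
times the noise standard deviation count as spikes, and each detection
records a 5 ms cutout starting 1 ms before the event (150 samples at
30 kHz).  Detection is applied to the bandpassed signal.  SNR is the spike
peak-to-peak amplitude divided by the noise SD, averaged over an
electrode's events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "estimate_noise",
    "detect_spikes",
    "compute_snr",
]


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection parameters.

    threshold_multiplier : threshold in units of noise SD (6).
    cutout_duration_ms / cutout_pre_ms : cutout window geometry (5 ms / 1 ms).
    polarity : 'negative', 'positive' or 'both' (absolute value; default —
        extracellular spikes in these tissues show both dominant signs).
    dead_time_ms : minimum spacing between events on one electrode; covers
        the pre-window plus neuronal refractoriness so multiphasic waveforms
        are not double-counted.
    noise_estimator : 'sd' (plain SD of the trace) or 'mad' (median absolute
        deviation / 0.6745, robust to dense firing).
    snr_interval_low_mv / snr_interval_high_mv : acquisition-software
        interval bounds carried in some vendor configs; retained for config
        compatibility, not used by any computation here.
    """

    threshold_multiplier: float = 6.0
    cutout_duration_ms: float = 5.0
    cutout_pre_ms: float = 1.0
    polarity: str = "both"
    dead_time_ms: float = 2.0
    noise_estimator: str = "sd"
    snr_interval_low_mv: float = 0.5  # unused placeholder
    snr_interval_high_mv: float = 1.5  # unused placeholder

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ConfigurationError("threshold_multiplier must be > 0")
        if not self.cutout_pre_ms < self.cutout_duration_ms:
            raise ConfigurationError("cutout_pre_ms must be < cutout_duration_ms")
        if self.dead_time_ms < 0:
            raise ConfigurationError("dead_time_ms must be >= 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.noise_estimator not in ("sd", "mad"):
            raise ConfigurationError(f"unknown noise estimator {self.noise_estimator!r}")

    def cutout_samples(self, fs: float) -> int:
        return round(self.cutout_duration_ms / 1000.0 * fs)

    def pre_samples(self, fs: float) -> int:
        return round(self.cutout_pre_ms / 1000.0 * fs)


@dataclass
class SpikeEvent:
    """One detected threshold crossing with its waveform cutout.

    ``time`` is the first supra-threshold sample (the crossing instant), in
    seconds; the cutout spans ``[time - cutout_pre, time - cutout_pre +
    cutout_duration]`` so its sample at index ``pre_samples`` is the crossing.
    """

    electrode_id: str
    time: float
    index: int  # crossing sample index in the source trace
    cutout: np.ndarray  # microvolts
    ptp_amplitude: float
    snr: float = float("nan")


def estimate_noise(channel_signal, estimator: str = "sd") -> float:
    """Estimate the noise SD of one channel, in microvolts.

    'sd' is the plain standard deviation of the whole trace (the acquisition
    hardware's definition); 'mad' the median absolute deviation scaled by
    1/0.6745, which resists inflation by dense large spikes.  An
    all-constant trace returns 0 (the caller's threshold becomes degenerate).
    """
    x = np.asarray(channel_signal, dtype=np.float64)
    if estimator == "sd":
        return float(x.std())
    if estimator == "mad":
        return float(np.median(np.abs(x - np.median(x))) / 0.6745)
    raise ConfigurationError(f"unknown noise estimator {estimator!r}")


def _crossing_indices(x: np.ndarray, threshold: float, polarity: str) -> np.ndarray:
    """Samples where the signal first exceeds the threshold (entering from below)."""
    if polarity == "both":
        above = np.abs(x) > threshold
    elif polarity == "negative":
        above = x < -threshold
    else:
        above = x > threshold
    if not above.any():
        return np.empty(0, dtype=np.int64)
    first = above.copy()
    first[1:] &= ~above[:-1]
    return np.flatnonzero(first)


def detect_spikes(
    channel_signal,
    noise_sd: float,
    params: DetectionParams | None = None,
    sampling_rate: float = 30000.0,
    electrode_id: str = "",
    start_time: float = 0.0,
) -> list[SpikeEvent]:
    """Detect threshold crossings on one channel and extract cutouts.

    An event fires at each sample where the signal first exceeds
    ``threshold_multiplier * noise_sd`` (per ``polarity``), provided at
    least ``dead_time_ms`` elapsed since the previous event.  Events whose
    cutout would overrun either trace edge are discarded.  Empty output is
    valid.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0 for detection")
    params = params or DetectionParams()
    x = np.asarray(channel_signal, dtype=np.float32)
    fs = sampling_rate
    threshold = params.threshold_multiplier * noise_sd
    pre = params.pre_samples(fs)
    n_cut = params.cutout_samples(fs)
    dead = round(params.dead_time_ms / 1000.0 * fs)
    events: list[SpikeEvent] = []
    last = -np.inf
    for i in _crossing_indices(x, threshold, params.polarity):
        if i - last < dead:
            continue
        lo = i - pre
        if lo < 0 or lo + n_cut > x.size:
            continue  # cutout would overrun an edge
        last = i
        cutout = x[lo : lo + n_cut].astype(np.float32).copy()
        events.append(
            SpikeEvent(
                electrode_id=electrode_id,
                time=start_time + i / fs,
                index=int(i),
                cutout=cutout,
                ptp_amplitude=float(np.ptp(cutout)),
            )
        )
    return events


def compute_snr(events: list[SpikeEvent], noise_sd: float) -> float:
    """Fill per-event SNR (= PTP / noise SD) and return the electrode mean.

    With no events, or a zero noise SD, the mean is undefined and reported
    as NaN (missing), never 0.
    """
    if noise_sd <= 0 or not events:
        for e in events:
            e.snr = float("nan")
        return float("nan")
    for e in events:
        e.snr = e.ptp_amplitude / noise_sd
    return float(np.mean([e.snr for e in events]))
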