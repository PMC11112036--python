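"""Raw-recording container, flat-binary I/O and the acquisition bandpass filter.

A recording is a dense ``[n_channels x n_samples]`` matrix of extracellular
voltages in microvolts, sampled at a common rate (30 kHz for the acquisition
hardware this package targets).  Channels are identified by a
``(strip_id, electrode_id)`` pair: the array carries 4 strips of 8 electrodes
each, so a full biochip recording has 32 channels.

On disk a recording is a channel-interleaved flat binary file (one frame =
one sample from every channel, frames in time order) plus a key-value text
sidecar declaring the sampling rate, channel map, dtype and, for integer
storage, the microvolt-per-count scale.  The format is deliberately trivial:
byte-exact, language-agnostic and easy to generate from fixtures.

The acquisition chain applies a 0.1 Hz first-order high-pass followed by a
5 kHz third-order Butterworth low-pass; :func:`bandpass` reproduces that
chain (causal by default, matching the real-time hardware; zero-phase
optionally for offline work).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, FormatError, RangeError

__all__ = [
    "Recording",
    "FilterSpec",
    "default_channel_map",
    "read_recording",
    "write_recording",
    "bandpass",
    "settling_time",
]


def default_channel_map(n_strips: int = 4, electrodes_per_strip: int = 8) -> list[tuple[str, str]]:
    """Channel map for the standard biochip layout.

    Electrodes are numbered consecutively across strips (E1..E8 on strip S1,
    E9..E16 on S2, ...), matching how per-electrode tables index them.
    """
    out = []
    for s in range(n_strips):
        for e in range(electrodes_per_strip):
            out.append((f"S{s + 1}", f"E{s * electrodes_per_strip + e + 1}"))
    return out


@dataclass
class Recording:
    """Multichannel extracellular voltage trace in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts (float32 internally).
    sampling_rate : float
        Samples per second per channel.
    channel_map : list of (strip_id, electrode_id)
        One entry per row of ``samples``; entries must be unique.
    start_time : float
        Absolute time of the first sample, seconds.
    transient_until : float
        Time (seconds, absolute) before which filtered output is still
        settling; 0 for raw recordings.  Flagged, never removed.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_map: list[tuple[str, str]] = field(default_factory=default_channel_map)
    start_time: float = 0.0
    transient_until: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be 2-D [n_channels x n_samples]")
        if self.samples.shape[0] != len(self.channel_map):
            raise ConfigurationError(
                f"channel_map has {len(self.channel_map)} entries for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(map(tuple, self.channel_map))) != len(self.channel_map):
            raise ConfigurationError("channel_map entries must be unique")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def electrode_ids(self) -> list[str]:
        return [e for _, e in self.channel_map]

    def channel(self, electrode_id: str) -> np.ndarray:
        """Return the trace of one electrode by id."""
        for i, (_, e) in enumerate(self.channel_map):
            if e == electrode_id:
                return self.samples[i]
        raise KeyError(electrode_id)


@dataclass(frozen=True)
class FilterSpec:
    """Acquisition bandpass: 1st-order high-pass + 3rd-order Butterworth low-pass."""

    hp_cutoff: float = 0.1
    hp_order: int = 1
    lp_cutoff: float = 5000.0
    lp_order: int = 3

    def validate(self, sampling_rate: float) -> None:
        if not (0 < self.hp_cutoff < self.lp_cutoff < sampling_rate / 2):
            raise ConfigurationError(
                f"need 0 < hp_cutoff ({self.hp_cutoff}) < lp_cutoff ({self.lp_cutoff}) "
                f"< Nyquist ({sampling_rate / 2})"
            )
        if self.hp_order < 1 or self.lp_order < 1:
            raise ConfigurationError("filter orders must be >= 1")


def settling_time(spec: FilterSpec) -> float:
    """Duration (s) flagged as filter transient: max(5 / hp_cutoff, 1 s)."""
    return max(5.0 / spec.hp_cutoff, 1.0)


# ---------------------------------------------------------------------------
# flat binary + sidecar


_DTYPES = {"float32": np.float32, "int16": np.int16}


def _write_sidecar(path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")


def _read_sidecar(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"malformed sidecar line: {line!r}")
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def write_recording(
    recording: Recording,
    path,
    metadata_path,
    dtype: str = "float32",
    scale_uv_per_count: float = 0.1,
) -> None:
    """Write a recording as channel-interleaved binary plus a text sidecar.

    ``float32`` stores microvolts exactly; ``int16`` quantizes to
    ``scale_uv_per_count`` microvolts per count and raises :class:`RangeError`
    if any value falls outside the representable int16 range.
    """
    if dtype not in _DTYPES:
        raise ConfigurationError(f"unsupported dtype {dtype!r}; use float32 or int16")
    interleaved = np.ascontiguousarray(recording.samples.T)  # frame-major
    if dtype == "int16":
        counts = np.round(interleaved.astype(np.float64) / scale_uv_per_count)
        if counts.size and (counts.max() > 32767 or counts.min() < -32768):
            raise RangeError(
                f"values exceed int16 range at scale {scale_uv_per_count} uV/count"
            )
        counts.astype("<i2").tofile(path)
    else:
        interleaved.astype("<f4").tofile(path)
    cmap = ",".join(f"{s}:{e}" for s, e in recording.channel_map)
    _write_sidecar(
        metadata_path,
        {
            "sampling_rate_hz": repr(float(recording.sampling_rate)),
            "n_channels": recording.n_channels,
            "dtype": dtype,
            "scale_uv_per_count": repr(float(scale_uv_per_count)),
            "start_time_s": repr(float(recording.start_time)),
            "channel_map": cmap,
        },
    )


def read_recording(path, metadata_path) -> Recording:
    """Read a flat-binary recording; samples come back in microvolts.

    Raises :class:`FormatError` naming the offending sidecar field when the
    metadata is missing, unparsable, or inconsistent with the file size.
    """
    meta = _read_sidecar(metadata_path)
    for key in ("sampling_rate_hz", "n_channels", "dtype", "channel_map"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    try:
        fs = float(meta["sampling_rate_hz"])
        n_channels = int(meta["n_channels"])
    except ValueError as exc:
        raise FormatError(f"unparsable numeric sidecar field: {exc}") from exc
    dtype = meta["dtype"]
    if dtype not in _DTYPES:
        raise FormatError(f"sidecar dtype {dtype!r} not supported")
    channel_map: list[tuple[str, str]] = []
    if meta["channel_map"]:
        for entry in meta["channel_map"].split(","):
            if ":" not in entry:
                raise FormatError(f"malformed channel_map entry {entry!r}")
            s, e = entry.split(":", 1)
            channel_map.append((s, e))
    if len(channel_map) != n_channels:
        raise FormatError(
            f"channel_map lists {len(channel_map)} channels but n_channels={n_channels}"
        )
    raw = np.fromfile(path, dtype=np.dtype(_DTYPES[dtype]).newbyteorder("<"))
    if n_channels and raw.size % n_channels:
        raise FormatError(
            f"sample count {raw.size} not divisible by n_channels={n_channels}"
        )
    frames = raw.reshape(-1, n_channels) if n_channels else raw.reshape(0, 0)
    if dtype == "int16":
        scale = float(meta.get("scale_uv_per_count", 0.1))
        samples = frames.T.astype(np.float32) * np.float32(scale)
    else:
        samples = frames.T.astype(np.float32)
    return Recording(
        samples=np.ascontiguousarray(samples),
        sampling_rate=fs,
        channel_map=channel_map,
        start_time=float(meta.get("start_time_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# bandpass


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    hp = sps.butter(spec.hp_order, spec.hp_cutoff, "highpass", fs=fs, output="sos")
    lp = sps.butter(spec.lp_order, spec.lp_cutoff, "lowpass", fs=fs, output="sos")
    return np.vstack([hp, lp])


def bandpass(recording: Recording, spec: FilterSpec | None = None, zero_phase: bool = False) -> Recording:
    """Apply the acquisition bandpass channel-by-channel.

    Causal by default (the hardware filters in real time); ``zero_phase=True``
    uses forward-backward filtering for offline analysis.  Output shape,
    sampling rate and channel map are unchanged; ``transient_until`` marks the
    high-pass settling window.
    """
    spec = spec or FilterSpec()
    spec.validate(recording.sampling_rate)
    sos = _bandpass_sos(spec, recording.sampling_rate)
    out = np.empty_like(recording.samples)
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    for i in range(recording.n_channels):
        out[i] = filt(sos, recording.samples[i].astype(np.float64)).astype(np.float32)
    transient = 0.0 if zero_phase else recording.start_time + settling_time(spec)
    return replace(recording, samples=out, transient_until=transient)


def bandpass_gain(spec: FilterSpec, freq_hz: float) -> float:
    """Closed-form magnitude response of the analog prototype at ``freq_hz``.

    Useful for validating the digital implementation well below Nyquist:
    |H| = |f/hp|/sqrt(1+(f/hp)^2) * 1/sqrt(1+(f/lp)^(2*lp_order)).
    """
    r_hp = freq_hz / spec.hp_cutoff
    r_lp = freq_hz / spec.lp_cutoff
    hp_mag = r_hp / math.sqrt(1.0 + r_hp**2)
    lp_mag = 1.0 / math.sqrt(1.0 + r_lp ** (2 * spec.lp_order))
    return hp_mag * lp_mag
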