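"""Shared containers and on-disk formats.

All continuous signals live in :class:`TimeSeries` (channels x samples,
uniform rate).  Detected deflection events live in :class:`EventSet`.
Signals are persisted as flat little-endian float32 binary (channel-major)
with a JSON sidecar carrying ``fs``, ``n_channels``, ``units`` and ``t0``;
tables are CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "EventSet",
    "SpikeTrain",
    "PhaseDistribution",
    "read_timeseries",
]


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values; microvolts for extracellular voltage, g for
        accelerometer channels.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample, seconds.
    units : str
        Unit label applying to every channel.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TimeSeries data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the record in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def save(self, path: str | Path) -> None:
        """Write flat binary (float32 channel-major) plus JSON sidecar."""
        path = Path(path)
        self.data.astype("<f4").tofile(path)
        sidecar = {
            "fs": float(self.fs),
            "n_channels": int(self.n_channels),
            "units": self.units,
            "t0": float(self.t0),
            "dtype": "<f4",
            "order": "channel-major",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_timeseries(path: str | Path) -> TimeSeries:
    """Load a flat-binary signal written by :meth:`TimeSeries.save`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "n_channels", "units", "t0"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    raw = np.fromfile(path, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch:
        raise ValueError("binary length not divisible by channel count")
    data = raw.reshape(n_ch, -1).astype(float)
    return TimeSeries(data, fs=float(meta["fs"]), t0=float(meta["t0"]), units=meta["units"])


@dataclass
class EventSet:
    """Detected (or sampled non-) deflection events.

    ``times`` anchor each event at its minimum-voltage sample (seconds,
    in the coordinate frame of the source recording).  ``amplitude`` is
    the signed minimum of the 1-40 Hz trace in the event window (uV);
    ``duration`` the full width at half magnitude around that minimum
    (ms).  ``snippets`` holds fixed-length raw-rate extracts, one row
    per event.
    """

    times: np.ndarray
    z_score: np.ndarray | None = None
    amplitude: np.ndarray | None = None
    duration: np.ndarray | None = None
    snippets: np.ndarray | None = None
    snippet_fs: float | None = None
    is_event: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            for name in ("z_score", "amplitude", "duration", "snippets"):
                val = getattr(self, name)
                if val is not None:
                    setattr(self, name, np.asarray(val)[order])

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        """Event table (one row per event; snippets omitted)."""
        cols: dict[str, object] = {"time_s": self.times}
        if self.z_score is not None:
            cols["z"] = self.z_score
        if self.amplitude is not None:
            cols["amplitude_uV"] = self.amplitude
        if self.duration is not None:
            cols["duration_ms"] = self.duration
        cols["is_event"] = np.full(len(self), self.is_event)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SpikeTrain:
    """Threshold-crossing spike times, sorted, per-channel."""

    times: np.ndarray
    channel: np.ndarray | None = None
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        if self.channel is not None:
            self.channel = np.asarray(self.channel)[order]
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)[order]

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"time_s": self.times}
        if self.channel is not None:
            cols["channel"] = self.channel
        if self.amplitude is not None:
            cols["amplitude_uV"] = self.amplitude
        return pd.DataFrame(cols)


@dataclass
class PhaseDistribution:
    """Normalized histogram of spike phases (degrees)."""

    bin_edges: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.probability.size != self.bin_edges.size - 1:
            raise ValueError("need len(bin_edges) == len(probability) + 1")
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probability.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rle_encode_mask(mask: np.ndarray) -> pd.DataFrame:
    """Run-length encode a boolean mask into (start, stop, value) rows.

    ``stop`` is exclusive.  Used for movement and MUA masks on disk.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return pd.DataFrame(columns=["start", "stop", "value"])
    change = np.flatnonzero(np.diff(mask)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [mask.size]))
    return pd.DataFrame({"start": starts, "stop": stops, "value": mask[starts]})


def rle_decode_mask(frame: pd.DataFrame, n: int | None = None) -> np.ndarray:
    if len(frame) == 0:
        return np.zeros(0 if n is None else n, dtype=bool)
    total = int(frame["stop"].iloc[-1]) if n is None else n
    out = np.zeros(total, dtype=bool)
    for start, stop, value in frame[["start", "stop", "value"]].itertuples(index=False):
        out[int(start):int(stop)] = bool(value)
    return out
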