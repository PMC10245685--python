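"""Deterministic signal conditioning shared by chronic and acute analyses.

Resampling, zero-phase Butterworth filtering, common average referencing,
bad-channel rejection, and accelerometer-based movement masking.  All
filters are 4th-order Butterworth applied forward-backward (zero phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import TimeSeries

__all__ = [
    "FilterSpec",
    "bandpass",
    "apply_filter",
    "resample_ts",
    "movement_mask",
    "MovementMask",
    "average_and_band",
    "common_average_reference",
    "remove_bad_channels",
    "hilbert_phase_deg",
]

LFP_BAND = (1.0, 40.0)  # deflection-detection band, Hz
MUA_BAND = (600.0, 6000.0)
ACUTE_LF_BAND = (1.0, 300.0)
ACUTE_HF_BAND = (300.0, 7000.0)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description (band edges in Hz)."""

    band: tuple[float, float]
    order: int = 4
    btype: str = "bandpass"  # bandpass | highpass | lowpass
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0 <= low < high <= fs / 2):
            raise ValueError(f"band {self.band} invalid for fs={fs}")


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    low, high = spec.band
    if spec.btype == "bandpass":
        return signal.butter(spec.order, [low, high], btype="bandpass", fs=fs, output="sos")
    if spec.btype == "highpass":
        return signal.butter(spec.order, low, btype="highpass", fs=fs, output="sos")
    if spec.btype == "lowpass":
        return signal.butter(spec.order, high, btype="lowpass", fs=fs, output="sos")
    raise ValueError(f"unknown filter type {spec.btype!r}")


def apply_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Filter along the last axis; zero-phase unless the FilterSpec disables it."""
    sos = _sos(spec, fs)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (convenience wrapper)."""
    return apply_filter(np.asarray(x, dtype=float), fs, FilterSpec(band=band, order=order))


def hilbert_phase_deg(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase in degrees in [0, 360) with phase(peak) = 90.

    Sine convention: sin(wt) has phase wt, so a positive peak of a
    band-limited oscillation sits at 90 degrees and a trough at 270.
    This single convention is used by the spike generator, the PAC
    estimator and the spike-phase extractor.
    """
    return (np.degrees(np.angle(signal.hilbert(x))) + 90.0) % 360.0


def resample_ts(ts: TimeSeries, target_fs: float, max_denominator: int = 1000) -> TimeSeries:
    """Polyphase anti-aliased resampling to ``target_fs``.

    The per-channel mean is subtracted before resampling and added back
    afterwards so that non-zero-centered traces (accelerometers) do not
    pick up edge artifacts from the anti-aliasing lowpass.
    """
    if target_fs > ts.fs:
        raise ValueError("target_fs must not exceed the source rate")
    if target_fs == ts.fs:
        return TimeSeries(ts.data.copy(), fs=ts.fs, t0=ts.t0, units=ts.units)
    ratio = Fraction(target_fs / ts.fs).limit_denominator(max_denominator)
    up, down = ratio.numerator, ratio.denominator
    means = ts.data.mean(axis=1, keepdims=True)
    out = signal.resample_poly(np.asarray(ts.data, dtype=float) - means, up, down, axis=-1)
    out += means
    actual_fs = ts.fs * up / down
    return TimeSeries(out, fs=actual_fs, t0=ts.t0, units=ts.units)


@dataclass
class MovementMask:
    """Boolean per-sample movement flag at the working rate."""

    mask: np.ndarray
    fs: float
    window_s: float
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def moving_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def _moving_std(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving SD via cumulative sums (O(n))."""
    kernel = np.ones(win) / win
    mean = np.convolve(x, kernel, mode="same")
    mean_sq = np.convolve(x * x, kernel, mode="same")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def movement_mask(
    accel: TimeSeries,
    window_s: float = 1.0,
    threshold: float | None = None,
    threshold_percentile: float = 95.0,
) -> MovementMask:
    """Flag movement from the moving SD of the accelerometer magnitude.

    The "velocity" proxy is the vector magnitude of the 3-axis signal
    after per-axis mean (gravity) removal.  ``threshold`` is an absolute
    moving-SD value; if None, the given percentile of the recording's
    moving-SD distribution is used.
    """
    win = int(round(window_s * accel.fs))
    if win > accel.n_samples:
        raise ValueError("window longer than the recording")
    win = max(win, 1)
    centered = accel.data - accel.data.mean(axis=1, keepdims=True)
    magnitude = np.sqrt(np.sum(centered**2, axis=0))
    mstd = _moving_std(magnitude, win)
    if threshold is None:
        threshold = float(np.percentile(mstd, threshold_percentile))
    mask = mstd > threshold
    return MovementMask(mask=mask, fs=accel.fs, window_s=window_s, threshold=float(threshold))


def average_and_band(ts: TimeSeries, band: tuple[float, float] = LFP_BAND) -> TimeSeries:
    """Average across channels, then zero-phase bandpass (1-40 Hz default)."""
    if ts.n_channels < 1 or ts.n_samples == 0:
        raise ValueError("empty channel set")
    avg = np.asarray(ts.data, dtype=float).mean(axis=0)
    filtered = bandpass(avg, ts.fs, band)
    return TimeSeries(filtered, fs=ts.fs, t0=ts.t0, units=ts.units)


def common_average_reference(ts: TimeSeries) -> TimeSeries:
    """Subtract the per-sample cross-channel mean from every channel."""
    if ts.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    data = np.asarray(ts.data, dtype=float)
    return TimeSeries(data - data.mean(axis=0, keepdims=True), fs=ts.fs, t0=ts.t0, units=ts.units)


def remove_bad_channels(ts: TimeSeries, sd_ratio: float = 10.0) -> tuple[TimeSeries, list[int]]:
    """Drop channels whose SD exceeds ``sd_ratio`` times the median channel SD.

    Emulates removal of electrodes whose signal is an order of magnitude
    larger than all others.  Returns the cleaned series and the dropped
    channel indices.
    """
    sds = np.asarray(ts.data, dtype=float).std(axis=1)
    median_sd = np.median(sds)
    bad = [int(i) for i in np.flatnonzero(sds > sd_ratio * median_sd)]
    if len(bad) == ts.n_channels:
        raise ValueError("all channels flagged bad")
    keep = [i for i in range(ts.n_channels) if i not in bad]
    return TimeSeries(ts.data[keep], fs=ts.fs, t0=ts.t0, units=ts.units), bad
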