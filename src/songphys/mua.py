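"""Multi-unit activity via the square-root local (Teager) energy operator.

The operator psi(x)[n] = x[n]^2 - x[n-1] x[n+1] tracks instantaneous
signal energy; on spiking band signals its square root, lightly Gaussian
smoothed, is a robust MUA envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import TimeSeries
from .preprocess import FilterSpec, apply_filter, resample_ts
from scipy import signal as _signal

__all__ = ["MuaConfig", "teager", "mua_envelope", "mua_mask"]


@dataclass
class MuaConfig:
    band: tuple[float, float] = (600.0, 6000.0)
    work_fs: float = 50_000.0
    smooth_sigma_ms: float = 0.4
    threshold_median_mult: float = 5.0  # threshold = mult x night median envelope
    output_fs: float = 30_000.0

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1] < self.work_fs / 2):
            raise ValueError("band must lie within Nyquist at work_fs")
        if self.smooth_sigma_ms <= 0 or self.threshold_median_mult <= 0:
            raise ValueError("smoothing sigma and threshold must be positive")


def teager(x: np.ndarray) -> np.ndarray:
    """psi(x)[n] = x[n]^2 - x[n-1] x[n+1]; endpoints copy their neighbor."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Teager operator needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def _upsample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase upsampling (resample_ts only goes down)."""
    from fractions import Fraction

    ratio = Fraction(target_fs / fs).limit_denominator(1000)
    return _signal.resample_poly(x, ratio.numerator, ratio.denominator)


def mua_envelope(ts: TimeSeries, cfg: MuaConfig | None = None, smooth: bool = True) -> TimeSeries:
    """MUA envelope of a (already common-average-referenced) channel.

    Bandpass 600-6000 Hz, upsample to 50 kHz, apply the Teager operator,
    clamp negative values to zero, take the square root, and Gaussian
    smooth with sigma = 0.4 ms.
    """
    cfg = cfg or MuaConfig()
    if cfg.band[1] >= ts.fs / 2:
        raise ValueError(f"band {cfg.band} incompatible with fs={ts.fs}")
    x = apply_filter(np.asarray(ts.data[0], dtype=float), ts.fs, FilterSpec(band=cfg.band))
    if cfg.work_fs > ts.fs:
        x = _upsample(x, ts.fs, cfg.work_fs)
    psi = teager(x)
    env = np.sqrt(np.maximum(psi, 0.0))
    if smooth:
        sigma_samples = cfg.smooth_sigma_ms / 1000.0 * cfg.work_fs
        env = gaussian_filter1d(env, sigma_samples)
    return TimeSeries(env, fs=cfg.work_fs, t0=ts.t0, units=ts.units)


def mua_mask(
    envelope: TimeSeries, cfg: MuaConfig | None = None, threshold: float | None = None
) -> np.ndarray:
    """Boolean high-MUA mask at ``output_fs``.

    The envelope is thresholded (default: ``threshold_median_mult`` times
    the recording's median envelope) and the boolean trace is downsampled
    by logical OR over each output sample's span, so no brief burst is
    lost to decimation.
    """
    cfg = cfg or MuaConfig()
    env = np.asarray(envelope.data[0], dtype=float)
    if threshold is None:
        threshold = cfg.threshold_median_mult * float(np.median(env))
    above = env > threshold
    n_out = int(round(env.size * cfg.output_fs / envelope.fs))
    out = np.zeros(n_out, dtype=bool)
    idx = np.flatnonzero(above)
    if idx.size:
        mapped = (idx * cfg.output_fs / envelope.fs).astype(int)
        out[np.minimum(mapped, n_out - 1)] = True
    return out
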