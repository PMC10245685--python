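"""Threshold spike detection and spike-phase locking statistics.

Spikes are threshold crossings at 9 SD of the local (2-minute window)
signal statistics on the common-average-referenced high-frequency band;
each spike is assigned the Hilbert phase of a band-limited LFP
oscillation at its time (phase(peak) = 90 convention); phase
distributions are compared with the two-sample Kolmogorov-Smirnov test
and per-neuron firing rates with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PhaseDistribution, SpikeTrain, TimeSeries
from .preprocess import bandpass, hilbert_phase_deg

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseLockConfig",
    "detect_spikes",
    "spike_phases",
    "phase_distribution",
    "compare_phase_cdfs",
    "compare_firing_rates",
    "circular_mean_deg",
    "resultant_length",
]


@dataclass
class PhaseLockConfig:
    spike_threshold_sd: float = 9.0
    sd_window_s: float = 120.0
    refractory_ms: float = 1.0
    two_sided: bool = True  # magnitude criterion; extracellular spikes are mostly negative
    alpha_band: tuple[float, float] = (1.0, 10.0)
    low_gamma_band: tuple[float, float] = (30.0, 70.0)
    phase_bins: int = 18

    def __post_init__(self) -> None:
        if 360 % self.phase_bins:
            raise ValueError("phase_bins must divide 360")
        if self.spike_threshold_sd <= 0 or self.sd_window_s <= 0:
            raise ValueError("threshold and window must be positive")


def detect_spikes(hf: TimeSeries, cfg: PhaseLockConfig | None = None) -> SpikeTrain:
    """Threshold crossings at 9 SD of the 2-minute local statistics.

    Within each window the threshold is mean +- 9 SD of that window; a
    spike is a contiguous supra-threshold excursion of |x - mean|, timed
    at its extremum sample, with a 1 ms refractory period.  Doubling the
    gain leaves spike times unchanged (the threshold is SD-relative).
    """
    cfg = cfg or PhaseLockConfig()
    x = np.asarray(hf.data[0], dtype=float)
    win = int(round(cfg.sd_window_s * hf.fs))
    win = max(min(win, x.size), 2)
    times: list[float] = []
    amps: list[float] = []
    refrac = cfg.refractory_ms / 1000.0
    for start in range(0, x.size, win):
        seg = x[start:start + win]
        if seg.size < 2:
            continue
        mu, sd = seg.mean(), seg.std()
        if sd == 0:
            raise ValueError(f"zero-SD window at sample {start}")
        dev = np.abs(seg - mu) if cfg.two_sided else (seg - mu)
        above = dev > cfg.spike_threshold_sd * sd
        padded = np.concatenate(([False], above, [False]))
        change = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(change[::2], change[1::2]):
            rel = int(np.argmax(dev[s:e]))
            t = (start + s + rel) / hf.fs + hf.t0
            if times and t - times[-1] < refrac:
                continue
            times.append(t)
            amps.append(float(seg[s + rel] - mu))
    return SpikeTrain(times=np.asarray(times), amplitude=np.asarray(amps))


def spike_phases(
    spikes: SpikeTrain, lfp: TimeSeries, band: tuple[float, float]
) -> np.ndarray:
    """Band-limited LFP phase at each spike time, degrees in [0, 360).

    The LFP is zero-phase bandpassed; the Hilbert phase is linearly
    interpolated (on the unit circle) to the spike times.  Spikes outside
    the LFP span are dropped and logged.
    """
    x = bandpass(np.asarray(lfp.data[0], dtype=float), lfp.fs, band)
    phase = np.radians(hilbert_phase_deg(x))
    t = lfp.t0 + np.arange(x.size) / lfp.fs
    inside = (spikes.times >= t[0]) & (spikes.times <= t[-1])
    if (~inside).any():
        logger.info("spike_phases: dropped %d spikes outside the LFP span", int((~inside).sum()))
    st = spikes.times[inside]
    # interpolate on the circle to avoid wrap artifacts
    cos_i = np.interp(st, t, np.cos(phase))
    sin_i = np.interp(st, t, np.sin(phase))
    return (np.degrees(np.arctan2(sin_i, cos_i))) % 360.0


def phase_distribution(
    phases_deg: np.ndarray, cfg: PhaseLockConfig | None = None
) -> PhaseDistribution:
    """Normalized histogram of spike phases over ``phase_bins`` bins."""
    cfg = cfg or PhaseLockConfig()
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size == 0:
        raise ValueError("no phases to histogram")
    edges = np.linspace(0.0, 360.0, cfg.phase_bins + 1)
    hist, _ = np.histogram(phases_deg % 360.0, bins=edges)
    return PhaseDistribution(bin_edges=edges, probability=hist / hist.sum())


def compare_phase_cdfs(
    phases_a: np.ndarray, phases_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test on phase samples (reference angle fixed at 0).

    Phases are compared as values on [0, 360) with the cut at 0 degrees;
    with fewer than 5 samples per side the exact small-sample p-value is
    used and a warning issued.
    """
    a = np.asarray(phases_a, dtype=float) % 360.0
    b = np.asarray(phases_b, dtype=float) % 360.0
    if a.size == 0 or b.size == 0:
        raise ValueError("both phase samples must be non-empty")
    method = "auto"
    if min(a.size, b.size) < 5:
        warnings.warn("fewer than 5 phases per side; using exact KS p-value", stacklevel=2)
        method = "exact"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_firing_rates(rates_a: np.ndarray, rates_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-neuron mean firing rates.

    Ties are handled by mid-ranks (the normal-approximation statistic of
    the rank-sum test).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rate samples must be non-empty")
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def circular_mean_deg(phases_deg: np.ndarray) -> float:
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    return float(np.degrees(np.angle(np.exp(1j * rad).sum())) % 360.0)


def resultant_length(phases_deg: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]; 0 = uniform, 1 = perfectly locked."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    return float(np.abs(np.exp(1j * rad).mean()))
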