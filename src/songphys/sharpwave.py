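"""Offline deflection (sharp-wave) detection by two-pass template matching.

Pass 1 finds putative events as sub-threshold runs of the channel-averaged,
1-40 Hz bandpassed LFP at 125 Hz: samples in the lowest 5% of non-movement
values, lasting at least 10 ms, at least 80 ms apart.  Pass 2 averages an
80 ms window around each putative event into a template, cross-correlates
the template with the whole trace, z-scores the correlation using
non-movement statistics only, and keeps correlation peaks above a constant
threshold with the same 80 ms spacing rule.  Final events are re-extracted
from the raw-rate trace as 500 ms snippets recentered on the local minimum,
and their amplitude (signed minimum) and duration (full width at half
magnitude) are measured on a 1-40 Hz version of the snippet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EventSet, TimeSeries
from .preprocess import (
    LFP_BAND,
    MovementMask,
    average_and_band,
    bandpass,
    movement_mask,
    resample_ts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SharpwaveConfig",
    "Template",
    "detect_candidates",
    "build_template",
    "score_template",
    "detect_events",
    "extract_snippets",
    "sample_non_events",
    "nightly_stats",
    "run_sharpwave_detection",
]


@dataclass
class SharpwaveConfig:
    """Detector parameters.

    ``candidate_percentile`` is applied to the signed bandpassed trace, so
    the candidate threshold is the most-negative-5% boundary of
    non-movement samples.  ``z_threshold`` is the constant threshold on the
    z-scored template correlation (the same value serves every recording).
    """

    candidate_percentile: float = 5.0
    min_candidate_ms: float = 10.0
    min_separation_ms: float = 80.0
    template_ms: float = 80.0
    z_threshold: float = 4.0
    snippet_ms: float = 500.0
    recenter_ms: float = 100.0
    working_fs: float = 125.0
    raw_fs: float = 30_000.0
    measure_fs: float = 1000.0
    band: tuple[float, float] = LFP_BAND
    artifact_band: tuple[float, float] = (300.0, 7000.0)
    artifact_rms_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.template_ms > self.min_separation_ms:
            raise ValueError("template_ms must not exceed min_separation_ms")
        if self.recenter_ms >= self.snippet_ms:
            raise ValueError("recenter_ms must be smaller than snippet_ms")

    @property
    def template_samples(self) -> int:
        return int(round(self.template_ms / 1000.0 * self.working_fs))

    @property
    def separation_samples(self) -> int:
        return int(round(self.min_separation_ms / 1000.0 * self.working_fs))


@dataclass
class Template:
    """Average deflection waveform at the working rate."""

    waveform: np.ndarray
    fs: float
    n_candidates: int


def _active_mask(n: int, mask: MovementMask | None) -> np.ndarray:
    """Non-movement indicator of length n (all True when no mask given)."""
    if mask is None:
        return np.ones(n, dtype=bool)
    if mask.mask.size != n:
        raise ValueError("movement mask length does not match the trace")
    return ~mask.mask


def _enforce_separation(
    anchors: np.ndarray, depth: np.ndarray, min_gap: int
) -> np.ndarray:
    """Greedy exclusion: keep deeper/stronger anchors, drop any within min_gap.

    ``depth`` is sorted descending by priority (ties broken by earlier
    anchor).  Returns the kept anchors in ascending order.
    """
    order = np.lexsort((anchors, -depth))
    kept: list[int] = []
    for idx in order:
        a = anchors[idx]
        if all(abs(a - b) >= min_gap for b in kept):
            kept.append(int(a))
    return np.sort(np.asarray(kept, dtype=int))


def detect_candidates(
    lfp125: TimeSeries, mask: MovementMask | None, cfg: SharpwaveConfig
) -> np.ndarray:
    """First-pass putative event times (seconds).

    A candidate is a maximal run of samples below the 5th percentile of
    non-movement values lasting at least ``min_candidate_ms``, anchored at
    the run's minimum sample; candidates closer than ``min_separation_ms``
    are resolved by keeping the deeper minimum.
    """
    x = np.asarray(lfp125.data[0], dtype=float)
    active = _active_mask(x.size, mask)
    if not active.any():
        raise ValueError("no non-movement data to detect candidates in")
    threshold = np.quantile(x[active], cfg.candidate_percentile / 100.0)
    below = (x < threshold) & active

    # maximal runs of below-threshold samples
    padded = np.concatenate(([False], below, [False]))
    change = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = change[::2], change[1::2]
    min_run = int(np.ceil(cfg.min_candidate_ms / 1000.0 * lfp125.fs))
    anchors = []
    depths = []
    for s, e in zip(starts, stops):
        if e - s < min_run:
            continue
        rel = int(np.argmin(x[s:e]))
        anchors.append(s + rel)
        depths.append(-x[s + rel])
    if not anchors:
        return np.empty(0)
    kept = _enforce_separation(
        np.asarray(anchors), np.asarray(depths), cfg.separation_samples
    )
    return kept / lfp125.fs + lfp125.t0


def build_template(
    lfp125: TimeSeries, candidates: np.ndarray, cfg: SharpwaveConfig
) -> Template:
    """Average the ``template_ms`` window centered on each candidate."""
    x = np.asarray(lfp125.data[0], dtype=float)
    n_t = cfg.template_samples
    half = n_t // 2
    windows = []
    skipped = 0
    for t in np.atleast_1d(candidates):
        c = int(round((t - lfp125.t0) * lfp125.fs))
        start = c - half
        if start < 0 or start + n_t > x.size:
            skipped += 1
            continue
        windows.append(x[start:start + n_t])
    if not windows:
        raise ValueError("no candidate has a full template window")
    if skipped:
        logger.info("build_template: skipped %d edge candidates", skipped)
    return Template(waveform=np.mean(windows, axis=0), fs=lfp125.fs, n_candidates=len(windows))


def score_template(
    lfp125: TimeSeries, template: Template, mask: MovementMask | None
) -> np.ndarray:
    """z-scored sliding correlation of the template against the trace.

    Output sample ``i`` is the dot product of the template with the window
    whose center sample is ``i`` (same alignment as ``build_template``);
    edge samples without a full window are NaN.  Mean and SD for the
    z-score come from non-movement samples only.
    """
    x = np.asarray(lfp125.data[0], dtype=float)
    w = np.asarray(template.waveform, dtype=float)
    n_t = w.size
    if n_t > x.size:
        raise ValueError("template longer than trace")
    half = n_t // 2
    valid = np.correlate(x, w, mode="valid")  # valid[s] = dot(x[s:s+n_t], w)
    scores = np.full(x.size, np.nan)
    scores[half:half + valid.size] = valid
    active = _active_mask(x.size, mask) & np.isfinite(scores)
    if not active.any():
        raise ValueError("no usable non-movement samples to z-score against")
    mu = scores[active].mean()
    sd = scores[active].std()
    if sd == 0:
        raise ValueError("constant correlation trace (zero SD)")
    return (scores - mu) / sd


def detect_events(
    zscores: np.ndarray, cfg: SharpwaveConfig, fs: float | None = None, t0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Final event times from the z-scored correlation trace.

    Local maxima above ``z_threshold`` are selected greedily in descending
    z with an ``min_separation_ms`` exclusion zone.  Returns (times_s, z).
    """
    if fs is None:
        fs = cfg.working_fs
    z = np.asarray(zscores, dtype=float)
    interior = z[1:-1]
    is_peak = np.zeros(z.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        is_peak[1:-1] = (interior > z[:-2]) & (interior >= z[2:]) & (interior > cfg.z_threshold)
    peaks = np.flatnonzero(is_peak)
    if peaks.size == 0:
        return np.empty(0), np.empty(0)
    kept = _enforce_separation(peaks, z[peaks], int(round(cfg.min_separation_ms / 1000.0 * fs)))
    return kept / fs + t0, z[kept]


def _measure_deflection(
    meas: np.ndarray, center: int, fs: float, cfg: SharpwaveConfig
) -> tuple[int, float, float]:
    """Recenter on the minimum in the central window and measure it.

    Returns (recentered index, amplitude uV, FWHM ms) on the 1-40 Hz
    measurement-rate trace ``meas``.
    """
    half_rc = int(round(cfg.recenter_ms / 2.0 / 1000.0 * fs))
    lo = max(center - half_rc, 0)
    hi = min(center + half_rc + 1, meas.size)
    m = lo + int(np.argmin(meas[lo:hi]))
    amp = float(meas[m])
    half_level = amp / 2.0
    max_reach = int(round(0.5 * cfg.snippet_ms / 1000.0 * fs))

    def _crossing(direction: int) -> float | None:
        i = m
        steps = 0
        while 0 < i < meas.size - 1 and steps < max_reach:
            j = i + direction
            if meas[j] >= half_level:
                # linear interpolation between i and j
                frac = (half_level - meas[i]) / (meas[j] - meas[i])
                return i + direction * frac
            i = j
            steps += 1
        return None

    left = _crossing(-1)
    right = _crossing(+1)
    fwhm = np.nan if left is None or right is None else (right - left) / fs * 1000.0
    return m, amp, float(fwhm)


def _raw_average(raw: TimeSeries) -> np.ndarray:
    if raw.n_channels == 1:
        return np.asarray(raw.data[0], dtype=float)
    # accumulate in float64 without materializing a float64 copy of the array
    return raw.data.mean(axis=0, dtype=np.float64)


def _measurement_trace(raw: TimeSeries, cfg: SharpwaveConfig) -> TimeSeries:
    """Channel-average raw trace resampled to the measurement rate, 1-40 Hz."""
    avg = TimeSeries(_raw_average(raw), fs=raw.fs, t0=raw.t0, units=raw.units)
    meas = resample_ts(avg, cfg.measure_fs)
    meas.data = bandpass(meas.data[0], meas.fs, cfg.band)[None, :]
    return meas


def extract_snippets(
    raw: TimeSeries,
    times: np.ndarray,
    cfg: SharpwaveConfig,
    z: np.ndarray | None = None,
    _meas: TimeSeries | None = None,
) -> EventSet:
    """Extract recentered 500 ms snippets and measure amplitude/duration.

    Each event window is recentered on the minimal value of the 1-40 Hz
    trace within the central ``recenter_ms``; amplitude is the signed
    minimum and duration the full width at half magnitude around it.
    Events without full raw coverage are dropped (logged); snippets whose
    high-frequency RMS exceeds ``artifact_rms_ratio`` times the night
    median are rejected as electrical artifacts (logged).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    meas = _measurement_trace(raw, cfg) if _meas is None else _meas
    mx = meas.data[0]
    raw_avg = _raw_average(raw)
    half_raw = int(round(cfg.snippet_ms / 2.0 / 1000.0 * raw.fs))
    n_snip = 2 * half_raw + 1

    keep_times, keep_z, amps, durs, snippets = [], [], [], [], []
    dropped_edge = 0
    for k, t in enumerate(times):
        c_meas = int(round((t - meas.t0) * meas.fs))
        if c_meas < 0 or c_meas >= mx.size:
            dropped_edge += 1
            continue
        m, amp, fwhm = _measure_deflection(mx, c_meas, meas.fs, cfg)
        t_centered = m / meas.fs + meas.t0
        c_raw = int(round((t_centered - raw.t0) * raw.fs))
        if c_raw - half_raw < 0 or c_raw + half_raw + 1 > raw_avg.size:
            dropped_edge += 1
            continue
        snippets.append(raw_avg[c_raw - half_raw:c_raw + half_raw + 1])
        keep_times.append(t_centered)
        keep_z.append(z[k] if z is not None else np.nan)
        amps.append(amp)
        durs.append(fwhm)
    if dropped_edge:
        logger.info("extract_snippets: dropped %d events near recording edges", dropped_edge)
    if not keep_times:
        return EventSet(times=np.empty(0), z_score=np.empty(0), amplitude=np.empty(0),
                        duration=np.empty(0), snippets=np.empty((0, n_snip)),
                        snippet_fs=raw.fs, is_event=True)

    snippets = np.asarray(snippets)
    keep = _artifact_filter(snippets, raw.fs, cfg)
    return EventSet(
        times=np.asarray(keep_times)[keep],
        z_score=np.asarray(keep_z)[keep],
        amplitude=np.asarray(amps)[keep],
        duration=np.asarray(durs)[keep],
        snippets=snippets[keep],
        snippet_fs=raw.fs,
        is_event=True,
    )


def _artifact_filter(snippets: np.ndarray, fs: float, cfg: SharpwaveConfig) -> np.ndarray:
    """Boolean keep-mask rejecting snippets with outlier high-frequency RMS."""
    if snippets.shape[0] < 3 or cfg.artifact_band[1] >= fs / 2:
        return np.ones(snippets.shape[0], dtype=bool)
    hf = bandpass(snippets, fs, cfg.artifact_band)
    rms = np.sqrt(np.mean(hf**2, axis=1))
    keep = rms <= cfg.artifact_rms_ratio * np.median(rms)
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("artifact filter rejected %d snippets", n_rej)
    return keep


def sample_non_events(
    raw: TimeSeries,
    mask: MovementMask | None,
    events: EventSet,
    n: int | None = None,
    seed: int = 0,
    cfg: SharpwaveConfig | None = None,
) -> EventSet:
    """Random 500 ms windows disjoint from movement and detected events."""
    cfg = cfg or SharpwaveConfig()
    if n is None:
        n = len(events)
    rng = np.random.default_rng(seed)
    raw_avg = _raw_average(raw)
    half_s = cfg.snippet_ms / 2.0 / 1000.0
    half_raw = int(round(half_s * raw.fs))
    n_snip = 2 * half_raw + 1
    duration = raw.duration

    def eligible(t: float) -> bool:
        if t - half_s < 0 or t + half_s > duration:
            return False
        for et in events.times:
            if abs(t - et) < cfg.snippet_ms / 1000.0:
                return False
        if mask is not None:
            i0 = max(int((t - half_s - raw.t0) * mask.fs), 0)
            i1 = min(int((t + half_s - raw.t0) * mask.fs) + 1, mask.mask.size)
            if mask.mask[i0:i1].any():
                return False
        return True

    times: list[float] = []
    attempts = 0
    max_attempts = max(2000, 1000 * n)
    while len(times) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} non-event windows ({len(times)} placed): "
                "insufficient eligible time without movement or events"
            )
        t = rng.uniform(half_s, duration - half_s)
        if any(abs(t - u) < cfg.snippet_ms / 1000.0 for u in times):
            continue
        if eligible(t):
            times.append(t)
    times_arr = np.sort(np.asarray(times))
    snippets = np.empty((n, n_snip))
    for i, t in enumerate(times_arr):
        c = int(round((t - raw.t0) * raw.fs))
        snippets[i] = raw_avg[c - half_raw:c + half_raw + 1]
    return EventSet(times=times_arr, snippets=snippets, snippet_fs=raw.fs, is_event=False)


def nightly_stats(
    events: EventSet, night_bounds: tuple[float, float], unmasked_duration_s: float | None = None
) -> dict:
    """Per-night event rate and amplitude/duration summaries.

    Rate is events per minute of unmasked night time; amplitude and
    duration get both mean +- SD and median/MAD summaries.
    """
    t0, t1 = night_bounds
    if t1 <= t0:
        raise ValueError("night bounds must span a positive duration")
    duration = unmasked_duration_s if unmasked_duration_s is not None else t1 - t0
    if duration <= 0:
        raise ValueError("unmasked night duration must be positive")
    in_night = (events.times >= t0) & (events.times <= t1)
    count = int(in_night.sum())
    out = {"n_events": count, "rate_per_min": count / (duration / 60.0)}
    for name in ("amplitude", "duration"):
        vals = getattr(events, name)
        if vals is None or count == 0:
            continue
        vals = np.asarray(vals, dtype=float)[in_night]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[f"{name}_median"] = med
        out[f"{name}_mad"] = float(np.median(np.abs(vals - med)))
    return out


def run_sharpwave_detection(
    raw: TimeSeries,
    accel: TimeSeries | None = None,
    cfg: SharpwaveConfig | None = None,
    mask_kwargs: dict | None = None,
) -> dict:
    """Full detection chain on one night.

    Resample to the working rate, build the movement mask (if an
    accelerometer is given), average channels and bandpass 1-40 Hz, run
    candidate detection -> template -> z-scored correlation -> final
    events, then extract and measure snippets.  Returns a dict with the
    intermediates and the final :class:`EventSet`.
    """
    cfg = cfg or SharpwaveConfig()
    # averaging commutes with the (linear) resampler, so average at the raw
    # rate first and resample one channel instead of all of them
    avg = TimeSeries(_raw_average(raw), fs=raw.fs, t0=raw.t0, units=raw.units)
    work = resample_ts(avg, cfg.working_fs) if raw.fs != cfg.working_fs else avg
    lfp125 = average_and_band(work, cfg.band)
    mask = None
    if accel is not None:
        accel125 = resample_ts(accel, cfg.working_fs) if accel.fs != cfg.working_fs else accel
        mask = movement_mask(accel125, **(mask_kwargs or {}))
    else:
        logger.warning("no accelerometer provided: movement masking disabled")
    candidates = detect_candidates(lfp125, mask, cfg)
    if candidates.size == 0:
        empty = EventSet(times=np.empty(0), is_event=True)
        return {"lfp_working": lfp125, "mask": mask, "candidates": candidates,
                "template": None, "zscores": None, "events": empty}
    template = build_template(lfp125, candidates, cfg)
    zscores = score_template(lfp125, template, mask)
    times, zvals = detect_events(zscores, cfg, fs=lfp125.fs, t0=lfp125.t0)
    # the channel average is already in hand; snippets come from it anyway
    events = extract_snippets(avg, times, cfg, z=zvals)
    return {
        "lfp_working": lfp125,
        "mask": mask,
        "candidates": candidates,
        "template": template,
        "zscores": zscores,
        "events": events,
    }
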