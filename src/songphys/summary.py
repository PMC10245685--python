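"""Per-syllable acoustic summaries and corpus-level degradation metrics.

Each song segment is summarized by seven numbers: average mean frequency,
average pitch, maximum goodness of pitch, maximum log power, minimum
Wiener entropy and entropy variance — all over the first 50 ms of the
segment (or the whole segment if shorter) — plus the full segment
duration.  Summaries are z-scored against a pre-perturbation baseline,
embedded in a PCA space fit on hand-labeled reference syllables, and
aggregated into daily trends and duration distributions.  A continuous
bout-trajectory embedding parameterizes sliding 150 ms windows by a
20 ms / 5 ms moving-average stack of six features reduced to 30 principal
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "SUMMARY_FEATURES",
    "BaselineStats",
    "summarize_segments",
    "normalize_to_baseline",
    "daily_trend",
    "syllable_pca",
    "duration_matrix",
    "TrajectoryConfig",
    "bout_trajectory",
]

SUMMARY_FEATURES = [
    "avg_mean_frequency",
    "avg_pitch",
    "max_goodness",
    "max_log_power",
    "min_entropy",
    "entropy_variance",
    "duration_ms",
]


def summarize_segments(
    track: pd.DataFrame, segments: pd.DataFrame, window_ms: float = 50.0
) -> pd.DataFrame:
    """Seven-dimensional acoustic summary of every song segment.

    Statistics are computed over the first ``window_ms`` of each segment
    (the whole segment if shorter); duration is copied from the segment
    table.
    """
    step_ms = float(track.attrs.get("step_ms", 1.0))
    times = track["time_ms"].to_numpy()
    rows = []
    for seg in segments.itertuples(index=False):
        if seg.onset_ms < times[0] - step_ms or seg.offset_ms > times[-1] + step_ms:
            raise ValueError(
                f"segment [{seg.onset_ms}, {seg.offset_ms}] ms outside track extent"
            )
        stop_ms = min(seg.onset_ms + window_ms, seg.offset_ms)
        sel = (times >= seg.onset_ms) & (times < stop_ms)
        if not sel.any():  # degenerate sub-ms segment: take nearest frame
            sel = np.zeros_like(sel)
            sel[np.argmin(np.abs(times - seg.onset_ms))] = True
        chunk = track.loc[sel]
        rows.append(
            {
                "avg_mean_frequency": chunk["mean_frequency_hz"].mean(),
                "avg_pitch": chunk["pitch_hz"].mean(),
                "max_goodness": chunk["goodness"].max(),
                "max_log_power": chunk["log_power_db"].max(),
                "min_entropy": chunk["wiener_entropy"].min(),
                "entropy_variance": chunk["wiener_entropy"].var(ddof=0),
                "duration_ms": seg.duration_ms,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_FEATURES)


@dataclass
class BaselineStats:
    """Per-feature mean and SD from the 5 days before perturbation."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def from_features(cls, features: pd.DataFrame) -> "BaselineStats":
        mean = features[SUMMARY_FEATURES].mean()
        sd = features[SUMMARY_FEATURES].std(ddof=0)
        degenerate = sd.index[sd <= 0].tolist()
        if degenerate:
            raise ValueError(f"zero-SD baseline feature(s): {degenerate}")
        return cls(mean=mean, sd=sd)


def normalize_to_baseline(features: pd.DataFrame, baseline: BaselineStats) -> pd.DataFrame:
    """z = (x - baseline mean) / baseline SD, per feature."""
    degenerate = baseline.sd.index[baseline.sd <= 0].tolist()
    if degenerate:
        raise ValueError(f"zero-SD baseline feature(s): {degenerate}")
    out = features.copy()
    for col in SUMMARY_FEATURES:
        out[col] = (features[col] - baseline.mean[col]) / baseline.sd[col]
    return out


def daily_trend(
    features: pd.DataFrame, day_column: str = "day", window_days: int = 3
) -> pd.DataFrame:
    """Per-day feature averages over the ``window_days`` nearest recorded days.

    For each plotted day, syllables from the ``window_days`` recorded days
    closest in time are pooled; the trend value is their mean and the
    error the standard error of that pool.  Days with no data in the
    window are reported as missing (NaN), never interpolated.
    """
    if day_column not in features.columns:
        raise ValueError(f"missing day column {day_column!r}")
    days = np.sort(features[day_column].unique())
    rows = []
    for day in days:
        nearest = days[np.argsort(np.abs(days - day), kind="stable")[:window_days]]
        pool = features[features[day_column].isin(nearest)]
        row: dict = {"day": day, "n": len(pool)}
        for col in SUMMARY_FEATURES:
            if col not in features.columns:
                continue
            vals = pool[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[col], row[f"{col}_se"] = np.nan, np.nan
            else:
                row[col] = vals.mean()
                row[f"{col}_se"] = (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Orient each component so its largest-magnitude loading is positive."""
    flip = np.sign(components[np.arange(components.shape[0]), np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return components * flip[:, None]


def syllable_pca(
    labeled: pd.DataFrame, others: pd.DataFrame | None = None, n_components: int = 2
) -> tuple[pd.DataFrame, PCA]:
    """PCA embedding of 7-dim syllable features.

    Components are fit on the labeled reference set only (features should
    already be baseline-standardized); all other segments are projected
    into that space.  Component signs follow the convention that the
    largest-magnitude loading is positive.
    """
    X = labeled[SUMMARY_FEATURES].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 labeled syllables to fit PCA")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < n_components:
        raise ValueError("labeled feature set is rank-deficient for the requested components")
    pca = PCA(n_components=n_components)
    pca.fit(X)
    pca.components_ = _fix_signs(pca.components_)
    frames = [labeled] if others is None else [labeled, others]
    labels = ["labeled"] * len(labeled) + ([] if others is None else ["other"] * len(others))
    all_X = pd.concat(frames, ignore_index=True)[SUMMARY_FEATURES].to_numpy(dtype=float)
    coords = pca.transform(all_X)
    out = pd.DataFrame(coords, columns=[f"pc{i + 1}" for i in range(n_components)])
    out["set"] = labels
    return out, pca


def duration_matrix(
    segments: pd.DataFrame,
    bin_edges: np.ndarray | None = None,
    day_column: str = "day",
) -> pd.DataFrame:
    """Column-normalized daily histograms of segment durations.

    Rows are duration bins (default 5 ms from 0 to 1000 ms), columns are
    days; each column with data sums to one. Empty days are all-NaN
    columns (flagged missing, not zero).
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 1000.0 + 5.0, 5.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    durations = segments["duration_ms"].to_numpy(dtype=float)
    if durations.size and (
        durations.min() < bin_edges[0] or durations.max() > bin_edges[-1]
    ):
        raise ValueError("bin edges do not cover the observed durations")
    days = np.sort(segments[day_column].unique())
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    out = pd.DataFrame(index=pd.Index(centers, name="duration_ms"))
    for day in days:
        vals = segments.loc[segments[day_column] == day, "duration_ms"].to_numpy(dtype=float)
        if vals.size == 0:
            out[day] = np.nan
            continue
        hist, _ = np.histogram(vals, bins=bin_edges)
        out[day] = hist / hist.sum()
    return out


@dataclass
class TrajectoryConfig:
    """Sliding-window bout parameterization.

    A 150 ms window slides in 3 ms steps; inside each window six features
    are summarized by 20 ms moving averages every 5 ms, and the stacked
    description is reduced to 30 principal components fit across the
    sampled bouts.
    """

    window_ms: float = 150.0
    step_ms: float = 3.0
    avg_len_ms: float = 20.0
    avg_step_ms: float = 5.0
    n_components: int = 30
    features: tuple[str, ...] = (
        "mean_frequency_hz",
        "pitch_hz",
        "goodness",
        "power_q4",
        "power_q2",
        "log_power_db",
    )


def _window_descriptor(chunk: np.ndarray, cfg: TrajectoryConfig, step_ms: float) -> np.ndarray:
    """20 ms / 5 ms moving-average stack of one 150 ms feature window."""
    avg_len = max(int(round(cfg.avg_len_ms / step_ms)), 1)
    avg_step = max(int(round(cfg.avg_step_ms / step_ms)), 1)
    starts = np.arange(0, chunk.shape[0] - avg_len + 1, avg_step)
    return np.concatenate(
        [chunk[s:s + avg_len].mean(axis=0) for s in starts]
    )


def bout_trajectory(
    bouts: list[pd.DataFrame], cfg: TrajectoryConfig | None = None
) -> tuple[pd.DataFrame, PCA]:
    """Continuous low-dimensional trajectory of each bout.

    Bouts shorter than one window are skipped.  Returns per-window PCA
    coordinates with bout id and window start time, plus the fitted PCA.
    """
    cfg = cfg or TrajectoryConfig()
    descriptors = []
    meta = []
    for bout_id, track in enumerate(bouts):
        step_ms = float(track.attrs.get("step_ms", 1.0))
        X = track[list(cfg.features)].to_numpy(dtype=float)
        win = int(round(cfg.window_ms / step_ms))
        step = max(int(round(cfg.step_ms / step_ms)), 1)
        if X.shape[0] < win:
            continue
        for start in range(0, X.shape[0] - win + 1, step):
            descriptors.append(_window_descriptor(X[start:start + win], cfg, step_ms))
            meta.append((bout_id, start * step_ms))
    if not descriptors:
        raise ValueError("no bout is at least one window long")
    D = np.asarray(descriptors)
    n_comp = min(cfg.n_components, D.shape[0], D.shape[1])
    if n_comp < cfg.n_components:
        raise ValueError(
            f"only {n_comp} components supported by {D.shape[0]} windows x {D.shape[1]} dims; "
            f"need {cfg.n_components}"
        )
    pca = PCA(n_components=cfg.n_components)
    coords = pca.fit_transform(D)
    pca.components_ = _fix_signs(pca.components_)
    coords = pca.transform(D)
    out = pd.DataFrame(coords, columns=[f"pc{i + 1}" for i in range(cfg.n_components)])
    out.insert(0, "bout", [m[0] for m in meta])
    out.insert(1, "window_start_ms", [m[1] for m in meta])
    return out, pca
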