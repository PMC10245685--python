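"""Independent brute-force reference implementations used by the tests.

Each oracle applies the detection/segmentation/statistics rules literally,
by exhaustive scanning, with no shared code with the package paths it
checks.
"""

from __future__ import annotations

import numpy as np


def candidate_oracle(
    x: np.ndarray,
    active: np.ndarray,
    percentile: float,
    min_run: int,
    min_gap: int,
) -> list[int]:
    """Literal first-pass candidate rules: percentile, run length, spacing."""
    threshold = np.quantile(x[active], percentile / 100.0)
    below = (x < threshold) & active
    # exhaustive run scan
    runs = []
    i = 0
    n = x.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    anchors = []
    for s, e in runs:
        best = s
        for k in range(s, e):
            if x[k] < x[best]:
                best = k
        anchors.append(best)
    # spacing: repeatedly keep the deepest remaining anchor (earlier on ties)
    remaining = sorted(anchors, key=lambda a: (x[a], a))
    kept: list[int] = []
    for a in remaining:
        if all(abs(a - b) >= min_gap for b in kept):
            kept.append(a)
    return sorted(kept)


def greedy_peak_oracle(z: np.ndarray, threshold: float, min_gap: int) -> list[int]:
    """Literal greedy peak exclusion on a z trace (NaNs never peak)."""
    peaks = []
    for i in range(1, z.size - 1):
        if np.isnan(z[i - 1]) or np.isnan(z[i]) or np.isnan(z[i + 1]):
            continue
        if z[i] > z[i - 1] and z[i] >= z[i + 1] and z[i] > threshold:
            peaks.append(i)
    order = sorted(peaks, key=lambda i: (-z[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    return sorted(kept)


def sliding_correlation_oracle(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """O(N*M) sliding dot product, aligned at the template center."""
    n, m = x.size, w.size
    half = m // 2
    out = np.full(n, np.nan)
    for i in range(n):
        start = i - half
        if start < 0 or start + m > n:
            continue
        acc = 0.0
        for j in range(m):
            acc += x[start + j] * w[j]
        out[i] = acc
    return out


def teager_oracle(x: np.ndarray) -> np.ndarray:
    """Three-term loop for the local energy operator."""
    psi = np.empty(x.size)
    for i in range(1, x.size - 1):
        psi[i] = x[i] * x[i] - x[i - 1] * x[i + 1]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def ranksum_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum z statistic from explicit mid-ranks (no library call)."""
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="stable")
    ranks = np.empty(combined.size)
    # mid-ranks for ties
    sorted_vals = combined[order]
    i = 0
    while i < combined.size:
        j = i
        while j < combined.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    n1, n2 = a.size, b.size
    w = ranks[:n1].sum()
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (w - expected) / sd


def segmentation_oracle(
    above: np.ndarray, min_silence: int, min_segment: int
) -> list[tuple[int, int]]:
    """Literal two-pass segmentation on a boolean trace (1 sample = 1 ms).

    Pass 1 converts every internal silence shorter than ``min_silence`` to
    song simultaneously; pass 2 drops segments shorter than ``min_segment``.
    """
    voiced = above.copy()
    n = voiced.size
    # find internal silences (False runs bounded by True on both sides)
    i = 0
    while i < n:
        if not voiced[i]:
            j = i
            while j < n and not voiced[j]:
                j += 1
            internal = i > 0 and j < n
            if internal and (j - i) < min_silence:
                voiced[i:j] = True
            i = j
        else:
            i += 1
    segments = []
    i = 0
    while i < n:
        if voiced[i]:
            j = i
            while j < n and voiced[j]:
                j += 1
            if j - i >= min_segment:
                segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def autocorr_pitch_oracle(
    frame: np.ndarray, fs: float, f_lo: float, f_hi: float
) -> float:
    """Fundamental from the autocorrelation peak in [f_lo, f_hi]."""
    frame = frame - frame.mean()
    ac = np.correlate(frame, frame, mode="full")[frame.size - 1:]
    lag_lo = int(np.floor(fs / f_hi))
    lag_hi = int(np.ceil(fs / f_lo))
    lag = lag_lo + int(np.argmax(ac[lag_lo:lag_hi + 1]))
    return fs / lag


def match_events(
    truth_times: np.ndarray, detected_times: np.ndarray, tol_s: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    truth = list(np.sort(truth_times))
    tp = 0
    for t in np.sort(detected_times):
        best = None
        for k, u in enumerate(truth):
            if abs(t - u) <= tol_s and (best is None or abs(t - u) < abs(t - truth[best])):
                best = k
        if best is not None:
            truth.pop(best)
            tp += 1
    fp = len(detected_times) - tp
    fn = len(truth_times) - tp
    return tp, fp, fn
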