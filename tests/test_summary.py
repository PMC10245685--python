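"""Syllable summaries, baseline normalization, PCA, durations, trajectories."""

import numpy as np
import pandas as pd
import pytest

from songphys.summary import (
    SUMMARY_FEATURES,
    BaselineStats,
    TrajectoryConfig,
    bout_trajectory,
    daily_trend,
    duration_matrix,
    normalize_to_baseline,
    summarize_segments,
    syllable_pca,
)


def _track(n_ms=200, **columns):
    base = {
        "time_ms": np.arange(n_ms, dtype=float),
        "pitch_hz": np.full(n_ms, 600.0),
        "goodness": np.full(n_ms, 2.0),
        "wiener_entropy": np.full(n_ms, -3.0),
        "log_power_db": np.full(n_ms, -10.0),
        "mean_frequency_hz": np.full(n_ms, 2500.0),
        "power_q1": np.zeros(n_ms),
        "power_q2": np.zeros(n_ms),
        "power_q3": np.zeros(n_ms),
        "power_q4": np.zeros(n_ms),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    track = pd.DataFrame(base)
    track.attrs["step_ms"] = 1.0
    return track


def _segments(*pairs):
    return pd.DataFrame(
        [
            {"onset_ms": a, "offset_ms": b, "duration_ms": b - a, "source_bout": 0}
            for a, b in pairs
        ]
    )


class TestSummarize:
    def test_constant_features(self):
        feats = summarize_segments(_track(), _segments((20.0, 120.0)))
        row = feats.iloc[0]
        assert row["avg_mean_frequency"] == 2500.0
        assert row["avg_pitch"] == 600.0
        assert row["entropy_variance"] == 0.0
        assert row["duration_ms"] == 100.0

    def test_short_segment_uses_whole_extent(self):
        # a 40 ms segment is summarized over all 40 ms, not 50
        track = _track(pitch_hz=np.concatenate([np.full(100, 500.0), np.full(100, 900.0)]))
        feats = summarize_segments(track, _segments((80.0, 120.0)))
        # frames 80..119: 20 at 500 Hz + 20 at 900 Hz
        assert feats["avg_pitch"].iloc[0] == pytest.approx(700.0)

    def test_first_50ms_window(self):
        track = _track(wiener_entropy=-np.linspace(1.0, 5.0, 200))
        feats = summarize_segments(track, _segments((0.0, 200.0)))
        # min over the first 50 ms only: the ramp is decreasing, so the
        # minimum within the window sits at frame 49
        scan_min = track["wiener_entropy"].iloc[:50].min()
        assert feats["min_entropy"].iloc[0] == scan_min
        assert scan_min > track["wiener_entropy"].min()

    def test_ramped_entropy_matches_scan_oracle(self, rng):
        vals = rng.standard_normal(200) - 3.0
        track = _track(wiener_entropy=vals)
        feats = summarize_segments(track, _segments((10.0, 90.0)))
        window = vals[10:60]  # first 50 ms of the segment
        assert feats["min_entropy"].iloc[0] == window.min()
        assert feats["entropy_variance"].iloc[0] == pytest.approx(window.var())

    def test_segment_outside_track_raises(self):
        with pytest.raises(ValueError):
            summarize_segments(_track(100), _segments((50.0, 150.0)))


class TestBaseline:
    def _features(self, rng, n=50):
        data = rng.standard_normal((n, 7)) * 3.0 + 10.0
        return pd.DataFrame(data, columns=SUMMARY_FEATURES)

    def test_mean_maps_to_zero_and_sd_to_one(self, rng):
        feats = self._features(rng)
        baseline = BaselineStats.from_features(feats)
        at_mean = pd.DataFrame([baseline.mean], columns=SUMMARY_FEATURES)
        z = normalize_to_baseline(at_mean, baseline)
        np.testing.assert_allclose(z.iloc[0].values.astype(float), 0.0, atol=1e-12)
        plus_sd = pd.DataFrame([baseline.mean + baseline.sd], columns=SUMMARY_FEATURES)
        z1 = normalize_to_baseline(plus_sd, baseline)
        np.testing.assert_allclose(z1.iloc[0].values.astype(float), 1.0, atol=1e-12)

    def test_matches_recompute_oracle(self, rng):
        feats = self._features(rng)
        baseline = BaselineStats.from_features(feats)
        z = normalize_to_baseline(feats, baseline)
        for col in SUMMARY_FEATURES:
            want = (feats[col] - feats[col].mean()) / feats[col].std(ddof=0)
            np.testing.assert_allclose(z[col], want, atol=1e-12)

    def test_zero_sd_named_in_error(self, rng):
        feats = self._features(rng)
        feats["avg_pitch"] = 5.0
        with pytest.raises(ValueError, match="avg_pitch"):
            BaselineStats.from_features(feats)


class TestDailyTrend:
    def test_single_day_equals_mean(self, rng):
        feats = pd.DataFrame(
            {c: rng.standard_normal(20) for c in SUMMARY_FEATURES} | {"day": 3}
        )
        trend = daily_trend(feats)
        assert len(trend) == 1
        assert trend["avg_pitch"].iloc[0] == pytest.approx(feats["avg_pitch"].mean())

    def test_constant_feature_zero_se(self):
        feats = pd.DataFrame(
            {c: 1.0 for c in SUMMARY_FEATURES} | {"day": [1] * 5 + [2] * 5}
        )
        trend = daily_trend(feats)
        assert (trend["avg_pitch_se"] == 0.0).all()

    def test_drift_recovered_within_2se(self, rng):
        days = np.repeat(np.arange(10), 30)
        drift = 0.2 * days  # linear drift in one feature
        feats = pd.DataFrame({c: 0.0 for c in SUMMARY_FEATURES} | {"day": days})
        feats["avg_pitch"] = drift + 0.5 * rng.standard_normal(len(days))
        trend = daily_trend(feats, window_days=3)
        for row in trend.itertuples():
            # the 3-day window average of the generating line
            nearest = np.sort(np.argsort(np.abs(np.arange(10) - row.day))[:3])
            want = (0.2 * nearest).mean()
            assert abs(row.avg_pitch - want) <= 2 * row.avg_pitch_se + 1e-9


class TestSyllablePca:
    def test_two_clusters_separate_in_pc1(self, rng):
        a = rng.standard_normal((50, 7)) * 0.1
        b = rng.standard_normal((50, 7)) * 0.1 + np.array([5, 5, 5, 5, 5, 5, 5])
        labeled = pd.DataFrame(np.vstack([a, b]), columns=SUMMARY_FEATURES)
        coords, _ = syllable_pca(labeled)
        pc1 = coords["pc1"].to_numpy()
        assert abs(pc1[:50].mean() - pc1[50:].mean()) > 3.0

    def test_projection_identity(self, rng):
        labeled = pd.DataFrame(rng.standard_normal((30, 7)), columns=SUMMARY_FEATURES)
        coords, pca = syllable_pca(labeled)
        again = pca.transform(labeled[SUMMARY_FEATURES].to_numpy())
        np.testing.assert_allclose(coords[["pc1", "pc2"]].to_numpy(), again, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        labeled = pd.DataFrame(rng.standard_normal((100, 7)), columns=SUMMARY_FEATURES)
        _, pca = syllable_pca(labeled)
        X = labeled.to_numpy()
        cov = np.cov(X - X.mean(axis=0), rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        top = evecs[:, np.argsort(evals)[::-1][:2]].T
        for row, want in zip(pca.components_, top):
            assert min(np.abs(row - want).max(), np.abs(row + want).max()) < 1e-9

    def test_rank_deficient_rejected(self):
        labeled = pd.DataFrame(np.ones((10, 7)), columns=SUMMARY_FEATURES)
        with pytest.raises(ValueError):
            syllable_pca(labeled)


class TestDurationMatrix:
    def test_single_segment_single_bin(self):
        segs = pd.DataFrame({"duration_ms": [30.0], "day": [1]})
        mat = duration_matrix(segs)
        col = mat[1]
        assert col.loc[32.5] == 1.0  # the 30-35 ms bin
        assert col.sum() == pytest.approx(1.0)

    def test_columns_sum_to_one(self, rng):
        segs = pd.DataFrame(
            {"duration_ms": rng.uniform(10, 900, 500), "day": rng.integers(0, 5, 500)}
        )
        mat = duration_matrix(segs)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-9)

    def test_bimodal_modes_recovered(self, rng):
        durations = np.concatenate(
            [rng.normal(25, 2, 300).clip(5, 95), rng.normal(700, 10, 300)]
        )
        segs = pd.DataFrame({"duration_ms": durations, "day": 0})
        mat = duration_matrix(segs)
        col = mat[0].to_numpy()
        centers = mat.index.to_numpy()
        peaks = centers[np.argsort(col)[::-1][:6]]
        assert np.any(np.abs(peaks - 25) <= 10)
        assert np.any(np.abs(peaks - 700) <= 15)

    def test_uncovered_durations_rejected(self):
        segs = pd.DataFrame({"duration_ms": [1500.0], "day": [0]})
        with pytest.raises(ValueError):
            duration_matrix(segs)


class TestBoutTrajectory:
    def _bout(self, rng, n_ms=300, jitter=0.0, seed_offset=0):
        local = np.random.default_rng(1000 + seed_offset)
        base = {
            "mean_frequency_hz": 2500 + 500 * np.sin(np.arange(n_ms) / 20.0),
            "pitch_hz": np.full(n_ms, 600.0),
            "goodness": np.linspace(1, 3, n_ms),
            "power_q4": np.zeros(n_ms),
            "power_q2": np.zeros(n_ms),
            "log_power_db": np.full(n_ms, -10.0),
        }
        if jitter:
            for key in base:
                base[key] = base[key] + jitter * local.standard_normal(n_ms)
        return _track(n_ms, **base)

    def test_window_count_arithmetic(self, rng):
        # floor((300 - 150) / 3) + 1 = 51 windows for a 300 ms bout
        bouts = [self._bout(rng, seed_offset=i) for i in range(3)]
        coords, _ = bout_trajectory(bouts, TrajectoryConfig(n_components=10))
        assert (coords["bout"] == 0).sum() == 51

    def test_identical_bouts_identical_trajectories(self, rng):
        bouts = [self._bout(rng), self._bout(rng)]
        coords, _ = bout_trajectory(bouts, TrajectoryConfig(n_components=10))
        a = coords[coords["bout"] == 0].filter(like="pc").to_numpy()
        b = coords[coords["bout"] == 1].filter(like="pc").to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_short_bouts_skipped(self, rng):
        bouts = [self._bout(rng, n_ms=100), self._bout(rng, n_ms=300)]
        coords, _ = bout_trajectory(bouts, TrajectoryConfig(n_components=10))
        assert set(coords["bout"]) == {1}

    def test_degraded_corpus_more_dispersed(self, rng):
        stereo = [self._bout(rng, seed_offset=i) for i in range(4)]
        degraded = [self._bout(rng, jitter=30.0, seed_offset=10 + i) for i in range(4)]
        coords, _ = bout_trajectory(stereo + degraded, TrajectoryConfig(n_components=10))

        def dispersion(ids):
            mats = [
                coords[coords["bout"] == i].filter(like="pc").to_numpy() for i in ids
            ]
            dists = [
                np.linalg.norm(a - b, axis=1).mean()
                for i, a in enumerate(mats)
                for b in mats[i + 1:]
            ]
            return np.mean(dists)

        assert dispersion([4, 5, 6, 7]) > dispersion([0, 1, 2, 3])


def test_variability_decreases_with_generator_jitter(rng):
    """Per-syllable feature SD tracks the generator's jitter monotonically."""
    from songphys.songfeat import SegmentationConfig, compute_feature_track, segment_bout
    from songphys.summary import summarize_segments
    from songphys.synth import SongDegradation, SynthSongSpec, gen_song

    sds = []
    for jitter in (0.0, 0.08):
        spec = SynthSongSpec(
            n_bouts=6,
            degradation=SongDegradation(f0_jitter_frac=jitter),
            seed=31,
        )
        audio, truth = gen_song(spec)
        track = compute_feature_track(audio)
        feats = summarize_segments(track, truth.rename(columns={}).assign(
            duration_ms=truth["duration_ms"]))
        sds.append(feats["avg_pitch"].std())
    assert sds[1] > sds[0]
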