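"""Sharp-wave detector: rule conformance, oracle equivalence, recovery."""

import numpy as np
import pytest

from oracles import (
    candidate_oracle,
    greedy_peak_oracle,
    match_events,
    sliding_correlation_oracle,
)
from songphys.core import EventSet, TimeSeries
from songphys.preprocess import MovementMask
from songphys.sharpwave import (
    SharpwaveConfig,
    Template,
    build_template,
    detect_candidates,
    detect_events,
    extract_snippets,
    nightly_stats,
    run_sharpwave_detection,
    sample_non_events,
    score_template,
)
from songphys.synth import SynthLfpSpec, deflection_waveform, gen_lfp

CFG = SharpwaveConfig()


def _ts(x, fs=125.0):
    return TimeSeries(np.asarray(x, dtype=float), fs=fs)


class TestDetectCandidates:
    def test_two_separated_dips(self, rng):
        # the dips supply ~5% of all samples, so the percentile threshold
        # separates them cleanly from the noise floor
        x = rng.standard_normal(125) * 0.1
        x[40:43] -= 10.0  # 24 ms dip
        x[65:68] -= 8.0  # 200 ms later
        times = detect_candidates(_ts(x), None, CFG)
        assert times.size == 2
        got = np.round(times * 125).astype(int)
        assert got[0] == 40 + np.argmin(x[40:43])
        assert got[1] == 65 + np.argmin(x[65:68])

    def test_close_dips_keep_deeper(self, rng):
        x = rng.standard_normal(125) * 0.1
        x[40:43] -= 8.0
        x[46:49] -= 10.0  # 48 ms later: within the 80 ms exclusion
        times = detect_candidates(_ts(x), None, CFG)
        assert times.size == 1
        assert int(round(times[0] * 125)) == 46 + int(np.argmin(x[46:49]))

    def test_all_masked_raises(self):
        mask = MovementMask(mask=np.ones(100, dtype=bool), fs=125.0, window_s=1, threshold=0)
        with pytest.raises(ValueError, match="no non-movement"):
            detect_candidates(_ts(np.zeros(100)), mask, CFG)

    def test_matches_bruteforce_oracle(self, rng):
        min_run = int(np.ceil(CFG.min_candidate_ms / 1000 * 125))
        for _ in range(100):
            n = int(rng.integers(200, 800))
            x = rng.standard_normal(n)
            active = rng.random(n) > 0.2
            if not active.any():
                active[0] = True
            mask = MovementMask(mask=~active, fs=125.0, window_s=1, threshold=0)
            got = np.round(detect_candidates(_ts(x), mask, CFG) * 125).astype(int)
            want = candidate_oracle(x, active, CFG.candidate_percentile, min_run,
                                    CFG.separation_samples)
            np.testing.assert_array_equal(got, want)

    def test_threshold_passes_five_percent(self, rng):
        # fuzzed separately in the acceptance suite; single spot check here
        x = rng.standard_normal(5000)
        threshold = np.quantile(x, 0.05)
        assert abs((x < threshold).mean() - 0.05) <= 1 / 5000 + 1e-9


class TestBuildTemplate:
    def test_identical_waveforms_recovered(self):
        x = np.zeros(2000)
        w = -deflection_waveform(-1.0, 40.0, 125.0)  # any symmetric bump
        w = deflection_waveform(-5.0, 40.0, 125.0)
        centers = [300, 700, 1100]
        for c in centers:
            x[c - w.size // 2:c + w.size // 2 + 1] += w
        tpl = build_template(_ts(x), np.array(centers) / 125.0, CFG)
        n_t = CFG.template_samples
        ref = x[centers[0] - n_t // 2:centers[0] - n_t // 2 + n_t]
        np.testing.assert_allclose(tpl.waveform, ref, atol=1e-9)
        assert tpl.n_candidates == 3

    def test_single_candidate_identity(self, rng):
        x = rng.standard_normal(500)
        tpl = build_template(_ts(x), np.array([250 / 125.0]), CFG)
        n_t = CFG.template_samples
        np.testing.assert_array_equal(tpl.waveform, x[250 - n_t // 2:250 - n_t // 2 + n_t])

    def test_noise_template_shrinks_with_candidate_count(self, rng):
        # averaging k independent noise windows shrinks the template ~1/sqrt(k)
        x = rng.standard_normal(60000)
        few = build_template(_ts(x), np.arange(4) * 40.0 + 10.0, CFG)
        many = build_template(_ts(x), np.arange(64) * 7.0 + 10.0, CFG)
        ratio = np.abs(few.waveform).max() / np.abs(many.waveform).max()
        expected = np.sqrt(64 / 4)
        assert expected / 2.5 < ratio < expected * 2.5

    def test_no_usable_candidate_raises(self):
        with pytest.raises(ValueError):
            build_template(_ts(np.zeros(20)), np.array([0.01]), CFG)


class TestScoreTemplate:
    def test_matched_filter_peaks_at_insertion(self):
        x = np.zeros(2000)
        w = deflection_waveform(-5.0, 40.0, 125.0)
        c = 900
        x[c - w.size // 2:c + w.size // 2 + 1] += w
        tpl = build_template(_ts(x), np.array([c / 125.0]), CFG)
        z = score_template(_ts(x), tpl, None)
        assert np.nanargmax(z) == c

    def test_zscore_contract(self, rng):
        x = rng.standard_normal(3000)
        tpl = Template(waveform=rng.standard_normal(10), fs=125.0, n_candidates=1)
        z = score_template(_ts(x), tpl, None)
        finite = z[np.isfinite(z)]
        assert abs(finite.mean()) < 1e-9
        assert abs(finite.std() - 1.0) < 1e-9

    def test_matches_naive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(50, 300))
            x = rng.standard_normal(n)
            m = int(rng.integers(4, 20))
            w = rng.standard_normal(m)
            tpl = Template(waveform=w, fs=125.0, n_candidates=1)
            z = score_template(_ts(x), tpl, None)
            raw = sliding_correlation_oracle(x, w)
            finite = np.isfinite(raw)
            z_oracle = (raw - raw[finite].mean()) / raw[finite].std()
            np.testing.assert_allclose(z[finite], z_oracle[finite], atol=1e-6)


class TestDetectEvents:
    def test_subthreshold_empty(self):
        times, _ = detect_events(np.ones(500), CFG)
        assert times.size == 0

    def test_close_peaks_keep_larger(self):
        z = np.zeros(1000)
        z[500] = 5.0
        z[505] = 6.0  # 40 ms later
        times, zvals = detect_events(z, CFG)
        assert times.size == 1 and zvals[0] == 6.0

    def test_matches_greedy_oracle(self, rng):
        gap = CFG.separation_samples
        for _ in range(100):
            z = rng.standard_normal(int(rng.integers(100, 500))) * 3.0
            got_t, _ = detect_events(z, CFG)
            got = np.round(got_t * CFG.working_fs).astype(int)
            want = greedy_peak_oracle(z, CFG.z_threshold, gap)
            np.testing.assert_array_equal(got, want)

    def test_all_pairs_separated(self, rng):
        # hard invariant, fuzzed: every final pair >= 80 ms apart
        for _ in range(100):
            z = rng.standard_normal(400) * 4.0
            times, _ = detect_events(z, CFG)
            if times.size > 1:
                assert np.diff(times).min() >= CFG.min_separation_ms / 1000.0 - 1e-12


@pytest.fixture(scope="module")
def night():
    spec = SynthLfpSpec(duration=60.0, n_channels=8, event_rate=0.15, seed=3)
    raw, truth = gen_lfp(spec)
    return raw, truth


class TestExtractAndNonEvents:

    def test_recenter_finds_true_minimum(self, night):
        raw, truth = night
        # perturb the anchor by up to +-30 ms: recentring must undo it
        times = truth.times + 0.03 * np.array([(-1) ** k for k in range(len(truth))])
        events = extract_snippets(raw, times, CFG)
        matched = np.abs(events.times[:, None] - truth.times[None, :]).min(axis=1)
        assert (matched <= 0.01).all()

    def test_recentering_idempotent(self, night):
        raw, truth = night
        once = extract_snippets(raw, truth.times, CFG)
        twice = extract_snippets(raw, once.times, CFG)
        assert np.abs(once.times - twice.times).max() <= 1.0 / CFG.measure_fs + 1e-9

    def test_amplitude_recovery_within_5pct(self, night):
        raw, truth = night
        events = extract_snippets(raw, truth.times, CFG)
        assert events.amplitude.mean() == pytest.approx(truth.amplitude.mean(), rel=0.05)

    def test_non_events_disjoint_from_truth(self, night):
        raw, truth = night
        events = extract_snippets(raw, truth.times, CFG)
        non = sample_non_events(raw, None, events, seed=1, cfg=CFG)
        assert len(non) == len(events)  # equal-count contract
        for t in non.times:
            assert np.abs(truth.times - t).min() >= CFG.snippet_ms / 1000.0 / 2

    def test_insufficient_eligible_time_raises(self, night):
        raw, _ = night
        short = TimeSeries(raw.data[:1, : int(0.8 * raw.fs)], fs=raw.fs)
        dense = EventSet(times=np.array([0.4]))
        with pytest.raises(ValueError, match="could not place"):
            sample_non_events(short, None, dense, n=5, seed=0, cfg=CFG)


class TestNightlyStats:
    def test_rate_arithmetic(self):
        ev = EventSet(times=np.linspace(1, 599, 120))
        stats = nightly_stats(ev, (0.0, 600.0))
        assert stats["rate_per_min"] == pytest.approx(12.0)

    def test_empty_rate_zero(self):
        stats = nightly_stats(EventSet(times=np.empty(0)), (0.0, 60.0))
        assert stats["rate_per_min"] == 0.0

    def test_zero_duration_raises(self):
        with pytest.raises(ValueError):
            nightly_stats(EventSet(times=np.empty(0)), (5.0, 5.0))


class TestEndToEnd:
    def test_f1_above_09_at_snr5(self):
        spec = SynthLfpSpec(duration=120.0, n_channels=8, event_rate=0.2,
                            noise_sd=106.0, seed=9)  # SNR 5
        raw, truth = gen_lfp(spec)
        events = run_sharpwave_detection(raw, cfg=CFG)["events"]
        tp, fp, fn = match_events(truth.times, events.times, tol_s=0.02)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9

    def test_gain_invariance(self, small_night):
        raw = small_night["raw"]
        events = small_night["events"]
        scaled = TimeSeries(raw.data * np.float32(3.7), fs=raw.fs)
        events_scaled = run_sharpwave_detection(scaled, cfg=CFG)["events"]
        np.testing.assert_allclose(events_scaled.times, events.times, atol=1e-9)

    def test_recovers_all_events_at_snr10(self, small_night):
        truth, events = small_night["truth"], small_night["events"]
        tp, fp, fn = match_events(truth.times, events.times, tol_s=0.02)
        assert fn == 0 and fp == 0

    def test_rate_sweep_within_poisson_intervals(self):
        from scipy import stats as sstats

        for rate, seed in [(0.05, 1), (0.2, 2), (0.5, 3)]:
            spec = SynthLfpSpec(duration=120.0, fs=2000.0, n_channels=2,
                                event_rate=rate, seed=seed)
            _, truth = gen_lfp(spec)
            lo, hi = sstats.poisson.interval(0.95, rate * 120.0)
            assert lo <= len(truth) <= hi
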