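import numpy as np
import pytest

from rfmonitor import (StaLtaConfig, aggregate_gates, detect_day,
                       fixed_baseline_thresholds, gen_radar_day)
from rfmonitor.radar_energy import EmptySeriesError, EnergySeries
from rfmonitor.stalta import (SegmentList, StaLtaSeries, ThresholdSet,
                              cfar_threshold, compute_sta_lta,
                              enforce_hysteresis, segment_activity,
                              sigma1_from_sta, sigma2_cfar, sigma3_from_ecdf)
from rfmonitor.synthetic import RadarDaySpec

from conftest import oracle_segment, oracle_sta_lta


def series(values, start=0.0):
    return EnergySeries(start, np.asarray(values, dtype=float))


class TestComputeStaLta:
    def test_constant_series_unit_ratio(self, stalta_config):
        s = compute_sta_lta(series([0.3] * 1000), stalta_config)
        interior = slice(0, 999)  # last sample has an empty forward window
        assert np.allclose(s.sta[interior], 0.3)
        assert np.allclose(s.lta, 0.3)
        assert np.allclose(s.ratio[interior], 1.0)

    def test_zero_series_guarded_ratio(self, stalta_config):
        s = compute_sta_lta(series([0.0] * 500), stalta_config)
        assert np.all(s.ratio[:-1] == 0.0)
        assert np.all(np.isfinite(s.ratio[:-1]))

    def test_step_matches_windowed_mean_oracle(self, stalta_config):
        vals = np.zeros(2000)
        t0 = 1200
        vals[t0:] = 1.0
        s = compute_sta_lta(series(vals), stalta_config)
        o_sta, o_lta, o_ratio = oracle_sta_lta(
            vals, stalta_config.T1, stalta_config.T2, stalta_config.epsilon)
        np.testing.assert_array_equal(s.sta, o_sta)
        np.testing.assert_array_equal(s.lta, o_lta)
        np.testing.assert_array_equal(s.ratio, o_ratio)
        # the forward STA reacts a full T1 before the backward LTA
        assert s.sta[t0 - 1] == pytest.approx(1.0)
        assert s.lta[t0 - 1] == pytest.approx(0.0)

    def test_too_short_raises(self, stalta_config):
        with pytest.raises(EmptySeriesError):
            compute_sta_lta(series([0.1]), stalta_config)


class TestSigma1:
    def test_degenerate_distribution(self, stalta_config):
        assert sigma1_from_sta(np.full(100, 0.1), stalta_config) == 0.1

    def test_ramp_percentile_convention(self, stalta_config):
        ramp = np.arange(100) / 100.0
        # linear interpolation between order statistics: 0.74 + 0.25 * 0.01
        assert sigma1_from_sta(ramp, stalta_config) == pytest.approx(0.7425)

    def test_insensitive_to_single_outlier(self, stalta_config):
        sta = np.zeros(100)
        sta[50] = 10.0
        assert sigma1_from_sta(sta, stalta_config) == 0.0

    def test_all_missing_raises(self, stalta_config):
        with pytest.raises(EmptySeriesError):
            sigma1_from_sta(np.full(10, np.nan), stalta_config)


def oracle_sigma3(sta, config):
    """Finite-difference ECDF-slope rule, written independently."""
    x = np.sort(sta[np.isfinite(sta)])
    grid = np.linspace(x[0], x[-1], config.ecdf_grid_points)
    F = np.array([np.mean(x <= gp) for gp in grid])
    slope = np.empty_like(F)
    slope[1:-1] = (F[2:] - F[:-2]) / (grid[2:] - grid[:-2])
    slope[0] = (F[1] - F[0]) / (grid[1] - grid[0])
    slope[-1] = (F[-1] - F[-2]) / (grid[-1] - grid[-2])
    peak = int(np.argmax(slope))
    hits = np.flatnonzero(slope[peak + 1:] <= config.alpha * slope[peak])
    if hits.size == 0:
        return None
    return float(grid[peak + 1 + hits[0]])


class TestSigma3:
    def test_bimodal_low_mode_cutoff(self, stalta_config):
        rng = np.random.default_rng(7)
        sta = np.concatenate([
            rng.normal(0.02, 0.002, 9500), rng.normal(0.5, 0.02, 500)])
        val, prov = sigma3_from_ecdf(sta, stalta_config)
        assert prov == "primary"
        assert 0.02 < val < 0.1
        grid_step = (sta.max() - sta.min()) / (stalta_config.ecdf_grid_points - 1)
        assert abs(val - oracle_sigma3(sta, stalta_config)) <= grid_step + 1e-12

    def test_constant_falls_back_to_p15(self, stalta_config):
        val, prov = sigma3_from_ecdf(np.full(100, 0.3), stalta_config)
        assert prov == "fallback_p15"
        assert val == 0.3

    def test_uniform_has_no_slope_drop(self, stalta_config):
        rng = np.random.default_rng(11)
        sta = rng.uniform(0.0, 1.0, 20_000)
        val, prov = sigma3_from_ecdf(sta, stalta_config)
        assert prov == "fallback_p15"
        assert val == pytest.approx(0.15, abs=0.02)


class TestSigma2:
    @staticmethod
    def fabricate(sta, ratio, start=0.0):
        sta = np.asarray(sta, dtype=float)
        return StaLtaSeries(start, sta, np.ones_like(sta),
                            np.asarray(ratio, dtype=float))

    def test_constant_background_identity(self, stalta_config):
        n = 20_000
        s = self.fabricate(np.full(n, 0.01), np.full(n, 1.0))
        val, flags = sigma2_cfar(s, sigma1=0.5, sigma3=0.02, config=stalta_config)
        assert val == 1.0 and "clipped" not in flags

    def test_order_statistic_convention(self):
        b = 0.5 * np.arange(1, 2001)
        # linear interpolation at q=99.9 of 2000 order statistics
        expected = b[1997] + 0.001 * (b[1998] - b[1997])
        assert cfar_threshold(b, 1e-3) == pytest.approx(expected)

    def test_upper_clip_flagged(self, stalta_config):
        n = 20_000
        s = self.fabricate(np.full(n, 0.01), np.full(n, 25.0))
        val, flags = sigma2_cfar(s, 0.5, 0.02, stalta_config)
        assert val == stalta_config.sigma2_max
        assert "clipped" in flags

    def test_guard_band_excludes_activity_neighborhood(self, stalta_config):
        n = 40_000
        sta = np.full(n, 0.01)
        ratio = np.ones(n)
        sta[20_000:20_100] = 1.0       # activity burst
        ratio[19_990:20_000] = 50.0    # contaminated pre-burst guard zone
        s = self.fabricate(sta, ratio)
        val, _ = sigma2_cfar(s, 0.5, 0.02, stalta_config)
        assert val == 1.0  # guard removed the contamination

    def test_relaxation_then_not_updated(self, stalta_config):
        # few samples below sigma3 but enough under the relaxed p35 limit
        n = 9_000
        rng = np.random.default_rng(3)
        sta = rng.uniform(0.05, 0.10, n)
        s = self.fabricate(sta, np.ones(n))
        val, flags = sigma2_cfar(s, sigma1=0.5, sigma3=0.01,
                                 config=stalta_config)
        assert val == 1.0 and "relaxed_bg" in flags
        # and when even the relaxed set is too small: not updated
        small = self.fabricate(sta[:500], np.ones(500))
        val, flags = sigma2_cfar(small, 0.5, 0.01, stalta_config)
        assert val is None and flags == {"not_updated"}


class TestHysteresisEnforcement:
    @pytest.mark.parametrize("s1,s3,expected,fixed", [
        (0.4, 0.1, 0.1, False),
        (0.2, 0.25, 0.15, True),   # max(0, 0.2 - 0.05)
        (0.03, 0.04, 0.0, True),   # floored at sigma_min
    ])
    def test_separation(self, stalta_config, s1, s3, expected, fixed):
        out, was_fixed = enforce_hysteresis(s1, s3, stalta_config)
        assert out == pytest.approx(expected)
        assert was_fixed is fixed
        assert out < s1


class TestSegmentation:
    def test_never_activates(self):
        n = 100
        s = StaLtaSeries(0.0, np.full(n, 0.01), np.ones(n), np.full(n, 0.1))
        out = segment_activity(s, ThresholdSet(0.5, 1.5, 0.05))
        assert out.segments == []

    def test_single_step_trace(self):
        sta = np.array([0.01] * 10 + [0.9] * 8 + [0.01] * 2)
        ratio = sta * 10.0
        s = StaLtaSeries(0.0, sta, np.ones_like(sta), ratio)
        out = segment_activity(s, ThresholdSet(0.5, 1.5, 0.05))
        assert out.segments == [(10.0, 18.0)]

    def test_conjunction_prevents_toggling(self):
        # after activation STA oscillates between sigma3 and sigma1, but the
        # ratio stays above sigma2: both OFF conditions never hold together
        sta = np.array([0.9] * 5 + [0.1, 0.4] * 10)
        ratio = np.full_like(sta, 5.0)
        s = StaLtaSeries(0.0, sta, np.ones_like(sta), ratio)
        out = segment_activity(s, ThresholdSet(0.5, 1.5, 0.2))
        assert len(out.segments) == 1
        assert out.segments[0][0] == 0.0

    def test_missing_holds_state(self):
        sta = np.array([0.9] * 5 + [np.nan] * 5 + [0.01] * 5)
        ratio = np.where(np.isnan(sta), np.nan, sta * 10)
        s = StaLtaSeries(0.0, sta, np.ones_like(sta), ratio)
        out = segment_activity(s, ThresholdSet(0.5, 1.5, 0.05))
        # state held through the missing run, OFF at the first sample where
        # both deactivation conditions hold
        assert out.segments == [(0.0, 10.0)]


class TestDetectDay:
    def test_short_record_excluded(self, stalta_config):
        result = detect_day(series(np.full(200, 0.1)), stalta_config)
        assert result.excluded
        assert result.thresholds.provenance == {"not_updated"}
        assert result.segments.segments == []

    def test_determinism(self, stalta_config):
        spec = RadarDaySpec(seed=5)
        frames, _, _ = gen_radar_day(spec)
        s = aggregate_gates(frames, "micro")
        r1 = detect_day(s, stalta_config)
        r2 = detect_day(s, stalta_config)
        assert r1.thresholds == r2.thresholds
        assert r1.segments.segments == r2.segments.segments

    def test_recovery_and_adaptivity(self, stalta_config):
        for seed in (0, 1):
            frames, occ, _ = gen_radar_day(RadarDaySpec(seed=seed))
            s = aggregate_gates(frames, "micro")
            res = detect_day(s, stalta_config)
            tm = occ.to_mask(s.start_time, len(s))
            dm = res.segments.to_mask(s.start_time, len(s))
            assert (tm & dm).sum() / (tm | dm).sum() >= 0.9
            # 3x background: thresholds shift up, recovery maintained
            frames3, occ3, _ = gen_radar_day(RadarDaySpec(
                seed=seed, micro_background=6.0, macro_background=3.0))
            s3 = aggregate_gates(frames3, "micro")
            res3 = detect_day(s3, stalta_config)
            assert res3.thresholds.sigma1 > res.thresholds.sigma1
            assert res3.thresholds.sigma3 > res.thresholds.sigma3
            tm3 = occ3.to_mask(s3.start_time, len(s3))
            dm3 = res3.segments.to_mask(s3.start_time, len(s3))
            assert (tm3 & dm3).sum() / (tm3 | dm3).sum() >= 0.9

    def test_threshold_invariants_on_synthetic_day(self, stalta_config):
        frames, _, _ = gen_radar_day(RadarDaySpec(seed=9))
        s = aggregate_gates(frames, "micro")
        thr = detect_day(s, stalta_config).thresholds
        assert thr.sigma3 < thr.sigma1
        assert stalta_config.sigma2_min <= thr.sigma2 <= stalta_config.sigma2_max

    def test_scale_invariant_segmentation(self, stalta_config):
        frames, _, _ = gen_radar_day(RadarDaySpec(seed=2))
        s = aggregate_gates(frames, "micro")
        res = detect_day(s, stalta_config)
        gamma = 0.5
        scaled = EnergySeries(s.start_time, s.values * gamma)
        res_g = detect_day(scaled, stalta_config)
        assert res_g.thresholds.sigma1 == pytest.approx(
            gamma * res.thresholds.sigma1, rel=1e-9)
        assert res_g.thresholds.sigma3 == pytest.approx(
            gamma * res.thresholds.sigma3, rel=1e-2)
        assert res_g.segments.segments == res.segments.segments


class TestFixedBaseline:
    def test_printed_values(self):
        thr = fixed_baseline_thresholds()
        assert (thr.sigma1, thr.sigma2, thr.sigma3) == (0.25, 1.5, 0.08)
        assert thr.sigma3 < thr.sigma1

    def test_constant_series_never_activates(self, stalta_config):
        s = compute_sta_lta(series([0.3] * 2000), stalta_config)
        out = segment_activity(s, fixed_baseline_thresholds())
        assert out.segments == []  # unit ratio stays below sigma2 = 1.5


class TestOracleEquivalence:
    def test_random_series_bit_match(self, stalta_config):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(400, 1200))
            vals = rng.uniform(0.0, 0.3, n)
            # add activity steps and missing runs
            for _ in range(int(rng.integers(0, 4))):
                a = int(rng.integers(0, n))
                b = min(n, a + int(rng.integers(10, 200)))
                vals[a:b] += rng.uniform(0.2, 0.7)
            vals = np.clip(vals, 0.0, 1.0)
            for _ in range(int(rng.integers(0, 3))):
                a = int(rng.integers(0, n))
                b = min(n, a + int(rng.integers(1, 400)))
                vals[a:b] = np.nan
            s = compute_sta_lta(series(vals), stalta_config)
            o_sta, o_lta, o_ratio = oracle_sta_lta(
                vals, stalta_config.T1, stalta_config.T2,
                stalta_config.epsilon)
            np.testing.assert_array_equal(s.sta, o_sta)
            np.testing.assert_array_equal(s.lta, o_lta)
            np.testing.assert_array_equal(s.ratio, o_ratio)
            s1 = float(rng.uniform(0.2, 0.6))
            s3 = float(rng.uniform(0.0, s1 - 0.05))
            s2 = float(rng.uniform(0.5, 2.0))
            got = segment_activity(s, ThresholdSet(s1, s2, s3),
                                   split_gap=stalta_config.T2)
            want = oracle_segment(o_sta, o_ratio, s1, s2, s3,
                                  split_gap=stalta_config.T2)
            np.testing.assert_array_equal(got.mask, want)


class TestSegmentList:
    def test_mask_round_trip(self):
        rng = np.random.default_rng(1)
        mask = rng.random(500) > 0.7
        sl = SegmentList.from_mask(mask, start_time=100.0)
        np.testing.assert_array_equal(sl.mask, mask)

    def test_rejects_overlap(self):
        with pytest.raises(ValueError):
            SegmentList([(0.0, 10.0), (5.0, 15.0)])
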