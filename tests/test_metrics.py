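"""Fold induction, error propagation, peaks, averages, background windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboreporter import (
    BackgroundWindowConfig,
    DataError,
    above_background_window,
    average_lum_over_od,
    fi_error,
    fold_induction,
    normalized_expression,
    parse_window,
    peak_lum_over_od,
    restricted_fold_induction,
    total_activity,
)

from conftest import triplicate, ws


class TestNormalizedExpression:
    def test_elementwise_division(self):
        out = normalized_expression(ws("A1", [10, 20], [0.1, 0.2]))
        np.testing.assert_allclose(out, [100, 100])

    def test_zero_lum_gives_zero(self):
        out = normalized_expression(ws("A1", [0, 0], [0.3, 0.4]))
        assert np.all(out == 0)

    def test_od_below_floor_errors_listing_timepoints(self):
        with pytest.raises(DataError, match=r"\[1\]"):
            normalized_expression(ws("A1", [1, 1], [0.2, 1e-5]))

    def test_random_series_matches_division_oracle(self):
        rng = np.random.default_rng(1)
        lum, od = rng.uniform(0, 1e4, 50), rng.uniform(0.05, 1.2, 50)
        out = normalized_expression(ws("A1", lum, od))
        oracle = np.array([l / o for l, o in zip(lum, od)])
        np.testing.assert_allclose(out, oracle, rtol=1e-14)


class TestTotalActivity:
    def test_constant_full_range(self):
        assert total_activity(np.full(10, 2.0), 0, 9) == 20.0

    def test_single_point_bounds(self):
        assert total_activity(np.array([1.0, 7.0, 3.0]), 1, 1) == 7.0

    def test_out_of_bounds_is_an_error(self):
        with pytest.raises(DataError, match="bounds"):
            total_activity(np.arange(5.0), 2, 5)

    def test_matches_loop_accumulation_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        acc = 0.0
        for i in range(3, 31):
            acc += x[i]
        assert total_activity(x, 3, 30) == pytest.approx(acc, rel=1e-12)


class TestFoldInduction:
    def test_identical_groups_give_fi_one_sigma_zero(self):
        g = triplicate("A", [100, 200, 300], [0.2, 0.4, 0.6])
        res = fold_induction(g, [ws(f"B{i}", [100, 200, 300], [0.2, 0.4, 0.6]) for i in range(3)])
        assert res.FI == 1.0
        assert res.sigma_FI == 0.0

    def test_scaling_with_ligand_lum_scales_fi(self):
        g0 = triplicate("A", [100, 200, 300], [0.2, 0.4, 0.6])
        gx = triplicate("B", [500, 1000, 1500], [0.2, 0.4, 0.6])
        assert fold_induction(g0, gx).FI == pytest.approx(5.0, rel=1e-12)

    @given(c=st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_common_scaling_leaves_fi_unchanged(self, c):
        rng = np.random.default_rng(3)
        lum = [rng.uniform(10, 100, 8) for _ in range(6)]
        od = rng.uniform(0.2, 0.8, 8)
        g0 = [ws(f"A{i}", lum[i], od) for i in range(3)]
        gx = [ws(f"B{i}", lum[3 + i], od) for i in range(3)]
        base = fold_induction(g0, gx).FI
        g0c = [ws(f"A{i}", c * lum[i], od) for i in range(3)]
        gxc = [ws(f"B{i}", c * lum[3 + i], od) for i in range(3)]
        assert fold_induction(g0c, gxc).FI == pytest.approx(base, rel=1e-9)

    def test_non_positive_reference_total_is_an_error(self):
        g0 = triplicate("A", [0, 0], [0.2, 0.2])
        gx = triplicate("B", [5, 5], [0.2, 0.2])
        with pytest.raises(DataError, match="FI undefined"):
            fold_induction(g0, gx)

    def test_groups_of_one_are_rejected(self):
        g = triplicate("A", [1, 2], [0.2, 0.2])
        with pytest.raises(DataError, match=">= 2"):
            fold_induction(g[:1], g)

    def test_unharmonized_groups_are_rejected(self):
        g0 = triplicate("A", [1, 2], [0.2, 0.2])
        gx = triplicate("B", [1, 2, 3], [0.2, 0.2, 0.2])
        with pytest.raises(DataError, match="harmonized"):
            fold_induction(g0, gx)

    def test_result_carries_sums_and_dispersions(self):
        g0 = [ws(f"A{i}", [10.0 * (i + 1)], [0.5]) for i in range(3)]
        gx = [ws(f"B{i}", [40.0 * (i + 1)], [0.5]) for i in range(3)]
        res = fold_induction(g0, gx)
        assert res.av_F0 == pytest.approx(np.mean([20, 40, 60]))
        assert res.sd_F0 == pytest.approx(np.std([20, 40, 60], ddof=1))
        assert res.FI == pytest.approx(4.0)
        assert (res.m, res.n) == (0, 0)


class TestFiError:
    def test_zero_dispersions_give_zero(self):
        assert fi_error(3.0, 0.0, 10.0, 0.0, 30.0) == 0.0

    def test_closed_form_example(self):
        # both relative SDs 0.1 -> sigma = 2*sqrt(0.02)
        assert fi_error(2.0, 1.0, 10.0, 2.0, 20.0) == pytest.approx(2 * np.sqrt(0.02))

    def test_zero_mean_is_an_error(self):
        with pytest.raises(DataError, match="zero"):
            fi_error(1.0, 0.1, 0.0, 0.1, 1.0)

    def test_strictly_increasing_in_each_relative_sd(self):
        base = fi_error(2.0, 1.0, 10.0, 2.0, 20.0)
        assert fi_error(2.0, 1.5, 10.0, 2.0, 20.0) > base
        assert fi_error(2.0, 1.0, 10.0, 2.5, 20.0) > base

    @pytest.mark.parametrize("cv0,cvx", [(0.05, 0.05), (0.1, 0.03), (0.02, 0.1)])
    def test_agrees_with_monte_carlo_ratio_distribution(self, cv0, cvx):
        """First-order propagation vs the SD of a simulated ratio of
        lognormal triplicate means (10,000 draws)."""
        av0, avx = 100.0, 450.0
        sd0, sdx = cv0 * av0, cvx * avx
        rng = np.random.default_rng(12345)
        sig0 = np.sqrt(np.log1p(cv0**2))
        sigx = np.sqrt(np.log1p(cvx**2))
        draws0 = rng.lognormal(np.log(av0) - sig0**2 / 2, sig0, size=10_000)
        drawsx = rng.lognormal(np.log(avx) - sigx**2 / 2, sigx, size=10_000)
        mc_sd = np.std(drawsx / draws0, ddof=1)
        FI = avx / av0
        assert fi_error(FI, sd0, av0, sdx, avx) == pytest.approx(mc_sd, rel=0.10)


class TestPeakLumOverOd:
    def test_peak_on_raw_lum_then_normalized(self):
        val, t = peak_lum_over_od(ws("A1", [10, 50, 30], [0.1, 0.5, 0.6]))
        assert val == pytest.approx(100.0)
        assert t == 20.0

    def test_tie_breaks_to_earliest_timepoint(self):
        val, t = peak_lum_over_od(ws("A1", [7, 7, 7], [0.1, 0.2, 0.7]))
        assert t == 0.0
        assert val == pytest.approx(70.0)

    def test_differs_from_max_of_normalized_series(self):
        w = ws("A1", [10, 50], [0.01, 0.5])  # lum/od = [1000, 100]
        val, t = peak_lum_over_od(w)
        assert (val, t) == (100.0, 20.0)  # raw peak wins

    def test_pooled_group_matches_argmax_oracle(self):
        rng = np.random.default_rng(5)
        group = [ws(f"A{i}", rng.uniform(0, 1e4, 30), rng.uniform(0.1, 1, 30)) for i in range(3)]
        val, t = peak_lum_over_od(group)
        flat = [(w.lum[i], w.times[i], w.od[i]) for w in group for i in range(30)]
        best = max(flat, key=lambda x: (x[0], -x[1]))
        assert val == pytest.approx(best[0] / best[2])
        assert t == best[1]


class TestAverageLumOverOd:
    def test_constant_series(self):
        assert average_lum_over_od(triplicate("A", [100, 100], [0.5, 0.5])) == pytest.approx(200)

    def test_ratio_of_means_not_mean_of_ratios(self):
        # per-point ratios are 195 and 105 (mean 150); ratio of means is 120
        w = ws("A1", [19.5, 52.5], [0.1, 0.5])
        assert np.mean(w.lum / w.od) == pytest.approx(150.0)
        assert average_lum_over_od([w]) == pytest.approx(120.0)

    def test_single_timepoint(self):
        assert average_lum_over_od([ws("A1", [30.0], [0.6])]) == pytest.approx(50.0)


class TestAboveBackgroundWindow:
    cfg = BackgroundWindowConfig()  # 9 points, 2 h persistence, 20-min interval

    def test_zero_mean_noise_has_no_window(self):
        rng = np.random.default_rng(6)
        group = [ws(f"A{i}", rng.normal(0, 10, 60), np.full(60, 0.5)) for i in range(3)]
        assert above_background_window(group, self.cfg) == []

    def test_step_signal_yields_one_window_near_onset(self):
        rng = np.random.default_rng(7)
        n, onset_idx = 90, 30  # onset at 10 h on a 20-min grid
        group = []
        for i in range(3):
            lum = np.zeros(n)
            lum[onset_idx:] = 1000 + rng.normal(0, 10, n - onset_idx)
            group.append(ws(f"A{i}", lum, np.full(n, 0.5)))
        windows = above_background_window(group, self.cfg)
        assert len(windows) == 1
        start, end = windows[0]
        assert abs(start - 600.0) <= 20.0  # within one timepoint of 10 h
        assert end == pytest.approx((n - 1) * 20.0)

    def test_one_hour_excursion_fails_persistence(self):
        n = 60
        group = []
        for i in range(3):
            lum = np.zeros(n)
            lum[30:33] = 1000.0  # 1 h above background only
            group.append(ws(f"A{i}", lum, np.full(n, 0.5)))
        assert above_background_window(group, self.cfg) == []

    def test_series_shorter_than_one_block_is_an_error(self):
        group = triplicate("A", [1, 2], [0.5, 0.5])
        with pytest.raises(DataError, match="block"):
            above_background_window(group, self.cfg)


class TestRestrictedFoldInduction:
    def _groups(self, n=30):
        rng = np.random.default_rng(8)
        od = np.full(n, 0.5)
        g0 = [ws(f"A{i}", rng.uniform(50, 100, n), od) for i in range(3)]
        gx = [ws(f"B{i}", rng.uniform(200, 400, n), od) for i in range(3)]
        return g0, gx

    def test_full_range_window_equals_fold_induction_exactly(self):
        g0, gx = self._groups()
        full = fold_induction(g0, gx)
        res = restricted_fold_induction(g0, gx, (0.0, g0[0].times[-1]))
        assert res.FI == full.FI  # bit-identical
        assert res.sigma_FI == full.sigma_FI
        assert (res.m, res.n) == (full.m, full.n)
        assert res.window == (0.0, g0[0].times[-1])

    def test_window_where_signals_are_equal_gives_fi_one(self):
        n = 30
        od = np.full(n, 0.5)
        lum0 = np.full(n, 100.0)
        lumx = np.concatenate([np.full(15, 100.0), np.full(15, 900.0)])
        g0 = [ws(f"A{i}", lum0, od) for i in range(3)]
        gx = [ws(f"B{i}", lumx, od) for i in range(3)]
        res = restricted_fold_induction(g0, gx, (0.0, 14 * 20.0))
        assert res.FI == 1.0

    def test_window_isolating_induced_phase_raises_fi(self):
        # induction only after 10 h: the full-range FI dilutes the effect
        n = 60
        od = np.full(n, 0.5)
        lum0 = np.full(n, 100.0)
        lumx = np.where(np.arange(n) >= 30, 2500.0, 100.0)
        g0 = [ws(f"A{i}", lum0, od) for i in range(3)]
        gx = [ws(f"B{i}", lumx, od) for i in range(3)]
        full = fold_induction(g0, gx)
        restricted = restricted_fold_induction(g0, gx, (600.0, (n - 1) * 20.0))
        assert restricted.FI > full.FI
        assert restricted.FI == pytest.approx(25.0)

    def test_disjoint_window_is_an_error(self):
        g0, gx = self._groups()
        with pytest.raises(DataError, match="intersect"):
            restricted_fold_induction(g0, gx, (1e6, 2e6))


class TestParseWindow:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("22h00-29h20", (1320.0, 1760.0)),
            ("22:00-29:20", (1320.0, 1760.0)),
            ("7h00-12h00", (420.0, 720.0)),
        ],
    )
    def test_clock_style_windows(self, text, expected):
        assert parse_window(text) == expected

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError, match="empty or reversed"):
            parse_window("12h00-7h00")
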