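"""Tests of firing-rate statistics: binning, baseline windows, inclusion
rules, burst/inter-burst partitioning, cytokine ratios, categorization,
heatmap ordering and group comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaguscap as vc
from vaguscap.firing import CATEGORY_ORDER, _window_mean
from vaguscap.types import BurstIntervals, RateSeries, SessionPlan


def make_series(rates, bin_s=1.0, plan=None, unit_id=0):
    plan = plan or SessionPlan()
    rates = np.asarray(rates, dtype=float)
    edges = np.arange(len(rates) + 1) * bin_s
    centers = edges[:-1] + bin_s / 2
    return RateSeries(
        unit_id=unit_id, bin_edges=edges, rates=rates,
        period_labels=plan.period_of(centers), plan=plan,
    )


class TestBinRates:
    def test_uniform_spikes_mean_rate(self, plan):
        times = np.linspace(0, 60, 120, endpoint=False)
        s = vc.bin_rates(times, plan, bin_s=1.0, duration_s=60.0)
        assert s.rates.mean() == pytest.approx(2.0)

    def test_empty_unit_all_zero(self, plan):
        s = vc.bin_rates(np.array([]), plan, bin_s=60.0)
        assert np.all(s.rates == 0)
        assert len(s.rates) == 60

    def test_half_filled_bin_averages_down(self, plan):
        times = np.arange(0, 30, 0.5)  # 2 CAPs/s over the first 30 s only
        s = vc.bin_rates(times, plan, bin_s=60.0, duration_s=60.0)
        assert s.rates[0] == pytest.approx(1.0)

    def test_period_labels_follow_injections(self, plan):
        s = vc.bin_rates(np.array([]), plan, bin_s=60.0)
        assert list(s.period_labels[:20]) == ["BL"] * 20
        assert list(s.period_labels[20:40]) == ["C1"] * 20
        assert list(s.period_labels[40:]) == ["C2"] * 20


class TestBaselineStats:
    def test_second_ten_minutes_selected(self):
        # 5 CAPs/s in minutes 0-10, 10 CAPs/s in minutes 10-20
        times = np.concatenate([
            np.arange(0, 600, 0.2)[:3000], np.arange(600, 1200, 0.1),
        ])
        assert vc.baseline_rate(times) == pytest.approx(10.0)

    def test_per_mouse_summation(self):
        units = {
            "m1": [np.arange(600, 1200, 1 / r) for r in (4.0, 6.0, 8.0)],
        }
        per_unit, per_mouse = vc.baseline_stats(units, session_s=1200.0)
        assert per_unit["rate"].tolist() == pytest.approx([4.0, 6.0, 8.0])
        assert per_mouse["m1"] == pytest.approx(18.0)

    def test_short_session_errors(self):
        with pytest.raises(ValueError, match="baseline window"):
            vc.baseline_stats({"m": [np.array([1.0])]}, session_s=900.0)


class TestApplyInclusion:
    def _cohort(self, bl_rates, zero_run_unit=None):
        plan = SessionPlan()
        series = []
        for i, r in enumerate(bl_rates):
            rates = np.full(3600, float(r))
            if zero_run_unit == i:
                rates[1260:1620] = 0.0  # six zero minutes after injection
            series.append(make_series(rates, plan=plan, unit_id=i))
        return series

    def test_high_baseline_excluded(self):
        series = self._cohort([4.0, 6.0, 6.0, 6.0, 8.5])  # mean 6.1, sd ~1.43
        included, log = vc.apply_inclusion(series)
        assert {s.unit_id for s in included} == {0, 1, 2, 3}
        assert log.iloc[0]["reason"] == "baseline>mean+1sd"

    def test_boundary_exactly_one_sd_included(self):
        # for two units the larger equals exactly mean + 1 sd; the rule is
        # strict ("higher than"), so it stays included
        series = self._cohort([4.0, 6.0])
        included, log = vc.apply_inclusion(series)
        assert len(included) == 2 and log.empty

    def test_zero_run_excluded(self):
        series = self._cohort([5.0, 5.0, 5.0], zero_run_unit=1)
        included, log = vc.apply_inclusion(series)
        assert {s.unit_id for s in included} == {0, 2}
        assert log.iloc[0]["reason"] == "zero-firing-run"

    def test_five_zero_minutes_is_kept(self):
        plan = SessionPlan()
        rates = np.full(3600, 5.0)
        rates[1260:1560] = 0.0  # exactly five zero minutes
        series = [make_series(rates, plan=plan, unit_id=0),
                  make_series(np.full(3600, 5.0), plan=plan, unit_id=1)]
        included, _ = vc.apply_inclusion(series)
        assert {s.unit_id for s in included} == {0, 1}


class TestBurstInterburstRates:
    def test_all_spikes_inside_bursts(self):
        bursts = BurstIntervals([[i, i + 0.2] for i in range(10)])  # 2 s of 10
        times = np.concatenate([np.linspace(i + 0.01, i + 0.19, 10) for i in range(10)])
        b, i = vc.burst_interburst_rates(times, bursts, observation=(0.0, 10.0))
        assert b == pytest.approx(50.0)
        assert i == 0.0

    def test_homogeneous_poisson_equal_rates(self, rng):
        times = np.sort(rng.uniform(0, 600, 6000))
        bursts = BurstIntervals([[i, i + 0.134] for i in np.arange(0.2, 599, 0.65)])
        b, i = vc.burst_interburst_rates(times, bursts, observation=(0.0, 600.0))
        se = np.sqrt(10.0 / bursts.total_time()) + np.sqrt(10.0 / (600 - bursts.total_time()))
        assert abs(b - i) < 2 * se

    def test_zero_burst_time_errors(self):
        with pytest.raises(ValueError, match="burst time"):
            vc.burst_interburst_rates(
                np.array([1.0]), BurstIntervals([[700.0, 700.5]]),
                observation=(0.0, 600.0),
            )

    def test_partition_identity(self, rng):
        times = np.sort(rng.uniform(0, 100, 1000))
        bursts = BurstIntervals([[i, i + 0.3] for i in np.arange(0.5, 99, 1.0)])
        b, i = vc.burst_interburst_rates(times, bursts, observation=(0.0, 100.0))
        tb = bursts.total_time()
        assert b * tb + i * (100 - tb) == pytest.approx(len(times), rel=1e-9)


class TestPeriEventHist:
    def test_spikes_at_onsets_give_single_peak_bin(self):
        bursts = BurstIntervals([[float(i), i + 0.134] for i in range(1, 50)])
        hist = vc.peri_event_hist([bursts.starts.copy()], bursts)
        assert hist.counts[np.flatnonzero(hist.lag_edges_ms[:-1] == 0.0)[0]] == 49
        assert hist.counts.sum() == 49

    def test_poisson_background_is_flat(self, rng):
        bursts = BurstIntervals([[float(i), i + 0.134] for i in range(1, 500)])
        times = np.sort(rng.uniform(0, 500, 20000))
        hist = vc.peri_event_hist([times], bursts)
        mean = hist.counts.mean()
        assert hist.counts.max() < mean + 4 * np.sqrt(mean)

    def test_burst_gain_elevates_only_burst_lags(self):
        cfg_gain = 4.0
        rng = np.random.default_rng(0)
        onsets = np.arange(1.0, 600.0, 0.65)
        bursts = BurstIntervals(np.column_stack([onsets, onsets + 0.134]))
        # piecewise-constant rate: 4x inside bursts
        times = []
        for on in onsets:
            times.extend(rng.uniform(on, on + 0.134, rng.poisson(4.0 * 10 * 0.134)))
            times.extend(rng.uniform(on + 0.134, on + 0.65, rng.poisson(10 * 0.516)))
        hist = vc.peri_event_hist([np.sort(times)], bursts)
        centers = hist.lag_centers_ms
        inside = (centers > 0) & (centers < 134)
        outside = (centers > 200) & (centers < 500)
        assert hist.counts[inside].mean() > 3 * hist.counts[outside].mean()


class TestCytokineRatio:
    @pytest.mark.parametrize("f_bl,f_cyt,expected", [
        (10.0, 10.0, 0.0), (0.0, 5.0, 1.0), (5.0, 15.0, 0.5),
    ])
    def test_worked_examples(self, f_bl, f_cyt, expected):
        assert vc.cytokine_ratio(f_bl, f_cyt) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert vc.cytokine_ratio(0.0, 0.0) is None

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry_and_bounds(self, a, b):
        if a + b == 0:
            return
        r = vc.cytokine_ratio(a, b)
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(-vc.cytokine_ratio(b, a))


class TestPeriodMeans:
    def test_constant_rate(self):
        s = make_series(np.full(3600, 5.0))
        assert vc.period_means(s) == pytest.approx((5.0, 5.0, 5.0))

    def test_step_changes(self):
        rates = np.full(3600, 5.0)
        rates[1200:2400] = 10.0
        rates[2400:] = 2.0
        assert vc.period_means(make_series(rates)) == pytest.approx((5.0, 10.0, 2.0))

    def test_last_ten_minutes_window(self):
        rates = np.full(3600, 5.0)
        rates[1200:1800] = 100.0  # ramp/artifact in the first 10 min of C1
        rates[1800:2400] = 8.0
        assert vc.period_means(make_series(rates))[1] == pytest.approx(8.0)

    def test_truncated_session_errors(self):
        s = make_series(np.full(2000, 5.0))
        with pytest.raises(ValueError, match="C1|C2"):
            vc.period_means(s)


class TestCategorizeUnit:
    @pytest.mark.parametrize("m,expected", [
        ((5.0, 8.0, 9.0), "increasing"),
        ((5.0, 3.0, 2.0), "decreasing"),
        ((5.0, 8.0, 3.0), "mixed"),
        ((5.0, 2.0, 8.0), "mixed"),
    ])
    def test_sign_patterns(self, m, expected):
        assert vc.categorize_unit(*m).category == expected

    def test_zero_delta_goes_to_mixed(self):
        assert vc.categorize_unit(5.0, 5.0, 7.0).category == "mixed"

    def test_deltas_are_relative_to_baseline(self):
        cat = vc.categorize_unit(5.0, 8.0, 9.0)
        assert cat.delta_c1 == pytest.approx(3.0)
        assert cat.delta_c2 == pytest.approx(4.0)


class TestCategoryFractions:
    def test_printed_cohort_percentages(self):
        cats = ["increasing"] * 33 + ["mixed"] * 13 + ["decreasing"] * 3
        frac = vc.category_fractions(cats)
        assert frac["increasing"] == 67.35
        assert frac["mixed"] == 26.53
        assert frac["decreasing"] == 6.12

    def test_single_category(self):
        frac = vc.category_fractions(["increasing"] * 7)
        assert frac["increasing"] == 100.0
        assert frac["mixed"] == 0.0

    def test_per_mouse_table(self):
        cats = [vc.categorize_unit(5, 8, 9, unit_id=i) for i in range(4)]
        table = vc.category_fractions(cats, mouse_of={0: "a", 1: "a", 2: "b", 3: "b"})
        assert isinstance(table, pd.DataFrame)
        assert table.loc["a", "increasing"] == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vc.category_fractions([])


class TestHeatmapMatrix:
    def test_rows_normalized_and_ordered_by_peak_time(self):
        early = np.zeros(3600); early[300] = 8.0
        late = np.zeros(3600); late[3300] = 4.0
        m, order = vc.heatmap_matrix(
            [make_series(late, unit_id=1), make_series(early, unit_id=0)]
        )
        assert m.max() == 1.0
        assert list(order) == [0, 1]
        assert m[0].argmax() < m[1].argmax()

    def test_constant_unit_ties_to_first_bin(self):
        m, order = vc.heatmap_matrix([make_series(np.full(3600, 3.0), unit_id=5)])
        assert np.all(m == 1.0)

    def test_all_zero_unit_last(self):
        m, order = vc.heatmap_matrix([
            make_series(np.zeros(3600), unit_id=0),
            make_series(np.full(3600, 2.0), unit_id=1),
        ])
        assert list(order) == [1, 0]
        assert np.all(m[1] == 0.0)


class TestGroupCompare:
    def test_identical_samples_mw(self):
        a = np.arange(10.0)
        stat, p, used = vc.group_compare(a, a, test="MW")
        assert p > 0.9

    def test_separated_normals_use_t(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        stat, p, used = vc.group_compare(a, b)
        assert used == "t"
        assert p < 1e-6

    def test_heavy_tailed_selects_mw(self, rng):
        a = rng.lognormal(0, 1.5, 50)
        b = rng.lognormal(0.2, 1.5, 50)
        _, _, used = vc.group_compare(a, b)
        assert used == "MW"

    def test_small_samples_error(self):
        with pytest.raises(ValueError, match="3"):
            vc.group_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_ks_on_request(self, rng):
        _, _, used = vc.group_compare(rng.normal(0, 1, 30), rng.normal(0, 2, 30), test="KS")
        assert used == "KS"


class TestSummarizeMouse:
    def test_sums_and_ratio_mapping(self, plan):
        # two units: constant 5 and constant 3 -> f_BL 8; C1 doubles unit 0
        r0 = np.full(3600, 5.0); r0[1200:2400] = 10.0
        r1 = np.full(3600, 3.0)
        summary = vc.summarize_mouse(
            "m0", [make_series(r0, unit_id=0), make_series(r1, unit_id=1)], plan
        )
        assert summary.f_bl == pytest.approx(8.0)
        assert summary.f_tnf == pytest.approx(13.0)  # TNF injected first
        assert summary.f_il1 == pytest.approx(8.0)
        assert summary.ratio_tnf == pytest.approx((13 - 8) / (13 + 8))
        assert summary.ratio_il1 == pytest.approx(0.0)

    def test_category_invariant_to_cytokine_order(self):
        # same deltas, opposite injection order: category must not change
        plan_ab = SessionPlan(cytokine_order=("TNF", "IL1B"))
        plan_ba = SessionPlan(cytokine_order=("IL1B", "TNF"))
        m = (5.0, 8.0, 3.0)
        assert vc.categorize_unit(*m).category == "mixed"
        # the category depends on injection slots, not cytokine identity
        for plan in (plan_ab, plan_ba):
            rates = np.full(3600, 5.0)
            rates[1200:2400] = 8.0
            rates[2400:] = 3.0
            s = make_series(rates, plan=plan)
            assert vc.categorize_unit(*vc.period_means(s)).category == "mixed"


class TestRebin:
    def test_rate_preserving(self):
        rates = np.arange(3600, dtype=float)
        s = make_series(rates)
        r = vc.rebin(s, 60.0)
        assert len(r.rates) == 60
        assert r.rates[0] == pytest.approx(np.mean(rates[:60]))
        assert r.rates.mean() == pytest.approx(rates.mean())

    def test_non_multiple_errors(self):
        with pytest.raises(ValueError):
            vc.rebin(make_series(np.zeros(3600)), 1.5)
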