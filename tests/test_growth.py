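"""Intake and growth curves, subgroup components and the binned mixture."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silogrowth import (
    BatchConfig,
    BatchEntry,
    ConsumptionSeries,
    DensityState,
    DepartureEvent,
    GrowthParams,
    SiloSpec,
    build_intake_series,
    deviation_series,
    gompertz_weight,
    merge_and_bin,
    subgroup_distributions,
    theoretical_afi,
    weight_variance,
)
from silogrowth.growth import SubgroupDistribution, afi_increment, linear_afi

from oracles import logistic_afi_highprecision, mixture_bin_count_quadrature

PARAMS = GrowthParams(
    A_feed=1000.0, b_feed=0.12, A_weight=160.0, b_weight=6.76, k_weight=0.008,
    var_coeffs=(6.0, 2.0, 0.3, 0.0), adg=0.67, fcr=2.35,
)


def constant_consumption(kg_per_day, days, start=date(2021, 3, 1)):
    """A synthetic per-interval consumption trace: 12 equal 2-h intervals/day."""
    from datetime import datetime, time

    t0 = datetime.combine(start, time(0, 0))
    n = days * 12
    starts = np.array([np.datetime64(t0 + timedelta(hours=2 * k)) for k in range(n)])
    ends = starts + np.timedelta64(2, "h")
    return ConsumptionSeries(interval_start=starts, interval_end=ends,
                             consumed=np.full(n, kg_per_day / 12.0))


def make_batch(entries, departures=()):
    return BatchConfig(
        batch_id="b", entries=entries, departures=list(departures),
        growth=PARAMS, density=DensityState(default_density=640.0),
        silo=SiloSpec(usable_volume=24.0),
    )


class TestTheoreticalAfi:
    def test_age_zero_is_half_the_asymptote(self):
        batch, per = theoretical_afi(0.0, 600, PARAMS)
        assert per == pytest.approx(PARAMS.A_feed / 2.0, rel=1e-15)
        assert batch == pytest.approx(600 * PARAMS.A_feed / 2.0, rel=1e-15)

    def test_asymptote_at_large_age(self):
        _, per = theoretical_afi(50.0 / PARAMS.b_feed, 1, PARAMS)
        assert per == pytest.approx(PARAMS.A_feed, rel=1e-15)

    def test_value_matches_high_precision_oracle(self):
        p = GrowthParams(A_feed=300.0, b_feed=0.15, A_weight=160.0, b_weight=6.76,
                         k_weight=0.008, var_coeffs=(6.0, 2.0, 0.3, 0.0))
        _, per = theoretical_afi(10.0, 1, p)
        assert per == pytest.approx(logistic_afi_highprecision(300, 0.15, 10), rel=1e-14)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            theoretical_afi(-1.0, 1, PARAMS)

    @settings(deadline=None, derandomize=True)
    @given(a1=st.floats(0, 40), a2=st.floats(0, 40))
    def test_strictly_increasing_in_age(self, a1, a2):
        if abs(a1 - a2) < 1e-6:
            return
        lo, hi = sorted((a1, a2))
        _, p_lo = theoretical_afi(lo, 1, PARAMS)
        _, p_hi = theoretical_afi(hi, 1, PARAMS)
        assert p_lo < p_hi < PARAMS.A_feed


class TestGompertz:
    def test_closed_form_at_zero(self):
        assert gompertz_weight(0.0, PARAMS) == pytest.approx(
            PARAMS.A_weight * np.exp(-np.exp(PARAMS.b_weight)), rel=1e-15
        )

    def test_inflection_point_value(self):
        afi = PARAMS.b_weight / PARAMS.k_weight
        assert gompertz_weight(afi, PARAMS) == pytest.approx(PARAMS.A_weight / np.e, rel=1e-14)

    def test_asymptote(self):
        afi = (PARAMS.b_weight + 50.0) / PARAMS.k_weight
        assert gompertz_weight(afi, PARAMS) == pytest.approx(PARAMS.A_weight, rel=1e-15)

    def test_weight_curve_nondecreasing_in_age(self):
        """Composing the intake logistic with the Gompertz curve gives a
        monotone weight-versus-age curve."""
        ages = np.linspace(0, 40, 200)
        _, afi = theoretical_afi(ages, 1, PARAMS)
        aw = gompertz_weight(afi, PARAMS)
        assert np.all(np.diff(aw) > 0)
        assert np.all(aw < PARAMS.A_weight)


class TestVariance:
    @pytest.mark.parametrize("coeffs,week,want", [((25.0, 0, 0, 0), 7, 25.0), ((9.0, 1.0, 0, 0), 4, 13.0)])
    def test_polynomial_evaluation(self, coeffs, week, want):
        p = PARAMS.model_copy(update={"var_coeffs": coeffs})
        assert weight_variance(week, p) == want


class TestSensorAfi:
    def test_constant_consumption_and_head_count(self):
        cfg = make_batch([BatchEntry(entry_date=date(2021, 3, 1), n_animals=600, avg_weight=25, age_weeks=10)])
        intake = build_intake_series(constant_consumption(1200.0, 14), cfg)
        assert intake.afi_sensor[0] == pytest.approx(14.0, rel=1e-12)  # 2 kg/day × 7
        assert intake.afi_sensor[1] == pytest.approx(28.0, rel=1e-12)

    def test_departure_doubles_per_animal_intake(self):
        cfg = make_batch(
            [BatchEntry(entry_date=date(2021, 3, 1), n_animals=600, avg_weight=25, age_weeks=10)],
            [DepartureEvent(date=date(2021, 3, 8), n_removed=300)],
        )
        intake = build_intake_series(constant_consumption(1200.0, 14), cfg)
        week0 = intake.afi_sensor[0]
        week1 = intake.afi_sensor[1] - intake.afi_sensor[0]
        assert week1 == pytest.approx(2.0 * week0, rel=1e-12)

    def test_zero_animals_with_consumption_rejected(self):
        cfg = make_batch(
            [BatchEntry(entry_date=date(2021, 3, 1), n_animals=100, avg_weight=25, age_weeks=10)],
            [DepartureEvent(date=date(2021, 3, 5), n_removed=100)],
        )
        with pytest.raises(ValueError, match="zero animals"):
            build_intake_series(constant_consumption(1200.0, 14), cfg)

    def test_linear_cross_check_column(self):
        cfg = make_batch([BatchEntry(entry_date=date(2021, 3, 1), n_animals=600, avg_weight=25, age_weeks=10)])
        intake = build_intake_series(constant_consumption(1200.0, 14), cfg)
        assert intake.afi_linear[0] == pytest.approx(linear_afi(7.0, PARAMS))

    def test_recovers_simulator_truth_within_one_percent(self, noisy_sim, noisy_result):
        est = noisy_result.intake.afi_sensor
        truth = noisy_sim.truth.weekly_afi_onfarm
        assert np.max(np.abs(est - truth) / truth) < 0.01


class TestSubgroups:
    def entry(self, day, n=200):
        return BatchEntry(entry_date=date(2021, 3, 1) + timedelta(days=day),
                          n_animals=n, avg_weight=25, age_weeks=10)

    def test_single_entry_single_component(self):
        cfg = make_batch([self.entry(0, 600)])
        intake = build_intake_series(constant_consumption(1200.0, 28), cfg)
        comps = subgroup_distributions(intake, cfg, 3)
        assert len(comps) == 1
        assert comps[0].n_alive == 600

    def test_later_entry_has_smaller_mean(self):
        cfg = make_batch([self.entry(0), self.entry(7)])
        intake = build_intake_series(constant_consumption(1200.0, 35), cfg)
        comps = subgroup_distributions(intake, cfg, 4, basis="theory")
        assert len(comps) == 2
        assert comps[1].mean < comps[0].mean

    def test_theory_means_equal_direct_curve_evaluation(self):
        cfg = make_batch([self.entry(0), self.entry(7), self.entry(14)])
        intake = build_intake_series(constant_consumption(1500.0, 49), cfg)
        week = 6
        comps = subgroup_distributions(intake, cfg, week, basis="theory")
        for comp, entry in zip(comps, cfg.entries):
            e_week = (entry.entry_date - cfg.start_date).days / 7.0
            afi_abs = theoretical_afi(entry.age_weeks, 1, PARAMS)[1] + afi_increment(
                entry.age_weeks, (week + 1) - e_week, PARAMS
            )
            assert comp.mean == pytest.approx(gompertz_weight(float(afi_abs), PARAMS), rel=1e-12)


class TestMergeAndBin:
    def one_component(self):
        return SubgroupDistribution(entry_index=0, week=10, mean=100.0, variance=25.0, n_alive=100.0)

    def test_bin_counts_match_quadrature_oracle(self):
        dist = merge_and_bin([self.one_component()], bin_width=5.0)
        for low, high, count in dist.bins:
            want = mixture_bin_count_quadrature([100.0], [5.0], [100.0], low, high)
            assert count == pytest.approx(want, abs=1e-6)
        by_low = {b[0]: b[2] for b in dist.bins}
        assert by_low[95.0] == pytest.approx(34.134, abs=1e-3)

    def test_symmetric_bins_carry_equal_counts(self):
        dist = merge_and_bin([self.one_component()], bin_width=5.0)
        by_low = {b[0]: b[2] for b in dist.bins}
        assert by_low[95.0] == pytest.approx(by_low[100.0], rel=1e-12)

    def test_counts_sum_to_head_count(self):
        dist = merge_and_bin([self.one_component()], bin_width=5.0)
        assert dist.total_count() == pytest.approx(100.0, abs=0.01)

    def test_bins_contiguous_half_open(self):
        comps = [
            self.one_component(),
            SubgroupDistribution(entry_index=1, week=10, mean=82.0, variance=16.0, n_alive=50.0),
        ]
        dist = merge_and_bin(comps, bin_width=5.0)
        lows = np.array([b[0] for b in dist.bins])
        highs = np.array([b[1] for b in dist.bins])
        assert np.allclose(highs[:-1], lows[1:])
        assert dist.total_count() == pytest.approx(150.0, rel=1e-4)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            merge_and_bin([])


class TestDeviation:
    def test_identity_gives_zeros(self):
        a = np.array([1.0, 2.0, 3.0])
        assert np.allclose(deviation_series(a, a), 0.0)

    def test_uniform_scaling(self):
        t = np.array([10.0, 20.0, 30.0])
        assert np.allclose(deviation_series(1.2 * t, t), 0.2)

    def test_zero_over_zero_defined_as_zero(self):
        assert deviation_series([0.0], [0.0])[0] == 0.0

    def test_sign_negative_exactly_in_underfed_weeks(self):
        """A windowed underfeeding episode shows up as negative weekly
        deviations exactly during the episode."""
        from silogrowth import ScenarioConfig, process_batch, simulate

        cfg = ScenarioConfig(seed=5, noise_sd_fraction=0.0, missing_probability=0.0,
                             anomalies=[(8, 0.8), (12, 1.0)])
        sim = simulate(cfg)
        res = process_batch(sim.series, sim.batch)
        dev = res.deviation_alert_basis
        assert np.all(dev[8:12] < -0.05)
        assert np.all(np.abs(np.concatenate([dev[:8], dev[12:]])) < 0.05)
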