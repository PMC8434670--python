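"""Silo stage: geometry, refill detection, density, cleaning, consumption."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silogrowth import (
    CleaningConfig,
    DensityState,
    LevelSeries,
    RefillEvent,
    SensorReading,
    SiloSpec,
    WeightSeries,
    clean_series,
    compute_consumption,
    detect_refills,
    estimate_density,
    level_to_volume,
    volume_to_weight,
)
from silogrowth.silo import blend_density, _increase_runs

from oracles import (
    cone_cylinder_volume_quadrature,
    increase_runs_bruteforce,
    refills_bruteforce,
    smooth_bruteforce,
)

T0 = datetime(2021, 3, 1)


def level_series(fractions, start=T0, step_hours=2):
    readings = []
    for k, f in enumerate(fractions):
        ts = start + timedelta(hours=step_hours * k)
        if f is None or (isinstance(f, float) and np.isnan(f)):
            readings.append(SensorReading(timestamp=ts, quality_flag="missing"))
        else:
            readings.append(SensorReading(timestamp=ts, level_fraction=float(f)))
    return LevelSeries(readings=readings)


def weight_series(weights, seg=None, start=T0):
    weights = np.asarray(weights, dtype=float)
    ts = np.array([np.datetime64(start) + np.timedelta64(2 * k, "h") for k in range(len(weights))])
    seg = np.zeros(len(weights), dtype=int) if seg is None else np.asarray(seg)
    return WeightSeries(timestamps=ts, weight=weights, segment_id=seg)


class TestGeometry:
    def test_linear_boundaries(self):
        silo = SiloSpec(usable_volume=20.0)
        assert level_to_volume(0.0, silo) == 0.0
        assert level_to_volume(1.0, silo) == 20.0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            level_to_volume(1.5, SiloSpec(usable_volume=20.0))

    def test_cylinder_cone_half_height_matches_quadrature(self):
        d, hc, hb = 2.5, 2.0, 6.0
        vol_total = math.pi * (d / 2) ** 2 * (hc / 3.0 + hb)
        silo = SiloSpec(usable_volume=vol_total, geometry="cylinder_cone",
                        body_height=hb, cone_height=hc, diameter=d)
        got = level_to_volume(0.5, silo)
        want = cone_cylinder_volume_quadrature(d, hc, hb, 0.5 * (hc + hb))
        assert got == pytest.approx(want, rel=1e-9)

    def test_monotone_in_fraction(self):
        d, hc, hb = 2.5, 2.0, 6.0
        vol_total = math.pi * (d / 2) ** 2 * (hc / 3.0 + hb)
        silo = SiloSpec(usable_volume=vol_total, geometry="cylinder_cone",
                        body_height=hb, cone_height=hc, diameter=d)
        f = np.linspace(0, 1, 101)
        v = np.array([level_to_volume(x, silo) for x in f])
        assert np.all(np.diff(v) > 0)
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(vol_total, rel=1e-12)


class TestVolumeToWeight:
    @pytest.mark.parametrize("vol,rho,want", [(20.0, 650.0, 13000.0), (0.0, 700.0, 0.0), (10.0, 640.0, 6400.0)])
    def test_product(self, vol, rho, want):
        assert volume_to_weight(vol, rho) == want

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            volume_to_weight(10.0, 0.0)


class TestDetectRefills:
    def test_strictly_decreasing_gives_no_events(self):
        silo = SiloSpec(usable_volume=24.0)
        series = level_series(np.linspace(0.9, 0.3, 80))
        assert detect_refills(series, silo, CleaningConfig()) == []

    def test_single_jump_detected_at_its_index(self):
        silo = SiloSpec(usable_volume=24.0)
        frac = list(np.linspace(0.5, 0.4, 50)) + list(np.linspace(0.4 + 10 / 24, 0.5, 50))
        series = level_series(frac)
        events = detect_refills(series, silo, CleaningConfig(refill_threshold=1.0))
        assert len(events) == 1
        assert events[0].timestamp == T0 + timedelta(hours=2 * 50)
        assert events[0].detected_volume_delta == pytest.approx(10.0, rel=1e-6)

    def test_noisy_trace_recovers_injected_refills_matching_bruteforce(self):
        """Two refills of 8 and 9 m³ amid ±0.05 m³ noise, against the
        exhaustive run-enumeration oracle."""
        rng = np.random.default_rng(7)
        usable = 24.0
        vol = 20.0 - 0.1 * np.arange(300.0)
        vol[100:] += 8.0
        vol[220:] += 9.0
        vol = vol + rng.uniform(-0.05, 0.05, size=300)
        silo = SiloSpec(usable_volume=usable)
        series = level_series(vol / usable)
        cfg = CleaningConfig(refill_threshold=1.0, despike_window=1)
        events = detect_refills(series, silo, cfg)
        got = [(e.timestamp, e.detected_volume_delta) for e in events]
        want = refills_bruteforce(vol, 1.0, halo=1)
        assert len(got) == 2
        assert [T0 + timedelta(hours=2 * k) for k, _ in want] == [t for t, _ in got]
        for (_, g1), (_, g2) in zip(want, got):
            assert g2 == pytest.approx(usable * (g1 / usable), rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_enumeration_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        vol = np.cumsum(rng.normal(-0.02, 0.4, size=400)) + 30.0
        runs = _increase_runs(vol)
        want = increase_runs_bruteforce(vol)
        assert [(i, j) for i, j, _ in runs] == [(i, j) for i, j, _ in want]
        assert np.allclose([g for *_, g in runs], [g for *_, g in want], atol=1e-12)


class TestDensity:
    def test_declared_weight_over_delta(self):
        ev = RefillEvent(timestamp=T0, declared_weight=6500.0, detected_volume_delta=10.0)
        assert estimate_density(ev, DensityState(default_density=640.0)) == 650.0

    def test_fallback_to_default(self):
        ev = RefillEvent(timestamp=T0, detected_volume_delta=10.0)
        assert estimate_density(ev, DensityState(default_density=640.0)) == 640.0

    def test_declared_without_delta_cannot_calibrate(self):
        ev = RefillEvent(timestamp=T0, declared_weight=6500.0)
        with pytest.raises(ValueError, match="calibrate"):
            estimate_density(ev, DensityState(default_density=640.0))

    def test_blend_is_mass_over_volume(self):
        # 2,000 kg at 600 kg/m³ + 6,000 kg at 660: density = total mass/total volume
        got = blend_density(2000.0, 600.0, 6000.0, 660.0)
        want = 8000.0 / (2000.0 / 600.0 + 6000.0 / 660.0)
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(643.9, abs=0.05)


class TestCleanSeries:
    def test_constant_segment_is_fixed_point(self):
        ws = weight_series(np.full(60, 5000.0))
        out = clean_series(ws, CleaningConfig())
        assert np.allclose(out.weight, 5000.0)

    def test_affine_segment_unchanged(self):
        ws = weight_series(10_000.0 - 25.0 * np.arange(80.0))
        out = clean_series(ws, CleaningConfig())
        assert np.allclose(out.weight, ws.weight, atol=1e-9)

    def test_matches_bruteforce_smoother_and_reduces_rmse(self):
        rng = np.random.default_rng(42)
        truth = 12_000.0 - 20.0 * np.arange(200.0)
        noisy = truth + rng.normal(0.0, 30.0, 200)
        out = clean_series(weight_series(noisy), CleaningConfig(window=13))
        want = smooth_bruteforce(noisy, 13)
        assert np.allclose(out.weight, want, atol=1e-9)
        assert np.sqrt(np.mean((out.weight - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_short_gaps_interpolated_long_gaps_dropped(self):
        w = 10_000.0 - 50.0 * np.arange(40.0)
        w[10:13] = np.nan  # 3 missing <= max_gap
        w[25:35] = np.nan  # 10 missing > max_gap
        out = clean_series(weight_series(w), CleaningConfig(window=3, max_gap_interpolate=6))
        assert len(out) == 40 - 10
        # interpolated stretch follows the affine trend exactly
        assert np.allclose(out.weight[:20], (10_000.0 - 50.0 * np.arange(40.0))[:20], atol=1e-9)

    def test_output_nonincreasing_within_segments(self):
        rng = np.random.default_rng(3)
        w = np.concatenate([9000 - 30 * np.arange(50.0), 14000 - 30 * np.arange(50.0)])
        w += rng.normal(0, 40, 100)
        seg = np.repeat([0, 1], 50)
        out = clean_series(weight_series(w, seg), CleaningConfig())
        for s in (0, 1):
            assert np.all(np.diff(out.weight[out.segment_id == s]) <= 1e-9)

    def test_idempotent_on_smooth_monotone_segment(self):
        cfg = CleaningConfig(window=13)
        base = clean_series(weight_series(11_000.0 - 18.0 * np.arange(120.0)), cfg)
        again = clean_series(WeightSeries(base.timestamps, base.weight.copy(), base.segment_id), cfg)
        assert np.allclose(again.weight, base.weight, atol=1e-9)


class TestConsumption:
    def test_within_segment_differences(self):
        out = compute_consumption(weight_series([10_000.0, 9_900.0, 9_850.0]))
        assert np.allclose(out.consumed, [100.0, 50.0])

    def test_refill_boundary_mass_balance(self):
        ws = weight_series([2_100.0, 2_000.0, 8_450.0, 8_400.0], seg=[0, 0, 1, 1])
        out = compute_consumption(ws, refill_weights={1: 6_500.0})
        assert np.allclose(out.consumed, [100.0, 50.0, 50.0])

    def test_negative_within_segment_is_invariant_violation(self):
        with pytest.raises(RuntimeError, match="invariant"):
            compute_consumption(weight_series([9_000.0, 9_100.0]))

    def test_segment_total_telescopes(self):
        rng = np.random.default_rng(5)
        w = np.sort(rng.uniform(4000, 12000, 50))[::-1].copy()
        out = compute_consumption(weight_series(w))
        assert out.total() == pytest.approx(w[0] - w[-1], rel=1e-12)
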