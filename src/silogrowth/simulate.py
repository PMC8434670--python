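"""Digital twin of a fattening batch fed from a sensor-monitored silo.

The generator produces ground-truthed scenarios so every pipeline stage can
be tested without hardware: a batch of pigs whose per-animal daily intake is
the day-differenced logistic intake curve (optionally scaled by injected
anomaly multipliers), a silo drained by that consumption and replenished by
a reorder-level policy with per-truckload density draws, and a 2-hourly
level trace with additive Gaussian reading noise and random missing
readings.  All randomness flows from one seeded stream in documented order:
the initial-fill density, then per-refill densities as they occur
interleaved with per-reading (noise, missingness) draws.

Default conditions: 600 pigs entering at age 10 weeks / 25 kg, an 18-week
horizon, a 24 m³ silo (~15,400 kg at the default 640 kg/m³ density),
truckloads of 6,000 kg delivered at the 10:00 reading whenever the level
has fallen to 25%, per-load densities uniform on 600–680 kg/m³, reading
noise of 1% of capacity and 2% missing readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .growth import _subgroup_head_counts, gompertz_weight, theoretical_afi
from .types import (
    BatchConfig,
    BatchEntry,
    DensityState,
    DepartureEvent,
    GrowthParams,
    LevelSeries,
    RefillEvent,
    SensorReading,
    SiloSpec,
)

__all__ = ["ScenarioConfig", "GroundTruth", "SimulationResult", "simulate", "simulate_batch", "simulate_silo_trace"]


def default_growth_params() -> GrowthParams:
    """Plausible fattening-pig curves: entry ≈ 25 kg at age 10 weeks,
    ≈ 110 kg after 18 weeks on farm, average intake ≈ 1.6 kg/day."""
    return GrowthParams(
        A_feed=1000.0,
        b_feed=0.12,
        A_weight=160.0,
        b_weight=6.76,
        k_weight=0.008,
        var_coeffs=(6.0, 2.0, 0.3, 0.0),
        adg=0.67,
        fcr=2.35,
    )


class ScenarioConfig(BaseModel):
    """One simulated study condition."""

    seed: int = 0
    n_animals: int = Field(default=600, ge=1)
    entry_age_weeks: float = 10.0
    entry_avg_weight: float = 25.0
    #: additional entries as (week offset, head count, age weeks, avg weight kg)
    extra_entries: list[tuple[int, int, float, float]] = Field(default_factory=list)
    horizon_weeks: int = Field(default=18, ge=1)
    start: date = date(2021, 3, 1)
    silo: SiloSpec = Field(default_factory=lambda: SiloSpec(usable_volume=24.0))
    default_density: float = Field(default=640.0, gt=0)
    density_range: tuple[float, float] = (600.0, 680.0)
    noise_sd_fraction: float = Field(default=0.01, ge=0)
    missing_probability: float = Field(default=0.02, ge=0, lt=0.5)
    reorder_level_fraction: float = Field(default=0.25, gt=0, lt=1)
    load_size_kg: float = Field(default=6000.0, gt=0)
    delivery_hour: int = Field(default=10, ge=0, le=22)
    reading_interval_hours: int = Field(default=2, ge=1)
    initial_fill_fraction: float = Field(default=0.92, gt=0, le=1)
    #: (start week, intake multiplier); each persists until overridden
    anomalies: list[tuple[int, float]] = Field(default_factory=list)
    #: indices (0-based, in time order) of in-series refills whose declared
    #: weight the farmer "forgets" to enter
    withhold_declarations: list[int] = Field(default_factory=list)
    marketing_weight: float = Field(default=110.0, gt=0)
    truckload: int = Field(default=100, ge=1)
    growth: GrowthParams = Field(default_factory=default_growth_params)

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        lo, hi = self.density_range
        if not (0 < lo <= hi):
            raise ValueError("density_range must be 0 < low <= high")
        if 24 % self.reading_interval_hours != 0:
            raise ValueError("reading_interval_hours must divide 24")
        return self

    def intake_multiplier(self, week: int) -> float:
        m = 1.0
        for start_week, mult in sorted(self.anomalies):
            if week >= start_week:
                m = mult
        return m


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    days: list[date]
    daily_per_animal_intake: np.ndarray  # kg, batch average over animals present
    daily_batch_consumption: np.ndarray  # kg
    heads: np.ndarray
    weekly_afi_onfarm: np.ndarray  # kg/animal, end of each complete week
    subgroup_weekly_afi_abs: np.ndarray  # (n_entries, n_weeks), kg/animal from birth
    subgroup_weekly_aw: np.ndarray  # (n_entries, n_weeks), kg
    total_consumption: float  # kg over the horizon
    # filled in by the trace simulation:
    initial_fill: dict = field(default_factory=dict)
    refill_log: list[dict] = field(default_factory=list)
    segment_densities: list[float] = field(default_factory=list)
    mass_residual: float = 0.0
    level_true: Optional[np.ndarray] = None
    mass_true: Optional[np.ndarray] = None


@dataclass
class SimulationResult:
    truth: GroundTruth
    batch: BatchConfig
    series: LevelSeries
    scenario: ScenarioConfig


def _entries(cfg: ScenarioConfig) -> list[BatchEntry]:
    entries = [
        BatchEntry(
            entry_date=cfg.start,
            n_animals=cfg.n_animals,
            avg_weight=cfg.entry_avg_weight,
            age_weeks=cfg.entry_age_weeks,
        )
    ]
    for week, n, age, w in cfg.extra_entries:
        entries.append(
            BatchEntry(entry_date=cfg.start + timedelta(weeks=week), n_animals=n, avg_weight=w, age_weeks=age)
        )
    return entries


def simulate_batch(cfg: ScenarioConfig) -> tuple[GroundTruth, BatchConfig]:
    """Generate the biological ground truth and the farmer-declared batch record.

    Per-animal daily intake is the day-differenced logistic intake curve at
    each subgroup's age, scaled by any active anomaly multiplier; subgroup
    average weights follow the Gompertz curve at the subgroup's (actual)
    accumulated intake.  Departures are scheduled in truckload-sized groups
    once a subgroup's average weight crosses the marketing weight.  The
    returned config carries no refills; the trace simulation adds them.
    """
    entries = _entries(cfg)
    n_days = cfg.horizon_weeks * 7
    n_weeks = cfg.horizon_weeks
    days = [cfg.start + timedelta(days=d) for d in range(n_days)]
    g = cfg.growth
    n_e = len(entries)
    entry_day = [(e.entry_date - cfg.start).days for e in entries]

    # per-subgroup per-animal daily intake (kg), anomaly-scaled
    sub_daily = np.zeros((n_e, n_days))
    for i, e in enumerate(entries):
        for d in range(entry_day[i], n_days):
            age = e.age_weeks + (d - entry_day[i]) / 7.0
            _, a0 = theoretical_afi(age, 1, g)
            _, a1 = theoretical_afi(age + 1.0 / 7.0, 1, g)
            sub_daily[i, d] = (a1 - a0) * cfg.intake_multiplier(d // 7)

    # schedule departures from the actual weight trajectory
    departures: list[DepartureEvent] = []
    sub_afi_abs = np.array([theoretical_afi(e.age_weeks, 1, g)[1] for e in entries])
    alive = np.array([float(e.n_animals) if entry_day[i] == 0 else 0.0 for i, e in enumerate(entries)])
    for d in range(n_days):
        for i in range(n_e):
            if entry_day[i] == d and d > 0:
                alive[i] += entries[i].n_animals
        if d % 7 == 6 and d > 0:  # end of a week: check the marketing rule
            aw = gompertz_weight(sub_afi_abs + 1e-12, g)
            heavy = int(np.argmax(aw))
            if aw[heavy] >= cfg.marketing_weight and alive.sum() > 0:
                n_out = int(min(cfg.truckload, alive.sum()))
                dep_date = cfg.start + timedelta(days=d + 1)
                departures.append(
                    DepartureEvent(date=dep_date, n_removed=n_out, abattoir_weight=n_out * float(aw[heavy]))
                )
                alive -= n_out * alive / alive.sum()
        sub_afi_abs += sub_daily[:, d]

    batch = BatchConfig(
        batch_id=f"sim-{cfg.seed}",
        entries=entries,
        departures=departures,
        refills=[],
        growth=g,
        density=DensityState(default_density=cfg.default_density),
        silo=cfg.silo,
    )

    heads = np.array([batch.animals_present(day) for day in days], dtype=float)
    counts = np.zeros((n_e, n_days))
    for d, day in enumerate(days):
        counts[:, d] = _subgroup_head_counts(batch, day)
    daily_batch = (counts * sub_daily).sum(axis=0)
    per_animal = np.divide(daily_batch, heads, out=np.zeros(n_days), where=heads > 0)
    cum = np.cumsum(per_animal)
    weekly_afi = np.array([cum[7 * (t + 1) - 1] for t in range(n_weeks)])

    sub_afi_abs_w = np.zeros((n_e, n_weeks))
    running = np.array([theoretical_afi(e.age_weeks, 1, g)[1] for e in entries])
    cum_sub = np.cumsum(sub_daily, axis=1)
    for t in range(n_weeks):
        sub_afi_abs_w[:, t] = running + cum_sub[:, 7 * (t + 1) - 1]
    sub_aw_w = gompertz_weight(sub_afi_abs_w, g)

    truth = GroundTruth(
        days=days,
        daily_per_animal_intake=per_animal,
        daily_batch_consumption=daily_batch,
        heads=heads,
        weekly_afi_onfarm=weekly_afi,
        subgroup_weekly_afi_abs=sub_afi_abs_w,
        subgroup_weekly_aw=sub_aw_w,
        total_consumption=float(daily_batch.sum()),
    )
    return truth, batch


def simulate_silo_trace(
    truth: GroundTruth, cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> tuple[LevelSeries, list[RefillEvent]]:
    """Drain the silo with the true consumption and emit the noisy level trace.

    The silo opens filled to ``initial_fill_fraction`` at a drawn density;
    the opening load is always declared (it is part of the batch set-up).
    Whenever the level at the delivery-hour reading has fallen to the
    reorder fraction, a truckload of ``load_size_kg`` at a freshly drawn
    density is added; blending is mass-weighted.  Readings get additive
    Gaussian level noise (sd = ``noise_sd_fraction`` of capacity) and are
    dropped with ``missing_probability`` (never the first reading, which
    anchors the declared opening content).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    per_day = 24 // cfg.reading_interval_hours
    n_days = cfg.horizon_weeks * 7
    n_read = n_days * per_day + 1
    t0 = datetime.combine(cfg.start, time(0, 0))
    dt = timedelta(hours=cfg.reading_interval_hours)
    silo = cfg.silo

    rho0 = float(rng.uniform(*cfg.density_range))
    vol = cfg.initial_fill_fraction * silo.usable_volume
    mass = vol * rho0
    m0, v0 = mass, vol
    truth.initial_fill = {"weight_kg": mass, "density": rho0, "volume_m3": vol}
    truth.segment_densities = [rho0]

    declared: list[RefillEvent] = [RefillEvent(timestamp=t0, declared_weight=mass)]
    refill_idx = 0
    loads_total = 0.0
    level_true = np.empty(n_read)
    mass_true = np.empty(n_read)
    readings: list[SensorReading] = []

    def level_of(v: float) -> float:
        if silo.geometry == "linear":
            return v / silo.usable_volume
        return silo.height_at_volume(v) / silo.total_height

    for k in range(n_read):
        ts = t0 + k * dt
        if k > 0:
            day = (k - 1) // per_day
            c = truth.daily_batch_consumption[day] / per_day
            if c > mass:
                raise RuntimeError(f"silo ran empty on {ts}: infeasible refill policy")
            rho_cur = mass / vol
            mass -= c
            vol -= c / rho_cur
            if ts.hour == cfg.delivery_hour and level_of(vol) <= cfg.reorder_level_fraction:
                rho_load = float(rng.uniform(*cfg.density_range))
                if vol + cfg.load_size_kg / rho_load > silo.usable_volume * (1 + 1e-9):
                    raise RuntimeError("infeasible refill policy: load exceeds silo capacity")
                vol += cfg.load_size_kg / rho_load
                mass += cfg.load_size_kg
                loads_total += cfg.load_size_kg
                withheld = refill_idx in cfg.withhold_declarations
                if not withheld:
                    declared.append(RefillEvent(timestamp=ts, declared_weight=cfg.load_size_kg))
                truth.refill_log.append(
                    {
                        "timestamp": ts.isoformat(),
                        "weight_kg": cfg.load_size_kg,
                        "density": rho_load,
                        "declared": not withheld,
                    }
                )
                truth.segment_densities.append(mass / vol)
                refill_idx += 1
        level_true[k] = level_of(vol)
        mass_true[k] = mass
        z = rng.normal()
        miss = rng.uniform() < cfg.missing_probability and k > 0
        if miss:
            readings.append(SensorReading(timestamp=ts, quality_flag="missing"))
        else:
            lvl = float(np.clip(level_true[k] + cfg.noise_sd_fraction * z, 0.0, 1.0))
            readings.append(SensorReading(timestamp=ts, level_fraction=lvl))

    truth.level_true = level_true
    truth.mass_true = mass_true
    consumed = float(truth.daily_batch_consumption[:n_days].sum())
    truth.mass_residual = float(mass_true[-1] - (m0 + loads_total - consumed))
    series = LevelSeries(readings=readings, nominal_interval=dt)
    return series, declared


def simulate(cfg: ScenarioConfig) -> SimulationResult:
    """Full scenario: biological truth, silo trace, and the declared batch record."""
    truth, batch = simulate_batch(cfg)
    rng = np.random.default_rng(cfg.seed)
    series, declared = simulate_silo_trace(truth, cfg, rng)
    batch = batch.model_copy(update={"refills": declared})
    return SimulationResult(truth=truth, batch=batch, series=series, scenario=cfg)
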