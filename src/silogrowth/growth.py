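"""Accumulated feed intake, Gompertz body weight, and the batch weight distribution.

Two curves drive everything.  Per-animal accumulated feed intake (AFI, kg)
is a logistic in the animals' age in weeks,

    afi(age) = A_feed / (1 + exp(-b_feed * age)),

and average body weight (kg) is a Gompertz curve in accumulated intake,

    aw(afi) = A_weight * exp(-exp(b_weight - k_weight * afi)).

A batch is a mixture of entry subgroups; each subgroup's weight spread at a
given week is modelled as a Normal with the Gompertz mean and a variance
given by a cubic polynomial in the weeks elapsed since that subgroup's
entry.  Merging the subgroup Normals head-count-weighted and integrating
over 5-kg bins gives the expected number of animals per weight range.

Week indexing is 0-based with half-open weeks [7t, 7t+7) from the batch
start; "AFI at week t" means the accumulation through the *end* of week t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .silo import ConsumptionSeries
from .types import BatchConfig, GrowthParams, animals_present

__all__ = [
    "theoretical_afi",
    "afi_increment",
    "gompertz_weight",
    "weight_variance",
    "linear_afi",
    "IntakeSeries",
    "build_intake_series",
    "SubgroupDistribution",
    "WeightDistribution",
    "subgroup_distributions",
    "merge_and_bin",
    "deviation_series",
]


def theoretical_afi(age_weeks, n_animals: int, params: GrowthParams):
    """Expected accumulated feed intake at a given age.

    Returns ``(batch_kg, per_animal_kg)``: the per-animal logistic value
    ``A_feed / (1 + exp(-b_feed * age))`` and the batch total for
    ``n_animals`` animals.  Strictly increasing in age, approaching
    ``n_animals * A_feed`` asymptotically.
    """
    age = np.asarray(age_weeks, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_weeks must be non-negative")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    per_animal = params.A_feed / (1.0 + np.exp(-params.b_feed * age))
    batch = n_animals * per_animal
    if np.ndim(age_weeks) == 0:
        return float(batch), float(per_animal)
    return batch, per_animal


def afi_increment(age_entry_weeks: float, elapsed_weeks, params: GrowthParams):
    """On-farm accumulated intake per animal: afi(entry age + elapsed) - afi(entry age)."""
    _, a0 = theoretical_afi(age_entry_weeks, 1, params)
    _, a1 = theoretical_afi(age_entry_weeks + np.asarray(elapsed_weeks, dtype=float), 1, params)
    return a1 - a0


def gompertz_weight(afi_per_animal, params: GrowthParams):
    """Average body weight (kg) at a per-animal accumulated intake (kg).

    Strictly increasing in AFI and bounded above by ``A_weight``.
    """
    afi = np.asarray(afi_per_animal, dtype=float)
    if np.any(afi < 0):
        raise ValueError("afi_per_animal must be non-negative")
    out = params.A_weight * np.exp(-np.exp(params.b_weight - params.k_weight * afi))
    if np.ndim(afi_per_animal) == 0:
        return float(out)
    return out


def weight_variance(week, params: GrowthParams):
    """Between-animal weight variance (kg²): cubic polynomial in elapsed weeks."""
    t = np.asarray(week, dtype=float)
    if np.any(t < 0):
        raise ValueError("week must be non-negative")
    c0, c1, c2, c3 = params.var_coeffs
    out = c0 + c1 * t + c2 * t**2 + c3 * t**3
    if np.ndim(week) == 0:
        return float(out)
    return out


def linear_afi(days_on_farm, params: GrowthParams):
    """Secondary linear intake cross-check: ADG × FCR × days on farm (kg/animal)."""
    if params.adg is None or params.fcr is None:
        raise ValueError("adg and fcr must be set for the linear cross-check")
    return params.adg * params.fcr * np.asarray(days_on_farm, dtype=float)


# ---------------------------------------------------------------------------
# intake series


@dataclass
class IntakeSeries:
    """Weekly per-animal accumulated feed intake, sensor-based and theoretical.

    ``afi_sensor[t]``/``afi_theory[t]`` are cumulative kg per animal through
    the end of week t; ``n_present[t]`` is the average head count that week.
    ``afi_linear`` is the ADG×FCR straight-line cross-check (NaN when ADG/FCR
    are not configured).
    """

    week: np.ndarray
    afi_sensor: np.ndarray
    afi_theory: np.ndarray
    n_present: np.ndarray
    afi_linear: np.ndarray
    daily_per_animal: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("afi_sensor", "afi_theory"):
            a = getattr(self, name)
            if np.any(np.diff(a) < -1e-9):
                raise ValueError(f"{name} must be non-decreasing in week")

    def weekly_increments(self, column: str = "afi_sensor") -> np.ndarray:
        a = getattr(self, column)
        return np.diff(np.concatenate([[0.0], a]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.week,
                "afi_sensor_kg": self.afi_sensor,
                "afi_theory_kg": self.afi_theory,
                "afi_linear_kg": self.afi_linear,
                "n_present": self.n_present,
                "deviation": deviation_series(self.afi_sensor, self.afi_theory),
            }
        )


def _subgroup_head_counts(config: BatchConfig, day: date) -> np.ndarray:
    """Head count per entry subgroup on ``day``, departures attributed
    proportionally to current subgroup sizes (the farmer does not report
    which entry the removed animals belonged to)."""
    alive = np.array([float(e.n_animals) if e.entry_date <= day else 0.0 for e in config.entries])
    for dep in config.departures:
        if dep.date <= day:
            tot = alive.sum()
            if tot > 0:
                alive -= dep.n_removed * alive / tot
    return np.clip(alive, 0.0, None)


def build_intake_series(
    consumption: ConsumptionSeries, config: BatchConfig
) -> IntakeSeries:
    """Weekly sensor-based and theoretical per-animal accumulated intake.

    Daily per-animal intake is the batch's daily consumption divided by the
    head count present that day; the weekly series accumulates complete
    weeks.  The theoretical column is the head-count-weighted mean over the
    entry subgroups of the on-farm logistic increment
    ``afi(entry age + weeks on farm) - afi(entry age)``.
    """
    daily = consumption.daily()
    start = config.start_date
    if len(daily) == 0:
        raise ValueError("consumption series is empty")
    last_day = daily.index.max()
    n_days = (last_day - start).days + 1
    days = [start + timedelta(days=d) for d in range(n_days)]
    batch_daily = np.array([float(daily.get(d, 0.0)) for d in days])
    heads = np.array([animals_present(config, d) for d in days], dtype=float)
    if np.any((heads == 0) & (batch_daily > 0)):
        bad = days[int(np.argmax((heads == 0) & (batch_daily > 0)))]
        raise ValueError(f"positive consumption with zero animals present on {bad.isoformat()}")
    per_animal_daily = np.divide(batch_daily, heads, out=np.zeros_like(batch_daily), where=heads > 0)
    cum = np.cumsum(per_animal_daily)

    n_weeks = n_days // 7
    weeks = np.arange(n_weeks)
    afi_sensor = np.array([cum[7 * (t + 1) - 1] for t in weeks])
    n_present = np.array([heads[7 * t : 7 * t + 7].mean() for t in weeks])

    afi_theory = np.empty(n_weeks)
    for t in weeks:
        day_end = start + timedelta(days=int(7 * (t + 1) - 1))
        counts = _subgroup_head_counts(config, day_end)
        incs = np.array(
            [
                float(afi_increment(e.age_weeks, max(0.0, (t + 1) - (e.entry_date - start).days / 7.0), config.growth))
                for e in config.entries
            ]
        )
        tot = counts.sum()
        afi_theory[t] = float((counts * incs).sum() / tot) if tot > 0 else 0.0

    if config.growth.adg is not None and config.growth.fcr is not None:
        afi_lin = linear_afi(7.0 * (weeks + 1), config.growth)
    else:
        afi_lin = np.full(n_weeks, np.nan)

    daily_series = pd.Series(per_animal_daily, index=pd.Index(days, name="date"))
    return IntakeSeries(
        week=weeks,
        afi_sensor=afi_sensor,
        afi_theory=afi_theory,
        n_present=n_present,
        afi_linear=afi_lin,
        daily_per_animal=daily_series,
    )


# ---------------------------------------------------------------------------
# weight distribution


@dataclass
class SubgroupDistribution:
    """Normal weight component of one entry subgroup at one week."""

    entry_index: int
    week: int
    mean: float  # kg
    variance: float  # kg²
    n_alive: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.mean <= 0:
            raise ValueError("mean must be positive")


@dataclass
class WeightDistribution:
    """Head-count-weighted Normal mixture with expected counts per weight bin."""

    components: list[SubgroupDistribution]
    bin_width: float
    bins: list[tuple[float, float, float]]  # (low kg, high kg, expected count)

    def total_count(self) -> float:
        return sum(b[2] for b in self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["bin_low_kg", "bin_high_kg", "expected_count"])


def subgroup_distributions(
    intake: IntakeSeries,
    config: BatchConfig,
    week: int,
    basis: Literal["sensor", "theory"] = "sensor",
) -> list[SubgroupDistribution]:
    """Normal weight components, one per entry subgroup present at ``week``.

    Each subgroup's Gompertz mean is evaluated at its own accumulated
    intake: the logistic value at its entry age (feed consumed before
    arriving) plus its on-farm accumulation, offset by its entry week.  On
    the sensor basis the on-farm part since the subgroup's entry is taken
    from the measured batch-average series.  The variance argument is the
    weeks elapsed since the subgroup's entry.
    """
    if week not in intake.week:
        raise ValueError(f"week {week} outside the intake series horizon")
    start = config.start_date
    day_end = start + timedelta(days=int(7 * (week + 1) - 1))
    counts = _subgroup_head_counts(config, day_end)
    comps: list[SubgroupDistribution] = []
    for i, e in enumerate(config.entries):
        entry_week = (e.entry_date - start).days / 7.0
        if counts[i] <= 0 or entry_week > week:
            continue
        elapsed = (week + 1) - entry_week
        _, afi_entry = theoretical_afi(e.age_weeks, 1, config.growth)
        if basis == "theory":
            onfarm = float(afi_increment(e.age_weeks, elapsed, config.growth))
        else:
            entry_w = int(np.floor(entry_week))
            prior = intake.afi_sensor[entry_w - 1] if entry_w >= 1 else 0.0
            onfarm = float(intake.afi_sensor[week] - prior)
        mean = gompertz_weight(afi_entry + onfarm, config.growth)
        var = weight_variance(week - entry_week, config.growth)
        comps.append(
            SubgroupDistribution(entry_index=i, week=week, mean=mean, variance=var, n_alive=float(counts[i]))
        )
    return comps


def merge_and_bin(
    components: Sequence[SubgroupDistribution], bin_width: float = 5.0
) -> WeightDistribution:
    """Merge subgroup Normals head-count-weighted and bin the expected counts.

    The expected count in [L, L+w) is Σ n_i (Φ((L+w-μ_i)/σ_i) - Φ((L-μ_i)/σ_i));
    bins are half-open, contiguous, aligned to multiples of ``bin_width``,
    and cover every component's mean ± 4 sd of the widest component, so the
    untallied tail mass is below 1e-4 of the head count.
    """
    if not components:
        raise ValueError("components must be non-empty")
    means = np.array([c.mean for c in components])
    sds = np.array([np.sqrt(c.variance) for c in components])
    ns = np.array([c.n_alive for c in components])
    sd_max = sds.max()
    lo = np.floor((means.min() - 4.0 * sd_max) / bin_width) * bin_width
    hi = np.ceil((means.max() + 4.0 * sd_max) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    bins = []
    for L, H in zip(edges[:-1], edges[1:]):
        count = float(np.sum(ns * (norm.cdf((H - means) / sds) - norm.cdf((L - means) / sds))))
        bins.append((float(L), float(H), count))
    return WeightDistribution(components=list(components), bin_width=bin_width, bins=bins)


def deviation_series(afi_sensor, afi_theory) -> np.ndarray:
    """Per-week relative deviation (sensor - theory) / theory; 0/0 defined as 0."""
    s = np.asarray(afi_sensor, dtype=float)
    t = np.asarray(afi_theory, dtype=float)
    out = np.zeros_like(s)
    nz = t != 0
    out[nz] = (s[nz] - t[nz]) / t[nz]
    return out
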