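"""Domain types for silo-sensor feed-intake and pig-growth analytics.

All timestamps are handled as naive UTC datetimes; farmer-entered calendar
dates are interpreted as midnight UTC.  A fattening *batch* starts at the
earliest entry date and may contain several entry subgroups; feed is drawn
from a single monitored silo whose one-point level sensor reports the
occupied fraction of the usable volume roughly every two hours.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "SensorReading",
    "LevelSeries",
    "SiloSpec",
    "DensityState",
    "RefillEvent",
    "BatchEntry",
    "DepartureEvent",
    "GrowthParams",
    "BatchConfig",
    "animals_present",
    "week_index",
    "as_utc_naive",
]

#: Horizon (weeks) over which the variance polynomial must stay positive.
VARIANCE_HORIZON_WEEKS = 25


def as_utc_naive(ts: datetime) -> datetime:
    """Normalise a datetime to naive UTC (tz-aware inputs are converted)."""
    if ts.tzinfo is not None:
        ts = ts.astimezone(timezone.utc).replace(tzinfo=None)
    return ts


def week_index(day: date, batch_start: date) -> int:
    """0-based week index of ``day`` in half-open weeks [7t, 7t+7) from start."""
    return (day - batch_start).days // 7


class SensorReading(BaseModel):
    """One silo level measurement.

    ``level_fraction`` is the fraction of the usable silo volume occupied
    (for conical silos: the fraction of total fill height).  Readings that
    could not be parsed or were never received carry ``quality_flag='missing'``
    and no level value.
    """

    timestamp: datetime
    level_fraction: Optional[float] = None
    quality_flag: Literal["ok", "missing"] = "ok"

    @model_validator(mode="after")
    def _check(self) -> "SensorReading":
        object.__setattr__(self, "timestamp", as_utc_naive(self.timestamp))
        if self.quality_flag == "ok":
            if self.level_fraction is None or not (0.0 <= self.level_fraction <= 1.0):
                raise ValueError(
                    f"level_fraction must be in [0,1] for an 'ok' reading "
                    f"(got {self.level_fraction!r} at {self.timestamp})"
                )
        return self


class LevelSeries(BaseModel):
    """An ordered series of level readings at a nominal cadence (default 2 h)."""

    readings: list[SensorReading]
    nominal_interval: timedelta = timedelta(hours=2)

    @model_validator(mode="after")
    def _check(self) -> "LevelSeries":
        prev = None
        for r in self.readings:
            if prev is not None and r.timestamp <= prev:
                raise ValueError(
                    f"timestamps must be strictly increasing: duplicate or "
                    f"out-of-order timestamp {r.timestamp.isoformat()}"
                )
            prev = r.timestamp
        return self

    def __len__(self) -> int:
        return len(self.readings)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (timestamps as datetime64[ns], level fractions with NaN for missing)."""
        ts = pd.DatetimeIndex([r.timestamp for r in self.readings]).values
        frac = np.array(
            [r.level_fraction if r.quality_flag == "ok" else np.nan for r in self.readings],
            dtype=float,
        )
        return ts, frac

    def to_frame(self) -> pd.DataFrame:
        ts, frac = self.arrays()
        return pd.DataFrame({"timestamp": ts, "level_fraction": frac})


class SiloSpec(BaseModel):
    """Silo geometry: either a linear level-volume map or a cylinder over a cone.

    For ``cylinder_cone`` geometry the fill occupies the bottom cone (apex
    down, height ``cone_height``) first and then the cylindrical body
    (height ``body_height``); the sensor's fraction refers to fill height
    over total height.
    """

    usable_volume: float = Field(gt=0, description="m³")
    geometry: Literal["linear", "cylinder_cone"] = "linear"
    body_height: Optional[float] = Field(default=None, gt=0, description="m")
    cone_height: Optional[float] = Field(default=None, gt=0, description="m")
    diameter: Optional[float] = Field(default=None, gt=0, description="m")

    @model_validator(mode="after")
    def _check(self) -> "SiloSpec":
        if self.geometry == "cylinder_cone":
            if None in (self.body_height, self.cone_height, self.diameter):
                raise ValueError("cylinder_cone geometry requires body_height, cone_height and diameter")
            total = self.volume_at_height(self.total_height)
            if abs(total - self.usable_volume) > 1e-3 * self.usable_volume:
                raise ValueError(
                    f"cylinder_cone dimensions give {total:.4f} m³ but usable_volume "
                    f"is {self.usable_volume:.4f} m³ (must agree within 0.1%)"
                )
        return self

    @property
    def total_height(self) -> float:
        if self.geometry == "linear":
            raise ValueError("total_height undefined for linear geometry")
        return self.cone_height + self.body_height  # type: ignore[operator]

    def volume_at_height(self, h: float) -> float:
        """Closed-form occupied volume (m³) at fill height h (m), cone apex at h=0."""
        hc = self.cone_height
        R = self.diameter / 2.0  # type: ignore[operator]
        if h <= hc:
            return math.pi * R * R * h**3 / (3.0 * hc * hc)
        v_cone = math.pi * R * R * hc / 3.0
        return v_cone + math.pi * R * R * (h - hc)

    def height_at_volume(self, v: float) -> float:
        """Inverse of :meth:`volume_at_height`."""
        hc = self.cone_height
        R = self.diameter / 2.0  # type: ignore[operator]
        v_cone = math.pi * R * R * hc / 3.0
        if v <= v_cone:
            return (3.0 * v * hc * hc / (math.pi * R * R)) ** (1.0 / 3.0)
        return hc + (v - v_cone) / (math.pi * R * R)


class DensityState(BaseModel):
    """Default feed density plus any per-segment overrides (kg/m³).

    Segments are the stretches of the series delimited by refills; each
    truckload may have a different density, so the pipeline re-estimates a
    density per segment and blends it with what remained in the silo.
    """

    default_density: float = Field(gt=0, description="kg/m³")
    segment_densities: list[tuple[int, float]] = Field(default_factory=list)

    @field_validator("segment_densities")
    @classmethod
    def _pos(cls, v: list[tuple[int, float]]) -> list[tuple[int, float]]:
        for _, d in v:
            if d <= 0:
                raise ValueError("all segment densities must be > 0")
        return v


class RefillEvent(BaseModel):
    """A feed delivery: declared by the farmer and/or detected as a level jump."""

    timestamp: datetime
    declared_weight: Optional[float] = Field(default=None, description="kg")
    detected_volume_delta: Optional[float] = Field(default=None, description="m³")

    @model_validator(mode="after")
    def _check(self) -> "RefillEvent":
        object.__setattr__(self, "timestamp", as_utc_naive(self.timestamp))
        if self.declared_weight is not None and self.declared_weight <= 0:
            raise ValueError("declared_weight must be > 0 when present")
        if self.detected_volume_delta is not None and self.detected_volume_delta <= 0:
            raise ValueError("detected_volume_delta must be > 0 when present")
        return self


class BatchEntry(BaseModel):
    """One truckload of piglets entering the batch."""

    entry_date: date
    n_animals: int = Field(ge=1)
    avg_weight: float = Field(gt=0, description="kg")
    age_weeks: float = Field(ge=0, description="animal age at entry, weeks")


class DepartureEvent(BaseModel):
    """A group of animals sent to the abattoir."""

    date: date
    n_removed: int = Field(ge=1)
    abattoir_weight: Optional[float] = Field(default=None, description="kg, total reported")


class GrowthParams(BaseModel):
    """Parameters of the intake and growth curves.

    Accumulated feed intake per animal follows a logistic in age
    ``afi(age) = A_feed / (1 + exp(-b_feed * age))`` and body weight follows
    a Gompertz curve in accumulated intake
    ``aw(afi) = A_weight * exp(-exp(b_weight - k_weight * afi))``.
    The between-animal weight variance (kg²) is a cubic polynomial in the
    weeks elapsed since the subgroup's entry.  ``adg``/``fcr`` feed a
    secondary linear intake cross-check.
    """

    A_feed: float = Field(gt=0, description="kg, adult accumulated-intake asymptote")
    b_feed: float = Field(gt=0, description="1/weeks")
    A_weight: float = Field(gt=0, description="kg, asymptotic adult body weight")
    b_weight: float = Field(description="dimensionless offset")
    k_weight: float = Field(gt=0, description="1/kg")
    var_coeffs: tuple[float, float, float, float] = Field(
        description="(c0,c1,c2,c3): variance kg² = c0+c1·t+c2·t²+c3·t³ in weeks t"
    )
    adg: Optional[float] = Field(default=None, gt=0, description="kg/day average daily gain")
    fcr: Optional[float] = Field(default=None, gt=0, description="kg feed / kg gain")

    @model_validator(mode="after")
    def _check(self) -> "GrowthParams":
        c0, c1, c2, c3 = self.var_coeffs
        t = np.arange(0.0, VARIANCE_HORIZON_WEEKS + 0.25, 0.25)
        var = c0 + c1 * t + c2 * t**2 + c3 * t**3
        if np.any(var <= 0):
            bad = t[np.argmax(var <= 0)]
            raise ValueError(
                f"variance polynomial must be positive over weeks "
                f"0..{VARIANCE_HORIZON_WEEKS} (non-positive at week {bad:g})"
            )
        return self


class BatchConfig(BaseModel):
    """Everything the farmer declares about one fattening batch."""

    batch_id: str
    entries: list[BatchEntry] = Field(min_length=1)
    departures: list[DepartureEvent] = Field(default_factory=list)
    refills: list[RefillEvent] = Field(default_factory=list)
    growth: GrowthParams
    density: DensityState
    silo: SiloSpec

    @model_validator(mode="after")
    def _check(self) -> "BatchConfig":
        entries = sorted(self.entries, key=lambda e: e.entry_date)
        departures = sorted(self.departures, key=lambda d: d.date)
        refills = sorted(self.refills, key=lambda r: r.timestamp)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "departures", departures)
        object.__setattr__(self, "refills", refills)
        # cumulative departures may never exceed cumulative entries
        for dep in departures:
            n_in = sum(e.n_animals for e in entries if e.entry_date <= dep.date)
            n_out = sum(d.n_removed for d in departures if d.date <= dep.date)
            if n_out > n_in:
                raise ValueError(
                    f"departures exceed entries on {dep.date.isoformat()} "
                    f"({n_out} removed vs {n_in} entered)"
                )
        return self

    @property
    def start_date(self) -> date:
        """The batch start: the earliest entrance of animals."""
        return self.entries[0].entry_date

    def animals_present(self, day: date) -> int:
        return animals_present(self, day)


def animals_present(config: BatchConfig, day: date) -> int:
    """Head count present on ``day`` (entries and departures effective at start of day).

    Raises ``ValueError`` for days before the batch start.
    """
    if day < config.start_date:
        raise ValueError(
            f"day {day.isoformat()} is before the batch start {config.start_date.isoformat()}"
        )
    n_in = sum(e.n_animals for e in config.entries if e.entry_date <= day)
    n_out = sum(d.n_removed for d in config.departures if d.date <= day)
    return n_in - n_out
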