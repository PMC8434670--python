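"""Raw level readings → cleaned feed-weight series → per-interval consumption.

The stage order mirrors the physical process: the level fraction is mapped
to an occupied volume through the silo geometry, feed deliveries show up as
upward jumps and delimit *segments*, a per-segment density (kg/m³)
calibrated from declared truckload weights converts volume to weight, the
weight series is smoothed with a centered moving average and projected onto
the non-increasing cone (feed only leaves a silo between refills), and
consecutive differences finally yield consumption.

Refill jump sizes are re-estimated with continuous piecewise-linear trend
fits (knots at UTC midnights, reflecting the daily granularity of feeding)
extrapolated to the refill instant from both sides; this removes the
consumption that happens during the refill interval from the apparent jump
and averages the reading noise over the fit windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.signal import medfilt
from sklearn.isotonic import IsotonicRegression

from .types import BatchConfig, DensityState, LevelSeries, RefillEvent, SiloSpec

__all__ = [
    "CleaningConfig",
    "WeightSeries",
    "ConsumptionSeries",
    "level_to_volume",
    "volume_to_weight",
    "detect_refills",
    "estimate_density",
    "blend_density",
    "clean_series",
    "compute_consumption",
    "run_silo_pipeline",
    "SiloPipelineResult",
]

log = logging.getLogger("silogrowth.silo")


class CleaningConfig(BaseModel):
    """Tunables of the cleaning stage.

    ``window`` is the centered moving-average width in readings (default 13
    ≈ one day at the 2-hour cadence); ``refill_threshold`` is the minimum
    cumulative volume gain (m³) for an increase run to count as a refill;
    gaps of up to ``max_gap_interpolate`` consecutive missing readings are
    linearly interpolated.  ``despike_window`` is the odd median-filter
    kernel applied to the volume series before refill detection (1 disables);
    ``density_fit_points`` bounds the trend-fit windows around a refill.
    """

    window: int = 13
    refill_threshold: float = Field(default=1.0, gt=0, description="m³")
    max_gap_interpolate: int = Field(default=6, ge=0)
    despike_window: int = 5
    density_fit_points: int = Field(default=36, ge=4)
    refill_match_tolerance: timedelta = timedelta(hours=6)

    @model_validator(mode="after")
    def _check(self) -> "CleaningConfig":
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.despike_window < 1 or self.despike_window % 2 == 0:
            raise ValueError("despike_window must be odd and >= 1")
        return self


@dataclass
class WeightSeries:
    """Feed weight (kg) per reading timestamp, segmented by refills."""

    timestamps: np.ndarray  # datetime64[ns]
    weight: np.ndarray  # kg; NaN where the reading is missing
    segment_id: np.ndarray  # int, non-decreasing

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.weight = np.asarray(self.weight, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        if np.any(np.diff(self.segment_id) < 0):
            raise ValueError("segment_id must be non-decreasing")
        w = self.weight[~np.isnan(self.weight)]
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.weight)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "weight_kg": self.weight, "segment_id": self.segment_id}
        )


@dataclass
class ConsumptionSeries:
    """Per-interval consumed feed (kg ≥ 0), stamped at the interval end."""

    interval_start: np.ndarray
    interval_end: np.ndarray
    consumed: np.ndarray
    #: intervals longer than this are attributed to the day of their end
    max_regular_interval: timedelta = timedelta(hours=14)

    def __post_init__(self) -> None:
        self.interval_start = np.asarray(self.interval_start, dtype="datetime64[ns]")
        self.interval_end = np.asarray(self.interval_end, dtype="datetime64[ns]")
        self.consumed = np.asarray(self.consumed, dtype=float)
        if np.any(self.consumed < -1e-9):
            raise ValueError("per-interval consumption must be non-negative")
        self.consumed = np.clip(self.consumed, 0.0, None)

    def total(self) -> float:
        return float(self.consumed.sum())

    def daily(self) -> pd.Series:
        """Aggregate to kg per calendar day.

        Regular intervals are attributed to the day of their midpoint; an
        interval spanning a long gap is attributed to the day of its end.
        """
        if len(self.consumed) == 0:
            return pd.Series(dtype=float)
        start = pd.DatetimeIndex(self.interval_start)
        end = pd.DatetimeIndex(self.interval_end)
        span = end - start
        mid = start + span / 2
        day = np.where(span <= self.max_regular_interval, mid.date, end.date)
        s = pd.Series(self.consumed).groupby(day).sum()
        s.index.name = "date"
        return s


# ---------------------------------------------------------------------------
# level → volume → weight


def level_to_volume(level_fraction, silo: SiloSpec):
    """Occupied volume (m³) at a level fraction; vectorised, NaN passes through."""
    frac = np.asarray(level_fraction, dtype=float)
    ok = ~np.isnan(frac)
    if np.any((frac[ok] < 0) | (frac[ok] > 1)):
        raise ValueError("level_fraction must be within [0, 1]")
    if silo.geometry == "linear":
        vol = frac * silo.usable_volume
    else:
        h = frac * silo.total_height
        vol = np.array([silo.volume_at_height(x) if np.isfinite(x) else np.nan for x in np.atleast_1d(h)])
        if np.isscalar(level_fraction) or np.ndim(level_fraction) == 0:
            return float(vol[0])
        return vol
    if np.isscalar(level_fraction) or np.ndim(level_fraction) == 0:
        return float(vol)
    return vol


def volume_to_weight(volume, density: float):
    """kg = m³ × kg/m³."""
    if density <= 0:
        raise ValueError("density must be positive")
    vol = np.asarray(volume, dtype=float)
    if np.any(vol[~np.isnan(vol)] < 0):
        raise ValueError("volume must be non-negative")
    out = vol * density
    if np.isscalar(volume) or np.ndim(volume) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# refill detection


def _increase_runs(volumes: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive increases.

    Returns (i, j, gain) per run where readings i..j each exceed their
    predecessor and gain = volumes[j] - volumes[i-1].
    """
    runs: list[tuple[int, int, float]] = []
    n = len(volumes)
    i = 1
    while i < n:
        if volumes[i] > volumes[i - 1]:
            j = i
            while j + 1 < n and volumes[j + 1] > volumes[j]:
                j += 1
            runs.append((i, j, float(volumes[j] - volumes[i - 1])))
            i = j + 1
        else:
            i += 1
    return runs


def _despike(volumes: np.ndarray, kernel: int) -> np.ndarray:
    if kernel <= 1 or len(volumes) < kernel:
        return volumes
    return medfilt(volumes, kernel_size=kernel)


def _pin_runs(
    volumes: np.ndarray, runs: list[tuple[int, int, float]], halo: int
) -> list[tuple[int, int, float]]:
    """Pin each run to the largest single-interval raw increase near it.

    The median despike can shift a jump's apparent position by up to half a
    kernel; the raw reading-to-reading increase at the true refill dwarfs
    the noise, so the argmax restores the exact boundary.
    """
    pinned: dict[int, tuple[int, int, float]] = {}
    n = len(volumes)
    for i, j, _gain in runs:
        lo = max(1, i - halo)
        hi = min(n - 1, j + halo)
        diffs = volumes[lo : hi + 1] - volumes[lo - 1 : hi]
        k = int(lo + np.argmax(diffs))
        # gain: cumulative raw increase over the maximal raw run containing k
        ii = k
        while ii - 1 >= 1 and volumes[ii - 1] > volumes[ii - 2]:
            ii -= 1
        jj = k
        while jj + 1 < n and volumes[jj + 1] > volumes[jj]:
            jj += 1
        pinned[k] = (k, k, float(volumes[jj] - volumes[ii - 1]))
    return [pinned[k] for k in sorted(pinned)]


def detect_refills(
    series: LevelSeries, silo: SiloSpec, cfg: CleaningConfig
) -> list[RefillEvent]:
    """Detect feed deliveries as upward jumps in the (despiked) volume series.

    One event is emitted per maximal run of consecutive increases whose
    cumulative volume gain reaches ``cfg.refill_threshold``; smaller
    increases are left to the smoother as surface noise.  The event
    timestamp is the first increased reading of the run.
    """
    if len(series) == 0:
        raise ValueError("series must be non-empty")
    ts, frac = series.arrays()
    valid = ~np.isnan(frac)
    vol = level_to_volume(frac[valid], silo)
    tsv = ts[valid]
    events = []
    for i, j, gain in _detect_refill_indices(np.asarray(vol, dtype=float), cfg):
        events.append(
            RefillEvent(
                timestamp=pd.Timestamp(tsv[i]).to_pydatetime(),
                detected_volume_delta=gain,
            )
        )
    return events


def _detect_refill_indices(
    vol_valid: np.ndarray, cfg: CleaningConfig
) -> list[tuple[int, int, float]]:
    """Detected refills as pinned single-reading jumps (valid-index space)."""
    filt = _despike(vol_valid, cfg.despike_window)
    runs = [r for r in _increase_runs(filt) if r[2] >= cfg.refill_threshold]
    halo = cfg.despike_window // 2 + 1
    return _pin_runs(vol_valid, runs, halo)


# ---------------------------------------------------------------------------
# refill delta refinement and density estimation


def _local_trend_fit(
    t_hours: np.ndarray, y: np.ndarray, knots: np.ndarray, t_evals: Sequence[float]
) -> np.ndarray:
    """Local volume-trend fit, evaluated at ``t_evals``.

    Two nested candidates are fitted by least squares: a straight line, and
    a continuous piecewise-linear spline with knots at the window's UTC
    midnights (feed rationing changes at the daily granularity, so the true
    depletion trend is a daily-knot spline).  The spline's per-day slopes
    rest on few points each, so its extrapolation variance under reading
    noise is large; the day-to-day ration drift, on the other hand, is tiny
    compared to any measurable noise.  The spline is therefore kept only
    when it explains the window essentially exactly (residuals at numerical
    precision, the noise-free regime); otherwise the straight line is used.
    """

    def fit(kn: np.ndarray) -> tuple[np.ndarray, float, int]:
        cols = [np.ones_like(t_hours), t_hours]
        for k in kn:
            cols.append(np.clip(t_hours - k, 0.0, None))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return beta, rss, X.shape[1]

    beta_l, rss_l, p_l = fit(np.array([]))
    chosen_knots = np.array([])
    beta = beta_l
    if len(knots) > 0 and len(t_hours) > p_l + len(knots):
        beta_s, rss_s, _ = fit(knots)
        if rss_s < 1e-9 * rss_l:
            chosen_knots, beta = knots, beta_s
    out = []
    for t_eval in t_evals:
        row = [1.0, t_eval] + [max(t_eval - k, 0.0) for k in chosen_knots]
        out.append(float(np.asarray(row) @ beta))
    return np.asarray(out)


def _midnight_knots(ts: pd.DatetimeIndex, t0: pd.Timestamp) -> np.ndarray:
    """Hours (relative to t0) of the UTC midnights strictly inside ts' span."""
    lo, hi = ts.min(), ts.max()
    days = pd.date_range(lo.ceil("D"), hi.floor("D"), freq="D")
    days = days[(days > lo) & (days < hi)]
    return np.array([(d - t0).total_seconds() / 3600.0 for d in days])


@dataclass
class _RefillFit:
    """Trend-fit quantities around one refill run."""

    delta: float  # m³ added
    v_pre: float  # m³ remaining just before the refill
    pre_end_eval: Optional[float]  # fitted volume at the last pre-refill reading
    post_start_eval: Optional[float]  # fitted volume at the first post-refill reading


def _refine_refill(
    tsv: pd.DatetimeIndex,
    vol: np.ndarray,
    run: tuple[int, int, float],
    lo: int,
    hi: int,
    cfg: CleaningConfig,
) -> _RefillFit:
    """Re-estimate a refill's volume jump from local trend fits on both sides.

    ``lo``/``hi`` bound the usable index range (previous/next refill).  The
    pre-side fit (with a one-reading guard band against detection jitter)
    is extrapolated to the refill reading's time; the post-side fit is
    evaluated there directly; the jump is their difference, free of the
    consumption that happened during the refill interval.  Falls back to
    the raw run gain when a side has too few points for a fit.
    """
    i, j, gain = run
    t0 = tsv[0]

    def hours(idx: np.ndarray) -> np.ndarray:
        return np.array([(tsv[k] - t0).total_seconds() / 3600.0 for k in idx])

    t_star = (tsv[i] - t0).total_seconds() / 3600.0
    t_last_pre = (tsv[i - 1] - t0).total_seconds() / 3600.0 if i >= 1 else t_star
    # guard band of one reading on the pre side against detection jitter
    pre_idx = np.arange(max(lo, i - 1 - cfg.density_fit_points), max(lo, i - 1))
    post_idx = np.arange(min(hi, j), min(hi, j + cfg.density_fit_points))
    if len(pre_idx) < 4 or len(post_idx) < 4:
        pre_vol = float(vol[i - 1]) if i >= 1 else float("nan")
        return _RefillFit(delta=gain, v_pre=pre_vol, pre_end_eval=None, post_start_eval=None)
    pre_vals = _local_trend_fit(
        hours(pre_idx), vol[pre_idx], _midnight_knots(tsv[pre_idx], t0), [t_star, t_last_pre]
    )
    post_vals = _local_trend_fit(
        hours(post_idx), vol[post_idx], _midnight_knots(tsv[post_idx], t0), [t_star]
    )
    delta = float(post_vals[0] - pre_vals[0])
    if delta <= 0:  # pathological noise; fall back to the raw gain
        return _RefillFit(delta=gain, v_pre=float(pre_vals[0]), pre_end_eval=None, post_start_eval=None)
    return _RefillFit(
        delta=delta,
        v_pre=float(pre_vals[0]),
        pre_end_eval=float(pre_vals[1]),
        post_start_eval=float(post_vals[0]),
    )


def estimate_density(event: RefillEvent, density: DensityState) -> float:
    """Density (kg/m³) of one truckload.

    With a declared weight the density is calibrated as declared weight over
    detected volume gain; otherwise the configured default is assumed.
    """
    if event.declared_weight is not None:
        if event.detected_volume_delta is None or event.detected_volume_delta <= 0:
            raise ValueError(
                f"cannot calibrate density for refill at {event.timestamp}: "
                "no positive detected volume delta"
            )
        return event.declared_weight / event.detected_volume_delta
    return density.default_density


def blend_density(
    remaining_mass: float, remaining_density: float, load_mass: float, load_density: float
) -> float:
    """Density of residual feed mixed with a new truckload.

    Both mass and volume are conserved in the silo, so the mixture density
    is total mass over total volume (a mass-weighted *harmonic* mean of the
    two densities); an arithmetic mean would break mass balance against the
    level sensor, which measures volume.
    """
    total = remaining_mass + load_mass
    if total <= 0:
        return load_density
    return total / (remaining_mass / remaining_density + load_mass / load_density)


# ---------------------------------------------------------------------------
# cleaning


def _interpolate_short_gaps(
    t_hours: np.ndarray, y: np.ndarray, max_gap: int
) -> np.ndarray:
    """Linearly interpolate NaN runs of length ≤ max_gap (in readings), on time."""
    y = y.copy()
    isnan = np.isnan(y)
    if not isnan.any():
        return y
    n = len(y)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j + 1 < n and isnan[j + 1]:
                j += 1
            if i > 0 and j < n - 1 and (j - i + 1) <= max_gap:
                y[i : j + 1] = np.interp(t_hours[i : j + 1], [t_hours[i - 1], t_hours[j + 1]], [y[i - 1], y[j + 1]])
            i = j + 1
        else:
            i += 1
    return y


def _centered_ma(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window truncated symmetrically at the edges."""
    n = len(y)
    half = window // 2
    out = np.empty(n)
    c = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (c[i + k + 1] - c[i - k]) / (2 * k + 1)
    return out


def _pav_antitonic(y: np.ndarray) -> np.ndarray:
    """Project onto the non-increasing cone (pool-adjacent-violators)."""
    if len(y) <= 1:
        return y.copy()
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(np.arange(len(y)), y)


def clean_series(series: WeightSeries, cfg: CleaningConfig) -> WeightSeries:
    """Interpolate short gaps, smooth, and enforce monotone depletion per segment.

    Within each segment independently (never across a refill): gaps of up to
    ``max_gap_interpolate`` missing readings are filled by linear
    interpolation on time; a centered moving average of width ``window``
    (truncated symmetrically at segment edges) removes surface noise; the
    pool-adjacent-violators projection in the antitonic direction restores
    the physical non-increasing shape.  Readings in longer gaps are dropped
    from the output.  Segments shorter than 2 readings pass through
    unchanged with a logged warning.
    """
    ts_all = pd.DatetimeIndex(series.timestamps)
    t0 = ts_all[0] if len(ts_all) else pd.Timestamp(0)
    th_all = np.array([(t - t0).total_seconds() / 3600.0 for t in ts_all])
    out_ts, out_w, out_seg = [], [], []
    for seg in np.unique(series.segment_id):
        m = series.segment_id == seg
        y = series.weight[m].copy()
        th = th_all[m]
        ts = series.timestamps[m]
        if (~np.isnan(y)).sum() < 2:
            log.warning("segment %d has fewer than 2 readings; passed through unchanged", seg)
            keep = ~np.isnan(y)
            out_ts.append(ts[keep]); out_w.append(y[keep]); out_seg.append(np.full(keep.sum(), seg))
            continue
        y = _interpolate_short_gaps(th, y, cfg.max_gap_interpolate)
        keep = ~np.isnan(y)
        y, th, ts = y[keep], th[keep], ts[keep]
        y = _centered_ma(y, cfg.window)
        y = _pav_antitonic(y)
        y = np.clip(y, 0.0, None)
        out_ts.append(ts); out_w.append(y); out_seg.append(np.full(len(y), seg))
    return WeightSeries(
        timestamps=np.concatenate(out_ts) if out_ts else np.array([], dtype="datetime64[ns]"),
        weight=np.concatenate(out_w) if out_w else np.array([]),
        segment_id=np.concatenate(out_seg) if out_seg else np.array([], dtype=int),
    )


# ---------------------------------------------------------------------------
# consumption


def compute_consumption(
    cleaned: WeightSeries, refill_weights: Optional[dict[int, float]] = None
) -> ConsumptionSeries:
    """Per-interval consumption from a cleaned, segment-monotone weight series.

    Within a segment the consumption of an interval is the drop between
    consecutive cleaned weights.  Across a refill boundary into segment s,
    the interval contributes ``max(0, pre - (post - refill_weights[s]))``
    (mass balance across the delivery); a negative value is floored at 0
    with a warning, as it means the sensor error exceeded the consumption.
    """
    refill_weights = refill_weights or {}
    n = len(cleaned)
    starts, ends, cons = [], [], []
    for a, b in zip(range(n - 1), range(1, n)):
        w0, w1 = cleaned.weight[a], cleaned.weight[b]
        s0, s1 = cleaned.segment_id[a], cleaned.segment_id[b]
        if s0 == s1:
            c = w0 - w1
            if c < -1e-9:
                raise RuntimeError(
                    "negative within-segment consumption after cleaning "
                    f"at {cleaned.timestamps[b]} (internal invariant violation)"
                )
            c = max(c, 0.0)
        else:
            refill_kg = refill_weights.get(int(s1), 0.0)
            c = w0 - (w1 - refill_kg)
            if c < 0:
                log.warning(
                    "negative consumption across refill boundary at %s (%.1f kg); floored at 0",
                    cleaned.timestamps[b], c,
                )
                c = 0.0
        starts.append(cleaned.timestamps[a])
        ends.append(cleaned.timestamps[b])
        cons.append(c)
    return ConsumptionSeries(
        interval_start=np.array(starts, dtype="datetime64[ns]"),
        interval_end=np.array(ends, dtype="datetime64[ns]"),
        consumed=np.array(cons, dtype=float),
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SiloPipelineResult:
    """Everything the silo stage derives from one level series."""

    refills: list[RefillEvent]  # detected events, declared weights attached
    load_densities: list[float]  # per-load density estimate, kg/m³
    segment_densities: list[float]  # blended per-segment density, kg/m³
    refill_weights: dict[int, float]  # kg added at the boundary into each segment
    raw_weights: WeightSeries
    cleaned: WeightSeries
    consumption: ConsumptionSeries
    initial_weight: Optional[float] = None  # declared opening content, kg
    undeclared_refills: list[RefillEvent] = field(default_factory=list)


def _match_declared(
    detected_ts: list[pd.Timestamp],
    declared: list[RefillEvent],
    tol: timedelta,
) -> dict[int, RefillEvent]:
    """Greedy nearest-in-time 1:1 matching of declared refills to detections."""
    pairs = []
    for di, dts in enumerate(detected_ts):
        for dec in declared:
            dt = abs(pd.Timestamp(dec.timestamp) - dts)
            if dt <= tol:
                pairs.append((dt, di, dec))
    pairs.sort(key=lambda p: p[0])
    matched: dict[int, RefillEvent] = {}
    used: set[int] = set()
    for _, di, dec in pairs:
        if di in matched or id(dec) in used:
            continue
        matched[di] = dec
        used.add(id(dec))
    return matched


def run_silo_pipeline(
    series: LevelSeries,
    config: BatchConfig,
    cfg: Optional[CleaningConfig] = None,
) -> SiloPipelineResult:
    """Full silo stage: detect refills, calibrate densities, clean, differentiate."""
    cfg = cfg or CleaningConfig()
    silo, density_state = config.silo, config.density
    ts, frac = series.arrays()
    valid = ~np.isnan(frac)
    vol_valid = np.asarray(level_to_volume(frac[valid], silo), dtype=float)
    tsv = pd.DatetimeIndex(ts[valid])
    t0 = tsv[0]

    def hours(idx: np.ndarray) -> np.ndarray:
        return np.array([(tsv[k] - t0).total_seconds() / 3600.0 for k in idx])

    runs = _detect_refill_indices(vol_valid, cfg)
    bounds = [0] + [r[0] for r in runs] + [len(vol_valid)]

    # split declared refills into opening-fill declarations and in-series ones
    opening = [r for r in config.refills if pd.Timestamp(r.timestamp) <= tsv[0] + cfg.refill_match_tolerance / 2]
    in_series = [r for r in config.refills if r not in opening]
    matched = _match_declared([tsv[r[0]] for r in runs], in_series, cfg.refill_match_tolerance)

    # opening segment: trend-fitted volume at the first reading anchors both
    # the declared-fill density calibration and the cleaned segment start
    idx0 = np.arange(0, min(cfg.density_fit_points, bounds[1]))
    if len(idx0) >= 4:
        v0 = float(
            _local_trend_fit(hours(idx0), vol_valid[idx0], _midnight_knots(tsv[idx0], t0), [0.0])[0]
        )
    else:
        v0 = float(vol_valid[0])
    initial_weight = None
    rho0 = density_state.default_density
    if opening:
        w0 = sum(r.declared_weight or 0.0 for r in opening)
        if w0 > 0:
            rho0 = w0 / v0
            initial_weight = w0
    overrides = dict(density_state.segment_densities)
    rho0 = overrides.get(0, rho0)

    # closing anchor: trend-fitted volume at the very last reading
    idx_end = np.arange(max(bounds[-2], len(vol_valid) - cfg.density_fit_points), len(vol_valid))
    if len(idx_end) >= 4:
        t_end = (tsv[-1] - t0).total_seconds() / 3600.0
        v_end = float(
            _local_trend_fit(hours(idx_end), vol_valid[idx_end], _midnight_knots(tsv[idx_end], t0), [t_end])[0]
        )
    else:
        v_end = float(vol_valid[-1])

    # walk the segments, refining each refill's jump and blending densities
    refills_out: list[RefillEvent] = []
    undeclared: list[RefillEvent] = []
    load_densities: list[float] = []
    segment_densities: list[float] = [rho0]
    refill_weights: dict[int, float] = {}
    fits: list[_RefillFit] = []
    rho = rho0
    for s, run in enumerate(runs, start=1):
        lo, hi = bounds[s - 1], bounds[s + 1]
        fit = _refine_refill(tsv, vol_valid, run, lo, hi, cfg)
        dec = matched.get(s - 1)
        ev = RefillEvent(
            timestamp=pd.Timestamp(tsv[run[0]]).to_pydatetime(),
            declared_weight=dec.declared_weight if dec else None,
            detected_volume_delta=fit.delta,
        )
        rho_load = estimate_density(ev, density_state)
        load_mass = ev.declared_weight if ev.declared_weight is not None else fit.delta * rho_load
        m_rem = max(fit.v_pre, 0.0) * rho
        rho = blend_density(m_rem, rho, load_mass, rho_load)
        rho = overrides.get(s, rho)
        refills_out.append(ev)
        if ev.declared_weight is None:
            undeclared.append(ev)
        load_densities.append(rho_load)
        segment_densities.append(rho)
        refill_weights[s] = load_mass
        fits.append(fit)

    # segment ids over the full (incl. missing) reading index space
    seg_valid = np.zeros(len(vol_valid), dtype=int)
    for s, run in enumerate(runs, start=1):
        seg_valid[run[0]:] = s
    seg_full = np.zeros(len(ts), dtype=int)
    seg_full[valid] = seg_valid
    # missing readings inherit the previous reading's segment
    last = 0
    for k in range(len(ts)):
        if valid[k]:
            last = seg_full[k]
        else:
            seg_full[k] = last

    weight_full = np.full(len(ts), np.nan)
    rho_per_valid = np.array([segment_densities[s] for s in seg_valid])
    weight_full[valid] = vol_valid * rho_per_valid

    raw = WeightSeries(timestamps=ts, weight=weight_full, segment_id=seg_full)
    cleaned = clean_series(raw, cfg)

    # Re-anchor segment endpoints on the trend fits: the symmetrically
    # truncated moving average leaves segment edges almost unsmoothed, and
    # refill-boundary consumption depends on exactly those points.
    anchors: dict[int, tuple[Optional[float], Optional[float]]] = {}
    n_seg = len(runs) + 1
    for s in range(n_seg):
        start_v = v0 if s == 0 else (fits[s - 1].post_start_eval if s - 1 < len(fits) else None)
        end_v = v_end if s == n_seg - 1 else (fits[s].pre_end_eval if s < len(fits) else None)
        anchors[s] = (start_v, end_v)
    for s in range(n_seg):
        m = cleaned.segment_id == s
        if m.sum() < 2:
            continue
        idx = np.flatnonzero(m)
        start_v, end_v = anchors[s]
        seg_w = cleaned.weight[idx]
        if start_v is not None:
            seg_w[0] = start_v * segment_densities[s]
        if end_v is not None:
            seg_w[-1] = end_v * segment_densities[s]
        cleaned.weight[idx] = np.clip(_pav_antitonic(seg_w), 0.0, None)

    consumption = compute_consumption(cleaned, refill_weights)
    return SiloPipelineResult(
        refills=refills_out,
        load_densities=load_densities,
        segment_densities=segment_densities,
        refill_weights=refill_weights,
        raw_weights=raw,
        cleaned=cleaned,
        consumption=consumption,
        initial_weight=initial_weight,
        undeclared_refills=undeclared,
    )
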