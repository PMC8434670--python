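"""Deviation and data-quality alerting with a pluggable notifier contract.

A *significant* intake deviation is a run of at least ``consecutive_weeks``
weeks whose absolute relative deviation exceeds ``deviation_threshold``.
Before blaming the animals, data accuracy is checked first: if the affected
span contains a refill whose declared weight is missing, a
``verify_refill_data`` alert is raised *instead of* the growth alert for
that span, asking the farmer to complete the refill records.  A
``missing_data`` alert flags weeks where more than a quarter of the
readings never arrived.

Delivery is decoupled behind a ``send(message)`` notifier contract so that
e-mail, push or any other transport can be plugged in; the default notifier
writes to the structured log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Literal, Optional, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .types import RefillEvent, week_index

__all__ = [
    "AlertRuleConfig",
    "Alert",
    "evaluate_alerts",
    "dispatch",
    "DeliveryReport",
    "LoggingNotifier",
    "write_alerts",
]

log = logging.getLogger("silogrowth.alerts")


class AlertRuleConfig(BaseModel):
    """Thresholds of the alerting rules.

    ``basis`` selects whether the deviation fed to the growth rule is
    computed on weekly intake increments (default: reacts within
    ``consecutive_weeks`` of an onset) or on the cumulative curves (slower,
    but smoother).
    """

    deviation_threshold: float = Field(default=0.10, gt=0)
    consecutive_weeks: int = Field(default=2, ge=1)
    data_check_first: bool = True
    basis: Literal["weekly", "cumulative"] = "weekly"
    missing_fraction_threshold: float = Field(default=0.25, gt=0, lt=1)


class Alert(BaseModel):
    kind: Literal["growth_deviation", "verify_refill_data", "missing_data"]
    week: int
    magnitude: float
    message: str


def evaluate_alerts(
    deviation: Sequence[float],
    refills: Sequence[RefillEvent],
    rule: AlertRuleConfig,
    batch_start: Optional[date] = None,
    weekly_missing_fraction: Optional[Sequence[float]] = None,
) -> list[Alert]:
    """Apply the alerting rules to a per-week deviation series.

    One ``growth_deviation`` alert is emitted for the first week of every
    maximal run of at least ``consecutive_weeks`` weeks with
    ``|deviation| > threshold``.  With ``data_check_first`` set, a run whose
    week span contains a refill lacking a declared weight yields a single
    ``verify_refill_data`` alert instead.  ``batch_start`` is required to
    map refill timestamps to weeks when refills are given.
    """
    dev = np.asarray(list(deviation), dtype=float)
    if dev.size == 0:
        raise ValueError("deviation series must be non-empty")
    if refills and batch_start is None:
        raise ValueError("batch_start is required to place refills on the week axis")

    undeclared_weeks = [
        week_index(r.timestamp.date(), batch_start)
        for r in refills
        if r.declared_weight is None
    ]

    alerts: list[Alert] = []
    exceed = np.abs(dev) > rule.deviation_threshold
    i = 0
    n = len(dev)
    while i < n:
        if exceed[i]:
            j = i
            while j + 1 < n and exceed[j + 1]:
                j += 1
            if (j - i + 1) >= rule.consecutive_weeks:
                span_undeclared = [w for w in undeclared_weeks if i <= w <= j]
                if rule.data_check_first and span_undeclared:
                    alerts.append(
                        Alert(
                            kind="verify_refill_data",
                            week=i,
                            magnitude=float(dev[i]),
                            message=(
                                f"Intake deviation of {dev[i]:+.1%} from week {i} coincides with "
                                f"refill(s) without a declared weight in week(s) "
                                f"{sorted(set(span_undeclared))}; please verify the refill records "
                                "before reviewing the animals."
                            ),
                        )
                    )
                else:
                    alerts.append(
                        Alert(
                            kind="growth_deviation",
                            week=i,
                            magnitude=float(dev[i]),
                            message=(
                                f"Sensor-based feed intake deviates {dev[i]:+.1%} from the "
                                f"theoretical curve for {j - i + 1} consecutive weeks starting "
                                f"at week {i}; review the animals."
                            ),
                        )
                    )
            i = j + 1
        else:
            i += 1

    if weekly_missing_fraction is not None:
        for w, fmiss in enumerate(weekly_missing_fraction):
            if fmiss > rule.missing_fraction_threshold:
                alerts.append(
                    Alert(
                        kind="missing_data",
                        week=w,
                        magnitude=float(fmiss),
                        message=f"{fmiss:.0%} of week {w}'s readings are missing.",
                    )
                )
    return alerts


class Notifier(Protocol):
    def send(self, message: str) -> None: ...


class LoggingNotifier:
    """Default notifier: one structured log record per alert."""

    def send(self, message: str) -> None:
        log.warning("ALERT %s", message)


@dataclass
class DeliveryReport:
    delivered: list[Alert] = field(default_factory=list)
    failed: list[tuple[Alert, str]] = field(default_factory=list)

    @property
    def n_delivered(self) -> int:
        return len(self.delivered)

    @property
    def n_failed(self) -> int:
        return len(self.failed)


def dispatch(alerts: Sequence[Alert], notifier: Optional[Notifier] = None) -> DeliveryReport:
    """Deliver each alert exactly once; failures are recorded, never raised."""
    notifier = notifier or LoggingNotifier()
    report = DeliveryReport()
    for alert in alerts:
        try:
            notifier.send(alert.message)
        except Exception as exc:  # noqa: BLE001 - delivery must not abort the batch
            log.error("alert delivery failed (week %d, %s): %s", alert.week, alert.kind, exc)
            report.failed.append((alert, str(exc)))
        else:
            report.delivered.append(alert)
    return report


def write_alerts(alerts: Sequence[Alert], path: Path | str) -> None:
    Path(path).write_text(
        json.dumps([a.model_dump() for a in alerts], indent=2) + "\n", encoding="utf-8"
    )
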