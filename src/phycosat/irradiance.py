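"""Minute-resolution PAR traces → condensed series, day length, H_sat.

The light logger records irradiance every minute from before sunrise (05:00)
to after sundown (19:30).  Two reductions are made from the trace:

* **Day length** uses a *condensed* series — a trailing 10-min moving average
  kept only at clock minutes :00, :10, :20, :30, :40, :50 — and counts the
  grid samples at or above 1 μmol photons m⁻² s⁻¹, 10 minutes each.
* **H_sat**, the daily time in saturating irradiance, counts raw per-minute
  samples at or above the plant's saturation irradiance E_k.

Because each plant is measured on days 1, 5 and 9 only, its E_k is mapped to
the nine experiment days by period: P1 = days 1–3 use the D1 value,
P2 = days 4–5 the D5 value, P3 = days 6–9 the D9 value.  A ``no_d5`` variant
(for runs where the D5 measurement was not taken) uses D1 for days 1–4 and
D9 for days 5–9.  The per-plant summary is the mean over the three period
means (equal period weights); a plain mean over all days is available as an
alternative mode.  rel-H_sat normalizes each day's H_sat by that day's day
length and averages the per-day percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IrradianceSeries",
    "CondensedSeries",
    "SaturationResult",
    "condense_series",
    "day_length",
    "assign_period_ek",
    "period_of_day",
    "hsat_day",
    "mean_hsat",
    "rel_hsat",
    "PERIOD_SCHEMES",
]

#: Logging window, minutes since midnight: 05:00 to 19:30 inclusive.
LOG_START, LOG_END = 5 * 60, 19 * 60 + 30

#: Day-length irradiance threshold, μmol photons m⁻² s⁻¹.
DAYLIGHT_THRESHOLD = 1.0

#: day index -> RLC day label, per scheme.
PERIOD_SCHEMES: dict[str, dict[int, str]] = {
    "standard": {1: "D1", 2: "D1", 3: "D1", 4: "D5", 5: "D5",
                 6: "D9", 7: "D9", 8: "D9", 9: "D9"},
    "no_d5": {1: "D1", 2: "D1", 3: "D1", 4: "D1", 5: "D9",
              6: "D9", 7: "D9", 8: "D9", 9: "D9"},
}


@dataclass
class IrradianceSeries:
    """Per-minute PAR trace for one calendar day.

    ``minutes`` are integer minutes since local midnight, strictly
    increasing; ``e_par`` the matching irradiances (≥ 0).
    """

    date: str
    minutes: np.ndarray
    e_par: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.e_par = np.asarray(self.e_par, dtype=float)
        if self.minutes.shape != self.e_par.shape:
            raise ValueError("minutes and e_par must have equal length")
        if len(self.minutes) and np.any(np.diff(self.minutes) <= 0):
            raise ValueError(f"minutes must be strictly increasing ({self.date})")
        if len(self.e_par) and np.any(self.e_par < 0):
            raise ValueError("e_par must be >= 0")

    def __len__(self) -> int:
        return len(self.minutes)


@dataclass
class CondensedSeries:
    """10-min-grid summary of a day's trace (trailing moving average)."""

    date: str
    minutes: np.ndarray
    e_par: np.ndarray

    def __len__(self) -> int:
        return len(self.minutes)


@dataclass
class SaturationResult:
    """Per-plant saturation summary over the nine experiment days."""

    plant_id: str
    h_sat: dict[int, float]  # day index -> minutes
    ek_used: dict[int, float]  # day index -> E_k applied
    day_lengths: dict[int, float]  # day index -> minutes
    period_scheme: str
    mean_h_sat: float
    rel_h_sat: float  # percent
    day_windows: dict[int, tuple[int, int]] = field(default_factory=dict)


def condense_series(series: IrradianceSeries, window: int = 10) -> CondensedSeries:
    """Trailing moving average sampled at the six 10-min grid minutes per hour.

    The average at labelled minute *m* covers the up-to-``window`` samples
    ending at *m*; at the start of the series a shorter window uses whatever
    samples exist.
    """
    if len(series) == 0:
        return CondensedSeries(series.date, np.array([], int), np.array([], float))
    s = pd.Series(series.e_par, index=series.minutes)
    avg = s.rolling(window, min_periods=1).mean()
    on_grid = series.minutes % 10 == 0
    return CondensedSeries(
        series.date, series.minutes[on_grid], avg.to_numpy()[on_grid]
    )


def day_length(condensed: CondensedSeries, threshold: float = DAYLIGHT_THRESHOLD) -> float:
    """Daylight minutes: grid samples at/above ``threshold``, 10 min each."""
    return 10.0 * int(np.sum(condensed.e_par >= threshold))


def period_of_day(day_index: int, scheme: str = "standard") -> str:
    """RLC day label (D1/D5/D9) whose E_k applies to experiment day ``day_index``."""
    try:
        mapping = PERIOD_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown period scheme {scheme!r}; expected one of {sorted(PERIOD_SCHEMES)}"
        ) from None
    if day_index not in mapping:
        raise ValueError(f"day_index must be in 1..9, got {day_index}")
    return mapping[day_index]


def assign_period_ek(day_index: int, fits: dict, scheme: str = "standard") -> float:
    """E_k to compare with irradiance on experiment day ``day_index``.

    ``fits`` maps day labels to either fitted-curve objects with an ``ek``
    attribute or plain numbers.
    """
    label = period_of_day(day_index, scheme)
    if label not in fits or fits[label] is None:
        raise ValueError(
            f"period scheme {scheme!r} needs an E_k for {label} "
            f"(day {day_index}), but none is available"
        )
    fit = fits[label]
    return float(getattr(fit, "ek", fit))


def hsat_day(
    series: IrradianceSeries,
    ek: float,
    window: tuple[int, int] | None = None,
) -> float:
    """Minutes of the day spent at saturating irradiance (E_par ≥ E_k).

    Counted on the raw 1-min trace.  ``window`` is an optional clock
    interval ``(start_minute, end_minute)``, inclusive, used to truncate the
    first and last experiment days to the plant's RLC times; a window
    extending beyond the logged span is clipped with a warning.
    """
    if ek <= 0:
        raise ValueError(f"ek must be > 0, got {ek}")
    minutes, e = series.minutes, series.e_par
    if window is not None:
        lo, hi = window
        if len(minutes) and (lo < minutes[0] or hi > minutes[-1]):
            warnings.warn(
                f"window [{lo}, {hi}] extends beyond logged span "
                f"[{minutes[0]}, {minutes[-1]}] on {series.date}; clipping",
                stacklevel=2,
            )
        keep = (minutes >= lo) & (minutes <= hi)
        e = e[keep]
    return float(np.sum(e >= ek))


def mean_hsat(
    daily: dict[int, float],
    scheme: str = "standard",
    mode: str = "period_means",
) -> float:
    """Summary H_sat over the experiment days.

    ``period_means`` (default): average the per-period means with equal
    period weights, so the 3-, 2- and 4-day periods count equally.
    ``all_days``: plain mean over every day present.
    """
    if not daily:
        raise ValueError("no daily h_sat values")
    if mode == "all_days":
        return float(np.mean(list(daily.values())))
    if mode != "period_means":
        raise ValueError(f"unknown hsat mean mode {mode!r}")
    groups: dict[str, list[float]] = {}
    for day, h in daily.items():
        groups.setdefault(period_of_day(day, scheme), []).append(h)
    return float(np.mean([np.mean(v) for v in groups.values()]))


def rel_hsat(daily_hsat: dict[int, float], daily_day_length: dict[int, float]) -> float:
    """Mean over days of 100 · H_sat(day) / day_length(day), percent.

    Days with zero day length are excluded with a warning.
    """
    ratios = []
    for day, h in daily_hsat.items():
        dl = daily_day_length.get(day)
        if dl is None:
            raise ValueError(f"no day length for day {day}")
        if dl <= 0:
            warnings.warn(f"day {day} has zero day length; excluded from rel-H_sat",
                          stacklevel=2)
            continue
        ratios.append(100.0 * h / dl)
    if not ratios:
        raise ValueError("no days with positive day length")
    return float(np.mean(ratios))
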