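"""Production indices: the diurnal saturated photosynthesis index and growth.

DSPI treats a plant as running photosynthesis at its maximum rate P_max for
exactly the minutes it spends in saturating irradiance (H_sat) each day:

    daily DSPI = P_max(period of day) · 60 · H_sat(day) · 10⁻⁶   [mol m⁻²]

(P_max is per second, H_sat in minutes, hence the 60; 10⁻⁶ converts μmol to
mol).  Daily values are averaged into the final index.  No respiration or
other non-irradiance loss enters — this is deliberately an irradiance-only
ceiling on gross production.

Nine-day growth is the plain relative wet-weight change, with an optional
deduction of parasite biomass picked off the plant at final weighing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .irradiance import period_of_day

__all__ = ["DSPIResult", "GrowthResult", "dspi", "growth_percent"]

#: seconds-per-minute × μmol→mol
_DSPI_UNIT = 60.0 * 1e-6


@dataclass
class DSPIResult:
    plant_id: str
    daily_dspi: dict[int, float]  # day index -> mol m⁻²
    dspi: float  # final averaged index, mol m⁻²


@dataclass
class GrowthResult:
    plant_id: str
    w_i: float
    w_f: float
    parasite_mass: float
    growth_pct: float


def dspi(
    pmax_by_period: dict,
    daily_hsat: dict[int, float],
    scheme: str = "standard",
    mode: str = "daily",
    plant_id: str = "",
) -> DSPIResult:
    """Diurnal saturated photosynthesis index for one plant.

    Parameters
    ----------
    pmax_by_period
        Maps day labels D1/D5/D9 to P_max (μmol electrons m⁻² s⁻¹), or to
        fitted-curve objects with a ``pmax`` attribute.
    daily_hsat
        Day index (1..9) -> H_sat minutes.
    scheme
        Period scheme mapping experiment days to D1/D5/D9 (see
        :mod:`phycosat.irradiance`).
    mode
        ``daily`` (default): final index is the mean of the daily values.
        ``period_means``: mean of per-period means, mirroring the H_sat
        averaging switch.
    """
    daily: dict[int, float] = {}
    for day, h in daily_hsat.items():
        if h < 0:
            raise ValueError(f"h_sat must be >= 0 (day {day})")
        label = period_of_day(day, scheme)
        if label not in pmax_by_period:
            raise ValueError(f"no P_max for period day {label}")
        p = pmax_by_period[label]
        p = float(getattr(p, "pmax", p))
        if p < 0:
            raise ValueError(f"pmax must be >= 0, got {p}")
        daily[day] = p * h * _DSPI_UNIT
    if not daily:
        raise ValueError("no daily h_sat values")
    if mode == "daily":
        final = float(np.mean(list(daily.values())))
    elif mode == "period_means":
        groups: dict[str, list[float]] = {}
        for day, v in daily.items():
            groups.setdefault(period_of_day(day, scheme), []).append(v)
        final = float(np.mean([np.mean(v) for v in groups.values()]))
    else:
        raise ValueError(f"unknown dspi mean mode {mode!r}")
    return DSPIResult(plant_id=plant_id, daily_dspi=daily, dspi=final)


def growth_percent(w_i: float, w_f: float, parasite_mass: float = 0.0) -> float:
    """Nine-day growth, percent: 100 · ((w_f − parasite) − w_i) / w_i.

    ``parasite_mass`` is biomass of an epiphytic parasite removed at final
    weighing and deducted from the plant's final weight.
    """
    if w_i <= 0:
        raise ValueError(f"initial weight must be > 0, got {w_i}")
    if parasite_mass < 0:
        raise ValueError("parasite_mass must be >= 0")
    if parasite_mass >= w_f:
        raise ValueError(
            f"parasite_mass {parasite_mass} not smaller than final weight {w_f}"
        )
    return 100.0 * ((w_f - parasite_mass) - w_i) / w_i
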