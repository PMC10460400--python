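"""CSV readers and writers for the three instrument-style input families.

Canonical dialects (UTF-8, header row, ISO 8601 local timestamps):

* RLC export, one row per actinic step:
  ``plant_id, species, day_label, timestamp, rlc_order, step_index, e_par, phi_psii``
* Light-logger trace, one row per minute:
  ``timestamp, e_par`` (timestamp ``YYYY-MM-DD HH:MM`` or ISO 8601)
* Plant metadata, one row per replicate:
  the design columns plus wet weights ``w_i, w_f, parasite_mass``.

Malformed RLC rows are collected into a rejects frame rather than silently
dropped; logger gaps and duplicated minutes are reported.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .irradiance import IrradianceSeries
from .rlc import RapidLightCurve, RLCStep

__all__ = [
    "read_rlc_csv",
    "write_rlc_csv",
    "read_licor_csv",
    "write_licor_csv",
    "read_metadata_csv",
    "write_metadata_csv",
]

RLC_REQUIRED = ["plant_id", "day_label", "timestamp", "rlc_order",
                "step_index", "e_par", "phi_psii"]


def read_rlc_csv(path) -> tuple[list[RapidLightCurve], pd.DataFrame]:
    """Parse an RLC export into curves grouped by (plant, day).

    Returns ``(curves, rejects)`` where ``rejects`` holds the malformed rows
    with a ``reject_reason`` column.  A missing required column is a format
    error; a duplicated (plant, day, step) triple is a data error.  Steps
    stored out of irradiance order are sorted with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in RLC_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"RLC file {path} is missing required columns: {missing}")

    bad = pd.Series(False, index=df.index)
    reason = pd.Series("", index=df.index)
    for col in ("e_par", "phi_psii", "step_index", "rlc_order"):
        vals = pd.to_numeric(df[col], errors="coerce")
        newly = vals.isna() & ~bad
        reason[newly] = f"missing or non-numeric {col}"
        bad |= vals.isna()
        df[col] = vals
    out_of_range = (~bad) & ((df["phi_psii"] < 0) | (df["phi_psii"] > 1) | (df["e_par"] < 0))
    reason[out_of_range] = "value out of range"
    bad |= out_of_range
    rejects = df[bad].copy()
    rejects["reject_reason"] = reason[bad]
    good = df[~bad]

    dup = good.duplicated(subset=["plant_id", "day_label", "step_index"], keep=False)
    if dup.any():
        offender = good[dup].iloc[0]
        raise ValueError(
            "duplicate RLC step for plant "
            f"{offender['plant_id']!r} {offender['day_label']} "
            f"step {int(offender['step_index'])}"
        )

    curves = []
    for (plant, day), sub in good.groupby(["plant_id", "day_label"], sort=True):
        sub = sub.sort_values("step_index")
        steps = [
            RLCStep(float(r.e_par), float(r.phi_psii), int(r.step_index))
            for r in sub.itertuples(index=False)
        ]
        curves.append(
            RapidLightCurve(
                plant_id=str(plant),
                day_label=str(day),
                timestamp=str(sub["timestamp"].iloc[0]),
                steps=steps,
                rlc_order=int(sub["rlc_order"].iloc[0]),
            )
        )
    return curves, rejects


def write_rlc_csv(curves, path) -> None:
    rows = []
    for c in curves:
        species = getattr(c, "species", "")
        for s in c.steps:
            rows.append(
                {
                    "plant_id": c.plant_id,
                    "species": species,
                    "day_label": c.day_label,
                    "timestamp": c.timestamp,
                    "rlc_order": c.rlc_order,
                    "step_index": s.step_index,
                    "e_par": s.e_par,
                    "phi_psii": s.phi_psii,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_logger_timestamps(ts: pd.Series) -> tuple[pd.Series, pd.Series]:
    t = pd.to_datetime(ts, format="mixed")
    date = t.dt.strftime("%Y-%m-%d")
    minutes = t.dt.hour * 60 + t.dt.minute
    return date, minutes


def read_licor_csv(paths) -> tuple[dict[str, IrradianceSeries], pd.DataFrame]:
    """Parse one or more logger files into per-day series.

    Multiple files spanning the same day are merged.  Duplicated minutes are
    averaged with a warning; non-monotone raw timestamps within one file and
    day are a data error.  Returns ``(series_by_date, gap_report)`` where
    the gap report lists missing intervals inside each day's logged span.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        df = pd.read_csv(path)
        if not {"timestamp", "e_par"} <= set(df.columns):
            raise ValueError(f"logger file {path} needs columns timestamp, e_par")
        date, minutes = _parse_logger_timestamps(df["timestamp"])
        part = pd.DataFrame(
            {"date": date, "minute": minutes, "e_par": df["e_par"].astype(float)}
        )
        for day, sub in part.groupby("date"):
            m = sub["minute"].to_numpy()
            if np.any(np.diff(m) < 0):
                raise ValueError(f"non-monotone timestamps in {path} on {day}")
        frames.append(part)
    allrows = pd.concat(frames, ignore_index=True)

    series: dict[str, IrradianceSeries] = {}
    gaps = []
    for day, sub in allrows.groupby("date"):
        if sub["minute"].duplicated().any():
            warnings.warn(f"duplicated minutes on {day}; averaging", stacklevel=2)
        agg = sub.groupby("minute")["e_par"].mean()
        minutes = agg.index.to_numpy()
        for a, b in zip(minutes, minutes[1:]):
            if b - a > 1:
                gaps.append({"date": day, "gap_start": int(a + 1), "gap_end": int(b - 1),
                             "missing_minutes": int(b - a - 1)})
        series[str(day)] = IrradianceSeries(str(day), minutes, agg.to_numpy())
    gap_report = pd.DataFrame(gaps, columns=["date", "gap_start", "gap_end",
                                             "missing_minutes"])
    return series, gap_report


def write_licor_csv(series_by_date: dict[str, IrradianceSeries], path) -> None:
    rows = []
    for date, s in series_by_date.items():
        for m, e in zip(s.minutes, s.e_par):
            rows.append(
                {"timestamp": f"{date} {m // 60:02d}:{m % 60:02d}", "e_par": e}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


METADATA_REQUIRED = ["replicate_id", "species", "treatment", "temperature", "run",
                     "plant_id", "rlc_order", "lunar_phase", "w_i", "w_f"]


def read_metadata_csv(path) -> pd.DataFrame:
    """Plant metadata table; enforces required columns and basic validity."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"metadata file {path} is empty")
    if "parasite_mass" not in df.columns:
        df["parasite_mass"] = 0.0
    if "excluded" not in df.columns:
        df["excluded"] = False
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = ""
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    treat_order = [t for t in ("T0", "T1", "T2", "T2.5", "T3", "T4")
                   if t in set(df["treatment"].astype(str))]
    df["treatment"] = pd.Categorical(df["treatment"].astype(str), categories=treat_order)
    temps = sorted(df["temperature"].unique())
    df["temperature"] = pd.Categorical(df["temperature"], categories=temps)
    return df


def write_metadata_csv(design: pd.DataFrame, weights: pd.DataFrame | None, path) -> None:
    df = design.copy()
    if weights is not None:
        df = df.merge(weights.drop(columns=["true_growth_pct"], errors="ignore"),
                      on="replicate_id", how="left")
    df.to_csv(path, index=False)
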