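"""Pipeline orchestration: fit → saturation → indices → models.

The stages are plain functions over in-memory objects so they can be driven
either from the CLI (file inputs, CSV outputs, manifest) or directly from a
generated :class:`~phycosat.simulate.SimStudy`.  Every replicate excluded at
any stage is logged with a reason; input rows are never silently lost.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indices import dspi as compute_dspi
from .indices import growth_percent
from .irradiance import (
    IrradianceSeries,
    assign_period_ek,
    condense_series,
    day_length,
    hsat_day,
    mean_hsat,
    rel_hsat,
)
from .models import fit_growth_regressions, growth_dspi_lmm, lrt_drop
from .rlc import RapidLightCurve, UnfittableCurveError, fit_webb

__all__ = ["PipelineConfig", "run_pipeline", "analyze_study", "fit_stage"]

#: Calendar convention for simulated runs: run *i* starts this many days
#: apart from run 1, whose day 1 is RUN_BASE_DATE.
RUN_BASE_DATE = _dt.date(2021, 9, 20)
RUN_SPACING_DAYS = 11

DEFAULT_RANDOM_EFFECTS = ("plant_id", "run", "rlc_order", "lunar_phase")
DEFAULT_RESPONSES = ("pmax", "ek", "h_sat", "rel_h_sat", "dspi", "growth_pct")


def run_day_date(run: str, day: int) -> str:
    """Date label of experiment day ``day`` (1..9) of ``run`` ("runN")."""
    idx = int(str(run).removeprefix("run"))
    d = RUN_BASE_DATE + _dt.timedelta(days=(idx - 1) * RUN_SPACING_DAYS + (day - 1))
    return d.isoformat()


def parse_clock_minutes(ts: str) -> int:
    """Minutes since midnight from 'HH:MM' or an ISO timestamp ending in it."""
    ts = str(ts).strip()
    if "T" in ts or " " in ts:
        ts = ts.replace("T", " ").split(" ")[-1]
    hh, mm = ts.split(":")[:2]
    return int(hh) * 60 + int(mm)


@dataclass
class PipelineConfig:
    """File-level configuration of a full pipeline run."""

    rlc_path: str = ""
    irradiance_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    period_scheme: str = "standard"
    hsat_mean_mode: str = "period_means"
    dspi_mean_mode: str = "daily"
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    random_effects: tuple[str, ...] = DEFAULT_RANDOM_EFFECTS
    run_models: bool = True
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("responses", "random_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for key, allowed in (
            ("period_scheme", {"standard", "no_d5"}),
            ("hsat_mean_mode", {"period_means", "all_days"}),
            ("dspi_mean_mode", {"daily", "period_means"}),
        ):
            if getattr(cfg, key) not in allowed:
                raise ValueError(f"{key} must be one of {sorted(allowed)}")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    saturation_daily: pd.DataFrame
    study: pd.DataFrame  # one row per analyzable replicate
    lrt_table: pd.DataFrame | None
    growth_regressions: pd.DataFrame | None
    growth_dspi: pd.DataFrame | None
    exclusions: pd.DataFrame
    accounting: dict = field(default_factory=dict)


def fit_stage(curves: list[RapidLightCurve]) -> tuple[pd.DataFrame, list[dict]]:
    """Fit every curve; unfittable ones become exclusion records."""
    rows, excl = [], []
    for c in curves:
        try:
            f = fit_webb(c)
        except UnfittableCurveError as err:
            excl.append(
                {"replicate_id": c.plant_id, "stage": "fit",
                 "reason": f"unfittable curve on {c.day_label}: {err}"}
            )
            continue
        rows.append(
            {
                "plant_id": c.plant_id,
                "day_label": c.day_label,
                "timestamp": c.timestamp,
                "rlc_order": c.rlc_order,
                "alpha": f.alpha,
                "ek": f.ek,
                "pmax": f.pmax,
                "retr_max": np.nan if f.retr_max is None else f.retr_max,
                "rss": f.rss,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows), excl


def analyze_study(
    curves: list[RapidLightCurve],
    metadata: pd.DataFrame,
    irradiance: dict[str, IrradianceSeries],
    date_for=run_day_date,
    period_scheme: str = "standard",
    hsat_mean_mode: str = "period_means",
    dspi_mean_mode: str = "daily",
    responses=DEFAULT_RESPONSES,
    random_effects=DEFAULT_RANDOM_EFFECTS,
    run_models: bool = True,
) -> PipelineResult:
    """Run the analysis stages over in-memory inputs.

    ``irradiance`` maps date strings to per-day series; ``date_for(run, day)``
    resolves which trace applies to each experiment day of each run.
    """
    exclusions: list[dict] = []

    # honour metadata exclusion flags up front
    meta = metadata.copy()
    for rec in meta[meta["excluded"].astype(bool)].itertuples(index=False):
        exclusions.append(
            {"replicate_id": rec.replicate_id, "stage": "metadata",
             "reason": rec.exclusion_reason or "flagged excluded"}
        )
    meta = meta[~meta["excluded"].astype(bool)]

    fits, fit_excl = fit_stage(curves)
    exclusions.extend(fit_excl)

    # day lengths per (run, day) from the condensed trace
    runs = sorted(meta["run"].unique())
    dl: dict[tuple[str, int], float] = {}
    for run in runs:
        for day in range(1, 10):
            date = date_for(run, day)
            if date not in irradiance:
                raise ValueError(f"no irradiance trace for {run} day {day} ({date})")
            dl[(run, day)] = day_length(condense_series(irradiance[date]))

    fits_ix = fits.set_index(["plant_id", "day_label"])
    sat_rows, study_rows = [], []
    for rec in meta.itertuples(index=False):
        rid = rec.replicate_id
        rep_fits = {}
        for day in ("D1", "D5", "D9"):
            if (rid, day) in fits_ix.index:
                rep_fits[day] = fits_ix.loc[(rid, day)]
        if "D9" not in rep_fits or (period_scheme == "standard" and "D5" not in rep_fits) \
                or "D1" not in rep_fits:
            needed = {"standard": "D1, D5 and D9", "no_d5": "D1 and D9"}[period_scheme]
            exclusions.append(
                {"replicate_id": rid, "stage": "saturation",
                 "reason": f"missing fitted curve(s); scheme {period_scheme} "
                           f"needs {needed}, have {sorted(rep_fits)}"}
            )
            continue
        ek_by_day = {d: float(f["ek"]) for d, f in rep_fits.items()}
        pmax_by_day = {d: float(f["pmax"]) for d, f in rep_fits.items()}
        w_start = parse_clock_minutes(rep_fits["D1"]["timestamp"])
        w_end = parse_clock_minutes(rep_fits["D9"]["timestamp"])
        daily_h, daily_dl = {}, {}
        for day in range(1, 10):
            series = irradiance[date_for(rec.run, day)]
            ek = assign_period_ek(day, ek_by_day, period_scheme)
            window = None
            if day == 1:
                window = (w_start, series.minutes[-1])
            elif day == 9:
                window = (series.minutes[0], w_end)
            h = hsat_day(series, ek, window)
            daily_h[day] = h
            daily_dl[day] = dl[(rec.run, day)]
            sat_rows.append(
                {"replicate_id": rid, "day_index": day, "h_sat_min": h,
                 "ek_used": ek, "day_length_min": dl[(rec.run, day)]}
            )
        m_hsat = mean_hsat(daily_h, period_scheme, hsat_mean_mode)
        r_hsat = rel_hsat(daily_h, daily_dl)
        d = compute_dspi(pmax_by_day, daily_h, period_scheme, dspi_mean_mode, rid)
        growth = growth_percent(
            float(rec.w_i), float(rec.w_f), float(getattr(rec, "parasite_mass", 0.0))
        )
        study_rows.append(
            {
                "replicate_id": rid,
                "species": rec.species,
                "treatment": rec.treatment,
                "temperature": rec.temperature,
                "run": rec.run,
                "plant_id": rec.plant_id,
                "rlc_order": rec.rlc_order,
                "lunar_phase": rec.lunar_phase,
                "alpha": float(rep_fits["D9"]["alpha"]),
                "ek": ek_by_day["D9"],
                "pmax": pmax_by_day["D9"],
                "retr_max": float(rep_fits["D9"]["retr_max"]),
                "h_sat": m_hsat,
                "rel_h_sat": r_hsat,
                "dspi": d.dspi,
                "w_i": float(rec.w_i),
                "w_f": float(rec.w_f),
                "parasite_mass": float(getattr(rec, "parasite_mass", 0.0)),
                "growth_pct": growth,
            }
        )

    study = pd.DataFrame(study_rows)
    if len(study):
        study["treatment"] = pd.Categorical(
            study["treatment"], categories=[c for c in metadata["treatment"].dtype.categories
                                            if c in set(study["treatment"])]
            if isinstance(metadata["treatment"].dtype, pd.CategoricalDtype)
            else sorted(study["treatment"].unique()),
        )
        study["temperature"] = pd.Categorical(
            study["temperature"], categories=sorted(study["temperature"].unique())
        )

    lrt_table = growth_reg = growth_dspi = None
    if run_models and len(study):
        lrt_rows = []
        for resp in responses:
            for term in ("treatment", "temperature"):
                full, reduced, test = lrt_drop(
                    study, resp, ["treatment", "temperature"],
                    list(random_effects), term,
                )
                lrt_rows.append(
                    {
                        "response": resp,
                        "effect": term,
                        "chi2": test.chi2,
                        "df": test.df,
                        "p_value": test.p_value,
                        "r2_marginal": full.r2_marginal,
                        "r2_conditional": full.r2_conditional,
                        "random_effects": "+".join(full.random),
                        "singular": full.singular,
                        "n": full.nobs,
                    }
                )
        lrt_table = pd.DataFrame(lrt_rows)
        growth_reg = fit_growth_regressions(study)
        gfit, gtest = growth_dspi_lmm(study)
        growth_dspi = pd.DataFrame(
            [
                {
                    "slope": float(gfit.params["dspi"]),
                    "stderr": float(gfit.bse["dspi"]),
                    "chi2": gtest.chi2,
                    "df": gtest.df,
                    "p_value": gtest.p_value,
                    "r2_marginal": gfit.r2_marginal,
                    "r2_conditional": gfit.r2_conditional,
                    "n": gfit.nobs,
                }
            ]
        )

    accounting = {
        "metadata_rows": int(len(metadata)),
        "curves_in": int(len(curves)),
        "curves_fitted": int(len(fits)),
        "replicates_analyzed": int(len(study)),
        "replicates_excluded": int(len(metadata) - len(study)),
    }
    return PipelineResult(
        fits=fits,
        saturation_daily=pd.DataFrame(sat_rows),
        study=study,
        lrt_table=lrt_table,
        growth_regressions=growth_reg,
        growth_dspi=growth_dspi,
        exclusions=pd.DataFrame(
            exclusions, columns=["replicate_id", "stage", "reason"]
        ),
        accounting=accounting,
    )


def _write_csv(df: pd.DataFrame | None, path: Path) -> None:
    if df is None:
        return
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: read inputs, run all stages, write outputs.

    Outputs (CSV + a JSON manifest) land in ``config.out_dir``; a repeated
    run with identical inputs and config is byte-identical.
    """
    from .io import read_licor_csv, read_metadata_csv, read_rlc_csv

    metadata = read_metadata_csv(config.metadata_path)
    curves, rejects = read_rlc_csv(config.rlc_path)
    irradiance, gaps = read_licor_csv(config.irradiance_path)

    result = analyze_study(
        curves,
        metadata,
        irradiance,
        period_scheme=config.period_scheme,
        hsat_mean_mode=config.hsat_mean_mode,
        dspi_mean_mode=config.dspi_mean_mode,
        responses=config.responses,
        random_effects=config.random_effects,
        run_models=config.run_models,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(result.fits.sort_values(["plant_id", "day_label"]), out / "fits.csv")
    _write_csv(result.saturation_daily, out / "saturation.csv")
    _write_csv(result.study, out / "study_table.csv")
    _write_csv(result.lrt_table, out / "models_lrt.csv")
    _write_csv(result.growth_regressions, out / "growth_regressions.csv")
    _write_csv(result.growth_dspi, out / "growth_dspi.csv")
    _write_csv(result.exclusions, out / "exclusions.csv")
    _write_csv(rejects, out / "rlc_rejects.csv")
    _write_csv(gaps, out / "irradiance_gaps.csv")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "accounting": result.accounting,
        "rlc_rejects": int(len(rejects)),
        "irradiance_gaps": int(len(gaps)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
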