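"""Synthetic study generator.

Emulates the structure of a 9-day macroalgal SGD-gradient experiment: two
species (a green *Ulva*-like and a red *Hypnea*-like alga) crossed over six
salinity/nutrient treatments (T0–T4, including the intermediate T2.5) and
three water temperatures (20, 27, 30 °C), 16 replicates per cell, measured
by rapid light curves on days 1, 5 and 9 under natural irradiance logged
every minute beneath ~50 % shade cloth.

The generator's defaults are calibrated to the study conditions: treatment
salinity/nutrient levels, the nine actinic steps, per-treatment mean P_max
and E_k surfaces, temperature offsets, daylight windows of 611–688 min, and
the two bookkeeping exclusions (the entire green-alga T2.5 cell, and two
depigmented red-alga individuals that cannot sustain a fluorescence signal
on D9).  Truth tables are retained alongside the generated data so every
analysis stage can be checked by parameter recovery.

Draw order under one study seed is fixed — design, plant parameters, RLC
yields, irradiance, growth — so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import dspi as compute_dspi
from .irradiance import LOG_END, LOG_START, IrradianceSeries
from .rlc import DEFAULT_ACTINIC_STEPS, RapidLightCurve, webb_yield

__all__ = [
    "TREATMENTS",
    "SimConfig",
    "SimStudy",
    "enumerate_design",
    "simulate_plant_params",
    "simulate_rlc",
    "simulate_irradiance",
    "simulate_growth",
    "simulate_study",
    "simulate_response_table",
    "study_table",
]

#: Treatment label -> (salinity ‰, nitrate μmol, phosphate μmol).
TREATMENTS: dict[str, tuple[float, float, float]] = {
    "T0": (35, 0.5, 0.005),
    "T1": (35, 14.3, 0.005),
    "T2": (28, 27.1, 0.15),
    "T2.5": (28, 52.9, 1.64),
    "T3": (18, 52.9, 1.64),
    "T4": (11, 80.0, 3.79),
}

TREATMENT_ORDER = ("T0", "T1", "T2", "T2.5", "T3", "T4")
TEMPERATURES = (20, 27, 30)
DAY_LABELS = ("D1", "D5", "D9")
LUNAR_PHASES = ("new", "waxing", "full", "waning")

# Mean D9 P_max (μmol electrons m⁻² s⁻¹) and E_k (μmol photons m⁻² s⁻¹)
# surfaces by treatment.  The green alga's T2.5 cell is excluded from
# analysis; its generating means are interpolated between T2 and T3.
ULVA_PMAX_MEANS = {"T0": 31.1, "T1": 52.3, "T2": 53.3, "T2.5": 62.8,
                   "T3": 72.3, "T4": 74.3}
ULVA_EK_MEANS = {"T0": 27.2, "T1": 65.2, "T2": 72.8, "T2.5": 89.1,
                 "T3": 105.3, "T4": 110.4}
HYPNEA_PMAX_MEANS = {"T0": 43.9, "T1": 47.5, "T2": 43.8, "T2.5": 58.7,
                     "T3": 49.0, "T4": 53.1}
HYPNEA_EK_MEANS = {"T0": 51.8, "T1": 71.4, "T2": 70.7, "T2.5": 93.8,
                   "T3": 70.5, "T4": 78.3}

# Temperature offsets, centred so the treatment surfaces above stay the
# across-temperature means.  The green alga shows a small E_k depression at
# the warmer temperatures and no temperature signal in P_max; the red alga
# is substantially less productive above 20 °C.
ULVA_PMAX_TEMP = {20: 0.0, 27: 0.0, 30: 0.0}
ULVA_EK_TEMP = {20: 7.03, 27: -3.47, 30: -3.57}
HYPNEA_PMAX_TEMP = {20: 12.23, 27: -5.07, 30: -7.17}
HYPNEA_EK_TEMP = {20: 25.07, 27: -10.73, 30: -14.33}

# Growth-model slopes (percent growth per unit DSPI).
ULVA_GROWTH_SLOPE = 12.2
HYPNEA_GROWTH_SLOPE = 4.1


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    species: str = "ulva"
    seed: int = 0
    replicates: int = 16
    temperatures: tuple[int, ...] = TEMPERATURES
    treatments: tuple[str, ...] = TREATMENT_ORDER
    pmax_means: dict[str, float] = field(default_factory=lambda: dict(ULVA_PMAX_MEANS))
    ek_means: dict[str, float] = field(default_factory=lambda: dict(ULVA_EK_MEANS))
    pmax_temp_offsets: dict[int, float] = field(default_factory=lambda: dict(ULVA_PMAX_TEMP))
    ek_temp_offsets: dict[int, float] = field(default_factory=lambda: dict(ULVA_EK_TEMP))
    # plant/replicate-level biological variation
    sd_ek_plant: float = 8.0
    sd_alpha_plant: float = 0.05
    sd_ek_replicate: float = 4.0
    sd_alpha_replicate: float = 0.02
    day_drift_ek: float = 0.0  # additive E_k drift per experiment day, D9-anchored
    # RLC measurement
    actinic_steps: tuple[float, ...] = DEFAULT_ACTINIC_STEPS
    rlc_noise_sd: float = 0.01
    alpha_bounds: tuple[float, float] = (0.02, 0.95)
    ek_floor: float = 5.0
    # irradiance
    daylight_min: float = 611.0
    daylight_max: float = 688.0
    peak_par: float = 700.0  # unshaded clear-sky peak at the sensor
    shading: float = 0.5
    cloud_sd: float = 0.2  # lognormal sigma of per-minute multiplicative noise
    # growth
    growth_intercept: float = -5.0
    growth_dspi_slope: float = ULVA_GROWTH_SLOPE
    growth_treatment_sd: float = 5.0
    growth_noise_sd: float = 8.0
    w_i_range: tuple[float, float] = (0.28, 0.30)
    parasite_rate: float = 0.0
    parasite_mass_max: float = 0.02
    # exclusions
    drop_ulva_t25: bool = True
    n_depigmented: int = 2

    @classmethod
    def for_species(cls, species: str, **overrides) -> "SimConfig":
        species = species.lower()
        if species == "ulva":
            cfg = cls(species="ulva")
        elif species == "hypnea":
            cfg = cls(
                species="hypnea",
                pmax_means=dict(HYPNEA_PMAX_MEANS),
                ek_means=dict(HYPNEA_EK_MEANS),
                pmax_temp_offsets=dict(HYPNEA_PMAX_TEMP),
                ek_temp_offsets=dict(HYPNEA_EK_TEMP),
                growth_dspi_slope=HYPNEA_GROWTH_SLOPE,
                drop_ulva_t25=False,
            )
        else:
            raise ValueError(f"unknown species {species!r}")
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimStudy:
    """A complete generated study: data plus the truth that produced it."""

    config: SimConfig
    design: pd.DataFrame
    truth: pd.DataFrame  # one row per replicate × day label
    curves: list[RapidLightCurve]
    irradiance: dict[tuple[str, int], IrradianceSeries]  # (run, day) -> series
    weights: pd.DataFrame
    truth_dspi: pd.DataFrame  # replicate_id, true_dspi


def _species_prefix(species: str) -> str:
    return {"ulva": "Ul", "hypnea": "Hm"}[species]


def _run_for(treatment: str, replicate: int) -> str:
    """Run assignment: the four base treatments share runs 1–8 (two
    replicates per cell per run); the later-added T0 and T2.5 cells were run
    separately, here as runs 9–10 and 11–12."""
    if treatment == "T0":
        return f"run{9 + (replicate - 1) // 8}"
    if treatment == "T2.5":
        return f"run{11 + (replicate - 1) // 8}"
    return f"run{(replicate - 1) // 2 + 1}"


def enumerate_design(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full treatment × temperature × replicate cross with exclusion flags.

    Source plants are sectioned into four replicate pieces in the base runs,
    so the plant-ID grouping (the random effect) spans four rows there; the
    later-added cells used one piece per collected plant.  Exclusions are
    flags plus reasons, never silent row drops.
    """
    rng = rng or np.random.default_rng(config.seed)
    prefix = _species_prefix(config.species)
    rows = []
    for treat in config.treatments:
        for temp in config.temperatures:
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "species": config.species,
                        "treatment": treat,
                        "temperature": temp,
                        "run": _run_for(treat, rep),
                        "replicate": rep,
                        "replicate_id": f"{prefix}-{treat}-{temp}-r{rep:02d}",
                    }
                )
    df = pd.DataFrame(rows)
    # group pieces into source plants: in the base runs each collected plant
    # is sectioned into pieces spread across the treatments (one piece per
    # treatment at a given temperature/replicate slot), so plant variation is
    # crossed with — not nested in — treatment; the added-treatment runs used
    # one piece per collected plant
    plant_ids = []
    for run, sub in df.groupby("run", sort=False):
        added = sub["treatment"].iloc[0] in ("T0", "T2.5")
        if added:
            for j, idx in enumerate(sub.index):
                plant_ids.append((idx, f"{prefix}-{run}-P{j + 1:02d}"))
        else:
            slots = {}
            for idx in sub.index:
                key = (df.at[idx, "temperature"], df.at[idx, "replicate"])
                slots.setdefault(key, len(slots) + 1)
                plant_ids.append((idx, f"{prefix}-{run}-P{slots[key]:02d}"))
    df["plant_id"] = pd.Series(dict(plant_ids))
    # morning measurement order: one random permutation per run
    order = np.empty(len(df), dtype=int)
    for run, sub in df.groupby("run", sort=False):
        order[sub.index.to_numpy()] = rng.permutation(len(sub)) + 1
    df["rlc_order"] = order
    df["lunar_phase"] = [
        LUNAR_PHASES[int(r.removeprefix("run")) % 4] for r in df["run"]
    ]
    df["excluded"] = False
    df["exclusion_reason"] = ""
    if config.species == "ulva" and config.drop_ulva_t25 and "T2.5" in config.treatments:
        mask = df["treatment"] == "T2.5"
        df.loc[mask, "excluded"] = True
        df.loc[mask, "exclusion_reason"] = "T2.5 lunar-phase tissue sloughing"
    if config.species == "hypnea" and config.n_depigmented > 0:
        eligible = df.index[~df["excluded"]].to_numpy()
        pick = rng.choice(eligible, size=min(config.n_depigmented, len(eligible)),
                          replace=False)
        df.loc[pick, "excluded"] = True
        df.loc[pick, "exclusion_reason"] = "depigmented on D9, RLC unfittable"
    # reference levels first: T0 for treatment, 20 °C for temperature
    df["treatment"] = pd.Categorical(df["treatment"], categories=list(config.treatments))
    df["temperature"] = pd.Categorical(
        df["temperature"], categories=list(config.temperatures)
    )
    return df


def simulate_plant_params(
    design: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-replicate, per-day true α and E_k.

    cell mean + source-plant intercept + replicate intercept + day drift,
    truncated into the physical range (α within ``alpha_bounds``, E_k above
    ``ek_floor``).  The α surface is tied to the P_max surface through
    α = P_max / E_k.
    """
    plant_fx: dict[str, tuple[float, float]] = {}
    rows = []
    day_number = {"D1": 1, "D5": 5, "D9": 9}
    for rec in design.itertuples(index=False):
        treat, temp = str(rec.treatment), int(rec.temperature)
        ek_cell = config.ek_means[treat] + config.ek_temp_offsets[temp]
        pmax_cell = config.pmax_means[treat] + config.pmax_temp_offsets[temp]
        alpha_cell = float(np.clip(pmax_cell / ek_cell, *config.alpha_bounds))
        if rec.plant_id not in plant_fx:
            plant_fx[rec.plant_id] = (
                rng.normal(0.0, config.sd_ek_plant),
                rng.normal(0.0, config.sd_alpha_plant),
            )
        b_ek, b_alpha = plant_fx[rec.plant_id]
        r_ek = rng.normal(0.0, config.sd_ek_replicate)
        r_alpha = rng.normal(0.0, config.sd_alpha_replicate)
        for day in DAY_LABELS:
            drift = config.day_drift_ek * (day_number[day] - 9)
            ek = max(config.ek_floor, ek_cell + b_ek + r_ek + drift)
            alpha = float(np.clip(alpha_cell + b_alpha + r_alpha, *config.alpha_bounds))
            rows.append(
                {
                    "replicate_id": rec.replicate_id,
                    "plant_id": rec.plant_id,
                    "day_label": day,
                    "true_alpha": alpha,
                    "true_ek": ek,
                    "true_pmax": alpha * ek,
                }
            )
    return pd.DataFrame(rows)


def simulate_rlc(
    alpha: float,
    ek: float,
    config: SimConfig,
    rng: np.random.Generator,
    plant_id: str = "sim",
    day_label: str = "D9",
    timestamp: str = "",
    rlc_order: int = 1,
) -> RapidLightCurve:
    """One RLC: Webb-model yields plus Gaussian noise, clipped to [0, 1]."""
    e = np.asarray(config.actinic_steps, dtype=float)
    phi = webb_yield(e, alpha, ek)
    if config.rlc_noise_sd > 0:
        phi = phi + rng.normal(0.0, config.rlc_noise_sd, size=e.shape)
    phi = np.clip(phi, 0.0, 1.0)
    return RapidLightCurve.from_arrays(
        plant_id, day_label, e, phi, timestamp=timestamp, rlc_order=rlc_order
    )


def simulate_irradiance(
    date: str, config: SimConfig, rng: np.random.Generator,
    daylight_minutes: float | None = None,
) -> IrradianceSeries:
    """One day's per-minute PAR trace on the 05:00–19:30 logging window.

    A half-sine clear-sky profile peaking mid-window, scaled by the shading
    factor, with per-minute multiplicative lognormal cloud noise.
    """
    if daylight_minutes is None:
        daylight_minutes = float(
            rng.uniform(config.daylight_min, config.daylight_max)
        )
    minutes = np.arange(LOG_START, LOG_END + 1)
    centre = (LOG_START + LOG_END) / 2.0
    sunrise = centre - daylight_minutes / 2.0
    t = minutes - sunrise
    inside = (t >= 0) & (t <= daylight_minutes)
    e = np.zeros(minutes.shape, dtype=float)
    e[inside] = (
        config.peak_par
        * config.shading
        * np.sin(np.pi * t[inside] / daylight_minutes)
    )
    if config.cloud_sd > 0:
        e = e * np.exp(rng.normal(0.0, config.cloud_sd, size=e.shape))
    return IrradianceSeries(date=date, minutes=minutes, e_par=np.maximum(e, 0.0))


def simulate_growth(
    design: pd.DataFrame,
    dspi_truth: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Initial/final wet weights from a linear growth model on true DSPI.

    growth% = intercept + slope·DSPI + treatment effect + noise, with the
    treatment effects drawn once per treatment (they are the random
    intercepts the growth LMM estimates).  Final weight is the initial
    weight grown by that percentage, plus any parasite biomass that is
    recorded separately and deducted again at analysis time.
    """
    treat_levels = list(dict.fromkeys(str(t) for t in design["treatment"]))
    treat_fx = {t: rng.normal(0.0, config.growth_treatment_sd) for t in treat_levels}
    rows = []
    for rec in design.itertuples(index=False):
        d = float(dspi_truth[rec.replicate_id])
        g = (
            config.growth_intercept
            + config.growth_dspi_slope * d
            + treat_fx[str(rec.treatment)]
            + rng.normal(0.0, config.growth_noise_sd)
        )
        g = max(g, -95.0)
        w_i = float(rng.uniform(*config.w_i_range))
        w_f = w_i * (1.0 + g / 100.0)
        parasite = 0.0
        if config.parasite_rate > 0 and rng.random() < config.parasite_rate:
            parasite = float(rng.uniform(0.0, config.parasite_mass_max))
        rows.append(
            {
                "replicate_id": rec.replicate_id,
                "w_i": w_i,
                "w_f": w_f + parasite,  # recorded weight includes the parasite
                "parasite_mass": parasite,
                "true_growth_pct": g,
            }
        )
    return pd.DataFrame(rows)


def _rlc_timestamp(order: int) -> str:
    minute = 8 * 60 + 4 * (order - 1)
    return f"{minute // 60:02d}:{minute % 60:02d}"


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate a complete study under one seed, truth retained throughout.

    Draw order is fixed: design → plant parameters → RLC yields →
    irradiance → growth, each from its own stream spawned from the study
    seed, so any stage can be regenerated independently.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_design, rng_params, rng_rlc, rng_irr, rng_growth = (
        np.random.default_rng(s) for s in streams
    )
    design = enumerate_design(config, rng_design)
    truth = simulate_plant_params(design, config, rng_params)

    truth_ix = truth.set_index(["replicate_id", "day_label"])
    depig = set(
        design.loc[
            design["exclusion_reason"].str.contains("depigmented"), "replicate_id"
        ]
    )
    curves: list[RapidLightCurve] = []
    for rec in design.itertuples(index=False):
        for day in DAY_LABELS:
            t = truth_ix.loc[(rec.replicate_id, day)]
            if rec.replicate_id in depig and day == "D9":
                # no photochemical signal: an all-zero curve, unfittable
                e = np.asarray(config.actinic_steps, dtype=float)
                curve = RapidLightCurve.from_arrays(
                    rec.replicate_id, day, e, np.zeros_like(e),
                    timestamp=_rlc_timestamp(int(rec.rlc_order)),
                    rlc_order=int(rec.rlc_order),
                )
            else:
                curve = simulate_rlc(
                    float(t["true_alpha"]), float(t["true_ek"]), config, rng_rlc,
                    plant_id=rec.replicate_id, day_label=day,
                    timestamp=_rlc_timestamp(int(rec.rlc_order)),
                    rlc_order=int(rec.rlc_order),
                )
            curves.append(curve)

    from .pipeline import run_day_date

    irradiance: dict[tuple[str, int], IrradianceSeries] = {}
    for run in sorted(design["run"].unique(), key=lambda r: int(r.removeprefix("run"))):
        for day in range(1, 10):
            irradiance[(run, day)] = simulate_irradiance(
                run_day_date(run, day), config, rng_irr
            )

    # truth DSPI from true parameters against the run's own irradiance
    from .irradiance import assign_period_ek, hsat_day

    dspi_vals = {}
    for rec in design.itertuples(index=False):
        fits = {
            day: float(truth_ix.loc[(rec.replicate_id, day)]["true_ek"])
            for day in DAY_LABELS
        }
        pmaxes = {
            day: float(truth_ix.loc[(rec.replicate_id, day)]["true_pmax"])
            for day in DAY_LABELS
        }
        daily = {
            day: hsat_day(
                irradiance[(rec.run, day)], assign_period_ek(day, fits)
            )
            for day in range(1, 10)
        }
        dspi_vals[rec.replicate_id] = compute_dspi(
            pmaxes, daily, plant_id=rec.replicate_id
        ).dspi
    truth_dspi = pd.Series(dspi_vals, name="true_dspi")

    weights = simulate_growth(design, truth_dspi, config, rng_growth)
    return SimStudy(
        config=config,
        design=design,
        truth=truth,
        curves=curves,
        irradiance=irradiance,
        weights=weights,
        truth_dspi=truth_dspi.rename_axis("replicate_id").reset_index(),
    )


def simulate_response_table(
    design: pd.DataFrame,
    rng: np.random.Generator,
    treatment_effects: dict[str, float] | None = None,
    temperature_effects: dict[int, float] | None = None,
    sd_plant: float = 1.0,
    sd_run: float = 1.0,
    sd_resid: float = 1.0,
    intercept: float = 0.0,
    response: str = "y",
) -> pd.DataFrame:
    """Design + one Gaussian response with known fixed and random structure.

    A light-weight generator for calibrating the model layer (type-I error,
    coverage) without simulating curves or light: the response is
    intercept + treatment effect + temperature effect + plant intercept +
    run intercept + noise.
    """
    table = design.copy()
    plant_fx = {p: rng.normal(0, sd_plant) for p in table["plant_id"].unique()}
    run_fx = {r: rng.normal(0, sd_run) for r in table["run"].unique()}
    y = np.full(len(table), float(intercept))
    for i, rec in enumerate(table.itertuples(index=False)):
        if treatment_effects:
            y[i] += treatment_effects.get(str(rec.treatment), 0.0)
        if temperature_effects:
            y[i] += temperature_effects.get(int(rec.temperature), 0.0)
        y[i] += plant_fx[rec.plant_id] + run_fx[rec.run]
    y += rng.normal(0, sd_resid, size=len(table))
    table[response] = y
    return table


def study_table(study: SimStudy) -> pd.DataFrame:
    """Design joined with truth-derived responses (no measurement layer).

    Convenience for model-layer tests; the measured analogue is produced by
    the pipeline from the generated curves and traces.
    """
    d9 = study.truth[study.truth["day_label"] == "D9"].set_index("replicate_id")
    t = study.design.set_index("replicate_id").join(
        d9[["true_alpha", "true_ek", "true_pmax"]]
    )
    t = t.join(study.truth_dspi.set_index("replicate_id"))
    t = t.join(study.weights.set_index("replicate_id"))
    return t.reset_index()
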