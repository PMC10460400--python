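# phycosat

Photophysiology analysis for macroalgal culture experiments: Webb
photosynthesis–irradiance fitting of PAM rapid light curves, diurnal
time-in-saturation from minute-resolution PAR logs, the diurnal saturated
photosynthesis index (DSPI), 9-day growth, and the linear mixed-model /
likelihood-ratio-test layer that relates them.

It is written for experiments of the kind used to probe how submarine-
groundwater-discharge conditions (salinity/nutrient gradients, temperature)
shape algal performance: replicate plants held in treatment jars under
natural light for nine days, measured by rapid light curve (RLC) on days 1,
5 and 9, weighed at start and end, with irradiance logged every minute.

## The model

Each RLC records the effective quantum yield of photosystem II, Φ_PSII, at
nine actinic irradiances E ∈ {0, 65, 90, 125, 190, 285, 420, 625, 820}
μmol photons m⁻² s⁻¹.  Yields are fitted with the irradiance-normalized
Webb model

```
Φ(E) = α · (E_k / E) · (1 − e^(−E/E_k)),     Φ(0) ≡ α
```

giving the light-limited efficiency α and the saturation irradiance E_k,
from which P_max = α·E_k (μmol electrons m⁻² s⁻¹).  rETR_max — the largest
E·Φ among steps with Φ_PSII > 0.1 — is reported alongside.

From the PAR trace, each plant's daily **H_sat** is the number of minutes
with E ≥ its E_k, with E_k mapped to experiment days by period (days 1–3 ←
D1 fit, 4–5 ← D5, 6–9 ← D9).  Day length is computed from a condensed trace
(10-min trailing moving average sampled on the :00/:10/… grid) as minutes
with E ≥ 1 μmol photons m⁻² s⁻¹, and rel-H_sat = mean of daily
100·H_sat/day-length.  The production index is

```
DSPI = mean over days of  P_max(period) · 60 · H_sat(day) · 10⁻⁶    [mol m⁻²]
```

and growth is 100·(w_f − w_i)/w_i on wet weights (parasite biomass
deducted).  Each response is then analyzed with ML linear mixed models —
treatment and temperature fixed; plant ID, run, RLC order and lunar phase as
crossed random intercepts — with likelihood-ratio tests and
Nakagawa–Schielzeth R²m/R²c.  A seeded generator produces complete synthetic
studies (design, curves, light, weights, with truth tables) so every stage
is testable end to end.  See `docs/methods.md` for details and assumptions.

## Worked example

Fit one noisy curve:

```python
import numpy as np
from phycosat import RapidLightCurve, fit_webb, webb_yield

e = np.array([0, 65, 90, 125, 190, 285, 420, 625, 820], float)
rng = np.random.default_rng(42)
phi = np.clip(webb_yield(e, 0.62, 85.0) + rng.normal(0, 0.01, 9), 0, 1)
fit = fit_webb(RapidLightCurve.from_arrays("UL-T3-20-r01", "D9", e, phi))
print(f"alpha={fit.alpha:.3f}  ek={fit.ek:.1f}  pmax={fit.pmax:.1f}")
```

```
alpha=0.625  ek=81.8  pmax=51.1
```

The true parameters (α = 0.62, E_k = 85) are recovered within the noise;
P_max is their product.  A small full study from the command line:

```
phycosat simulate --species ulva --seed 1 --replicates 2 --out data
phycosat run --config cfg.yml        # paths to the three CSVs in data/
```

with `cfg.yml` pointing `rlc_path`, `irradiance_path`, `metadata_path` at
the generated files.  Treatment means from `results/study_table.csv` (30
analyzable replicates; the T2.5 cell is excluded by design):

```
           pmax     ek  h_sat  dspi  growth_pct
T0         28.7   31.1  566.6   0.9         1.2
T1         50.0   61.8  533.0   1.5        18.0
T2         51.9   69.8  522.6   1.6        20.3
T3         71.7  101.0  487.5   2.0        14.9
T4         74.2  110.7  477.2   2.0        29.9
```

P_max and E_k rise along the salinity/nutrient gradient while H_sat falls —
plants that saturate at higher irradiance spend less of the day saturated.
`results/growth_dspi.csv` holds the growth~DSPI mixed model: slope 15.8 ±
4.6 % growth per mol m⁻² (χ²(1) = 8.6, p < 0.001) against a generating
slope of 12.2.  `results/models_lrt.csv` mirrors the per-response LRT table
(effect, χ², df, p, R²m, R²c, random effects used).

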