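"""Mixed-model layer: OLS degeneracy, LRT bookkeeping, Nakagawa R²."""

import numpy as np
import pandas as pd
import pytest

from phycosat.models import (
    fit_growth_regressions,
    fit_lmm,
    growth_dspi_lmm,
    lrt,
    lrt_drop,
    r2_nakagawa,
)
from phycosat.simulate import SimConfig, enumerate_design, simulate_response_table


@pytest.fixture(scope="module")
def small_design():
    cfg = SimConfig.for_species("ulva", replicates=4, drop_ulva_t25=False,
                                treatments=("T0", "T1", "T2", "T3", "T4"))
    return enumerate_design(cfg, np.random.default_rng(11))


@pytest.fixture(scope="module")
def effect_table(small_design):
    rng = np.random.default_rng(5)
    return simulate_response_table(
        small_design, rng,
        treatment_effects={"T4": 20.0, "T3": 10.0},
        sd_plant=1.0, sd_run=1.0, sd_resid=2.0,
    )


class TestFitLMM:
    def test_zero_random_variance_matches_ols(self, small_design):
        """With no random structure in the data, the ML mixed fit's fixed
        effects coincide with plain least squares."""
        rng = np.random.default_rng(7)
        table = simulate_response_table(
            small_design, rng, treatment_effects={"T4": 5.0},
            sd_plant=0.0, sd_run=0.0, sd_resid=1.0,
        )
        mixed = fit_lmm(table, "y", ["treatment", "temperature"], ["run"],
                        drop_singular=False)
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ C(treatment) + C(temperature)", data=table).fit()
        for name in ols.params.index:
            assert mixed.params[name] == pytest.approx(ols.params[name], abs=1e-6)

    def test_intercept_only_marginal_r2_is_zero(self, effect_table):
        fit = fit_lmm(effect_table, "y", [], ["plant_id", "run"])
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-10)
        assert fit.r2_conditional > 0

    def test_r2_ordering_and_bounds(self, effect_table):
        fit = fit_lmm(effect_table, "y", ["treatment", "temperature"],
                      ["plant_id", "run"])
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1

    def test_r2_matches_generating_variance_ratios(self):
        """Data built with fixed/random/residual variances 4/2/2 give
        R²m ≈ 0.5 and R²c ≈ 0.75."""
        rng = np.random.default_rng(42)
        n_groups, per = 100, 20
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(0, 1, n_groups * per)
        y = 2.0 * x + np.sqrt(2.0) * rng.normal(0, 1, n_groups)[g] \
            + np.sqrt(2.0) * rng.normal(0, 1, n_groups * per)
        table = pd.DataFrame({"x": x, "g": g.astype(str), "y": y})
        fit = fit_lmm(table, "y", ["x"], ["g"])
        assert fit.r2_marginal == pytest.approx(0.5, abs=0.05)
        assert fit.r2_conditional == pytest.approx(0.75, abs=0.05)

    def test_singular_fallback_drops_in_priority_order(self, small_design):
        """A noise-only lunar-phase component collapses and is dropped
        first; plant ID is always retained."""
        rng = np.random.default_rng(9)
        table = simulate_response_table(
            small_design, rng, sd_plant=2.0, sd_run=0.0, sd_resid=1.0,
        )
        fit = fit_lmm(table, "y", ["treatment"],
                      ["plant_id", "run", "rlc_order", "lunar_phase"])
        assert "plant_id" in fit.random
        assert set(fit.dropped) <= {"lunar_phase", "rlc_order", "run"}

    def test_rank_deficient_design_raises(self, small_design):
        table = small_design.copy()
        table["y"] = 1.0
        table["treatment2"] = table["treatment"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lmm(table, "y", ["treatment", "treatment2"], [])

    def test_single_level_factor_raises(self, small_design):
        table = small_design[small_design["treatment"] == "T0"].copy()
        table["y"] = np.arange(len(table), dtype=float)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_lmm(table, "y", ["treatment"], [])


class TestLRT:
    def test_self_test_is_null(self, effect_table):
        fit = fit_lmm(effect_table, "y", ["treatment"], ["plant_id"])
        res = lrt(fit, fit)
        assert res.chi2 == 0.0
        assert res.df == 0
        assert res.p_value == 1.0

    def test_df_matches_factor_levels(self, effect_table):
        """Dropping a 5-level treatment gives df 4; a 3-level temperature
        gives df 2."""
        _, _, t_treat = lrt_drop(effect_table, "y", ["treatment", "temperature"],
                                 ["plant_id", "run"], "treatment")
        _, _, t_temp = lrt_drop(effect_table, "y", ["treatment", "temperature"],
                                ["plant_id", "run"], "temperature")
        assert t_treat.df == 4
        assert t_temp.df == 2
        assert t_treat.chi2 > t_temp.chi2  # real treatment effect, no temp effect

    def test_noise_covariate_never_lowers_loglik(self, effect_table):
        rng = np.random.default_rng(3)
        table = effect_table.copy()
        table["noise"] = rng.normal(size=len(table))
        base = fit_lmm(table, "y", ["treatment"], ["plant_id"], drop_singular=False)
        bigger = fit_lmm(table, "y", ["treatment", "noise"], ["plant_id"],
                         drop_singular=False)
        assert bigger.llf >= base.llf - 1e-6
        res = lrt(bigger, base)
        assert res.df == 1
        assert res.chi2 >= 0

    def test_non_nested_rejected(self, effect_table):
        a = fit_lmm(effect_table, "y", ["treatment"], ["plant_id"])
        b = fit_lmm(effect_table, "y", ["temperature"], ["plant_id"])
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_mismatched_random_structure_rejected(self, effect_table):
        a = fit_lmm(effect_table, "y", ["treatment"], ["plant_id"],
                    drop_singular=False)
        b = fit_lmm(effect_table, "y", [], ["run"], drop_singular=False)
        with pytest.raises(ValueError, match="random structures"):
            lrt(a, b)


class TestGrowthModels:
    def test_exact_line_recovers_slope(self, small_design, rng):
        table = small_design.copy()
        table["dspi"] = rng.uniform(1, 5, len(table))
        table["growth_pct"] = 2.0 * table["dspi"]
        table["pmax"] = rng.uniform(20, 80, len(table))
        table["ek"] = rng.uniform(20, 120, len(table))
        table["h_sat"] = rng.uniform(300, 600, len(table))
        reg = fit_growth_regressions(table).set_index("predictor")
        assert reg.loc["dspi", "slope"] == pytest.approx(2.0, abs=1e-10)
        assert reg.loc["dspi", "p_value"] < 1e-12

    def test_duplicated_rows_leave_slope_unchanged(self, small_design, rng):
        table = small_design.copy()
        table["dspi"] = rng.uniform(1, 5, len(table))
        table["growth_pct"] = 3.0 + 1.5 * table["dspi"] + rng.normal(0, 1, len(table))
        doubled = pd.concat([table, table], ignore_index=True)
        r1 = fit_growth_regressions(table, predictors=("dspi",))
        r2 = fit_growth_regressions(doubled, predictors=("dspi",))
        assert r1["slope"].iloc[0] == pytest.approx(r2["slope"].iloc[0])

    def test_constant_predictor_raises(self, small_design):
        table = small_design.copy()
        table["growth_pct"] = 1.0
        table["dspi"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            fit_growth_regressions(table, predictors=("dspi",))

    def test_growth_dspi_lmm_estimates_slope(self, small_design):
        rng = np.random.default_rng(17)
        table = small_design.copy()
        table["dspi"] = rng.uniform(1, 5, len(table))
        fx = {t: rng.normal(0, 3) for t in table["treatment"].unique()}
        table["growth_pct"] = (
            -5 + 12.2 * table["dspi"]
            + np.array([fx[t] for t in table["treatment"]])
            + rng.normal(0, 5, len(table))
        )
        fit, test = growth_dspi_lmm(table)
        lo, hi = fit.conf_int("dspi")
        assert lo < 12.2 < hi
        assert test.df == 1
        assert test.p_value < 0.001

    def test_single_treatment_falls_back_to_ols(self, small_design):
        rng = np.random.default_rng(2)
        table = small_design[small_design["treatment"] == "T1"].copy()
        table["dspi"] = rng.uniform(1, 5, len(table))
        table["growth_pct"] = 1.0 + 2.0 * table["dspi"] + rng.normal(0, 1, len(table))
        with pytest.warns(UserWarning, match="single treatment"):
            fit, test = growth_dspi_lmm(table)
        assert fit.random == ()
        assert test.df == 1
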