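"""Synthetic-study generator: design bookkeeping, determinism, calibration."""

import numpy as np
import pytest

from phycosat.irradiance import condense_series, day_length
from phycosat.rlc import fit_webb
from phycosat.simulate import (
    SimConfig,
    enumerate_design,
    simulate_growth,
    simulate_irradiance,
    simulate_plant_params,
    simulate_rlc,
    simulate_response_table,
    simulate_study,
)


class TestDesign:
    def test_design_counts_after_exclusions(self):
        ul = enumerate_design(SimConfig.for_species("ulva", seed=1))
        hm = enumerate_design(SimConfig.for_species("hypnea", seed=1))
        assert len(ul) == 288 and len(hm) == 288
        assert (~ul["excluded"]).sum() == 240  # all 48 T2.5 rows flagged
        assert (~hm["excluded"]).sum() == 286  # two depigmented individuals

    def test_minimal_design(self):
        cfg = SimConfig.for_species("hypnea", treatments=("T1",),
                                    temperatures=(27,), n_depigmented=0)
        assert len(enumerate_design(cfg)) == 16

    def test_source_plants_group_four_pieces_in_base_runs(self):
        d = enumerate_design(SimConfig.for_species("ulva", seed=1))
        base = d[~d["treatment"].isin(["T0", "T2.5"])]
        sizes = base.groupby("plant_id").size()
        assert (sizes == 4).all()
        added = d[d["treatment"] == "T0"]
        assert added.groupby("plant_id").size().max() == 1

    def test_reference_levels_first(self):
        d = enumerate_design(SimConfig.for_species("ulva", seed=1))
        assert d["treatment"].dtype.categories[0] == "T0"
        assert d["temperature"].dtype.categories[0] == 20


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig.for_species("hypnea", seed=77, replicates=2)
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.design.equals(b.design)
        assert a.truth.equals(b.truth)
        assert a.weights.equals(b.weights)
        for (k, sa) in a.irradiance.items():
            assert np.array_equal(sa.e_par, b.irradiance[k].e_par)
        for ca, cb in zip(a.curves, b.curves):
            assert np.array_equal(ca.phi_psii, cb.phi_psii)

    def test_different_seed_differs(self):
        a = simulate_study(SimConfig.for_species("ulva", seed=1, replicates=2))
        b = simulate_study(SimConfig.for_species("ulva", seed=2, replicates=2))
        assert not a.truth.equals(b.truth)


class TestPlantParams:
    def test_zero_sds_give_cell_means(self):
        cfg = SimConfig.for_species("ulva", sd_ek_plant=0, sd_alpha_plant=0,
                                    sd_ek_replicate=0, sd_alpha_replicate=0,
                                    replicates=2)
        design = enumerate_design(cfg, np.random.default_rng(0))
        truth = simulate_plant_params(design, cfg, np.random.default_rng(0))
        row = truth[(truth["replicate_id"].str.contains("T4-20")) &
                    (truth["day_label"] == "D9")].iloc[0]
        expected_ek = cfg.ek_means["T4"] + cfg.ek_temp_offsets[20]
        assert row["true_ek"] == pytest.approx(expected_ek)

    def test_cell_mean_recovered_at_scale(self):
        """Sample mean of 200 plants in one cell within 3 SE of the
        configured mean."""
        cfg = SimConfig.for_species("ulva", treatments=("T1",),
                                    temperatures=(27,), replicates=200)
        design = enumerate_design(cfg, np.random.default_rng(0))
        truth = simulate_plant_params(design, cfg, np.random.default_rng(1))
        d9 = truth[truth["day_label"] == "D9"]
        target = cfg.ek_means["T1"] + cfg.ek_temp_offsets[27]
        se = np.sqrt(cfg.sd_ek_plant**2 + cfg.sd_ek_replicate**2) / np.sqrt(len(d9))
        assert abs(d9["true_ek"].mean() - target) < 3 * se


class TestRLCSim:
    def test_noiseless_round_trip(self):
        cfg = SimConfig(rlc_noise_sd=0.0)
        curve = simulate_rlc(0.45, 80.0, cfg, np.random.default_rng(0))
        fit = fit_webb(curve)
        assert fit.alpha == pytest.approx(0.45, abs=1e-6)
        assert fit.ek == pytest.approx(80.0, abs=1e-4)

    def test_noisy_recovery_within_sampling_error(self, rng):
        cfg = SimConfig(rlc_noise_sd=0.01)
        eks = [fit_webb(simulate_rlc(0.5, 100.0, cfg, rng)).ek for _ in range(200)]
        assert abs(np.mean(eks) - 100.0) < 3.0

    def test_yields_clipped_to_unit_interval(self, rng):
        cfg = SimConfig(rlc_noise_sd=0.5)
        curve = simulate_rlc(0.95, 50.0, cfg, rng)
        assert np.all(curve.phi_psii <= 1.0)
        assert np.all(curve.phi_psii >= 0.0)


class TestIrradianceSim:
    def test_cloudless_profile_symmetric_peaked_at_midday(self):
        cfg = SimConfig(cloud_sd=0.0)
        s = simulate_irradiance("d", cfg, np.random.default_rng(0),
                                daylight_minutes=650)
        mid = np.argmax(s.e_par)
        assert s.minutes[mid] == pytest.approx((300 + 1170) / 2, abs=1)
        # the logging window is centred on the daylight window, so the whole
        # trace is symmetric under time reversal
        assert np.allclose(s.e_par, s.e_par[::-1], atol=1e-9)

    def test_shading_scales_linearly(self):
        full = SimConfig(shading=1.0, cloud_sd=0.2)
        half = SimConfig(shading=0.5, cloud_sd=0.2)
        a = simulate_irradiance("d", full, np.random.default_rng(5))
        b = simulate_irradiance("d", half, np.random.default_rng(5))
        assert np.allclose(b.e_par, a.e_par / 2.0)

    def test_day_length_consistent_with_configured_window(self):
        cfg = SimConfig(cloud_sd=0.2)
        s = simulate_irradiance("d", cfg, np.random.default_rng(3),
                                daylight_minutes=600)
        assert day_length(condense_series(s)) == pytest.approx(600, abs=10)


class TestGrowthSim:
    def test_deterministic_case(self):
        import pandas as pd

        cfg = SimConfig(growth_intercept=0.0, growth_dspi_slope=10.0,
                        growth_treatment_sd=0.0, growth_noise_sd=0.0,
                        w_i_range=(0.30, 0.30))
        design = enumerate_design(
            SimConfig.for_species("ulva", treatments=("T1",), temperatures=(27,),
                                  replicates=1),
            np.random.default_rng(0),
        )
        dspi_truth = pd.Series(1.2, index=design["replicate_id"])
        w = simulate_growth(design, dspi_truth, cfg, np.random.default_rng(0))
        assert w["true_growth_pct"].iloc[0] == pytest.approx(12.0)
        assert w["w_f"].iloc[0] == pytest.approx(0.30 * 1.12)

    def test_response_table_null_has_no_treatment_signal(self):
        cfg = SimConfig.for_species("ulva", replicates=8, drop_ulva_t25=False)
        design = enumerate_design(cfg, np.random.default_rng(0))
        t = simulate_response_table(design, np.random.default_rng(1),
                                    sd_plant=1, sd_run=1, sd_resid=1)
        means = t.groupby("treatment", observed=True)["y"].mean()
        assert means.std() < 1.5  # only random-effect leakage, no fixed signal


class TestEndToEndCalibration:
    def test_t0_ek_recovery_against_calibration_mean(self):
        """Curves simulated from the T0 calibration cell recover its
        configured mean E_k of 27.2 within sampling error."""
        cfg = SimConfig.for_species("ulva", treatments=("T0",), replicates=67)
        design = enumerate_design(cfg, np.random.default_rng(0))
        truth = simulate_plant_params(design, cfg, np.random.default_rng(1))
        d9 = truth[truth["day_label"] == "D9"].head(200)
        rng = np.random.default_rng(2)
        eks = [
            fit_webb(simulate_rlc(r.true_alpha, r.true_ek, cfg, rng)).ek
            for r in d9.itertuples(index=False)
        ]
        assert np.mean(eks) == pytest.approx(27.2, abs=2.0)

    def test_depigmented_curves_are_flat(self):
        cfg = SimConfig.for_species("hypnea", seed=4, replicates=2)
        study = simulate_study(cfg)
        depig = study.design[
            study.design["exclusion_reason"].str.contains("depigmented")
        ]["replicate_id"]
        assert len(depig) == 2
        flat = [
            c for c in study.curves
            if c.plant_id in set(depig) and c.day_label == "D9"
        ]
        assert flat and all(np.all(c.phi_psii == 0) for c in flat)
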