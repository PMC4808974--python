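"""Generator structure: determinism, gradients, ground truth, violations."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from greenbirth.exposure import assign_exposure
from greenbirth.synthetic_data import (SimConfig, community_layout,
                                       simulate_cohort, simulate_point_layers,
                                       simulate_raster)


def small_config(**overrides):
    base = dict(seed=5,
                n_births={"city": 600, "borough": 600, "township": 800},
                n_communities={"city": 6, "borough": 6, "township": 8})
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_births={"city": -1, "borough": 0, "township": 0}).validate()

    def test_births_without_communities_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_communities={"city": 0, "borough": 6,
                                        "township": 8}).validate()

    def test_race_mixture_must_sum_to_one(self):
        cfg = small_config()
        cfg.race_props["city"] = {"white": 0.5, "black": 0.2,
                                  "hispanic": 0.2, "other": 0.2}
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            small_config(resolution_m=0.0).validate()


class TestRaster:
    def test_degenerate_field_is_constant(self):
        cfg = small_config(
            ndvi_base={"city": 0.5, "borough": 0.5, "township": 0.5},
            ndvi_between_community_sd=0.0, ndvi_within_community_sd=0.0,
            season_ndvi_amplitude=0.0, ndvi_noise_sd=0.0)
        r = simulate_raster(cfg)
        assert np.allclose(r.values, 0.5)

    def test_city_zones_less_green_than_townships(self, medium_config,
                                                  medium_raster):
        layout = community_layout(medium_config)
        mean_by_type = {}
        res = medium_config.resolution_m
        for t in ("city", "township"):
            vals = []
            for _, c in layout[layout["community_type"] == t].iterrows():
                j0, j1 = int(c["x0"] // res), int(c["x1"] // res)
                i0, i1 = int(c["y0"] // res), int(c["y1"] // res)
                vals.append(medium_raster.values[:, i0:i1, j0:j1].mean())
            mean_by_type[t] = np.mean(vals)
        assert mean_by_type["city"] < mean_by_type["township"]

    def test_values_in_valid_range(self, medium_raster):
        assert medium_raster.values.min() >= -1.0
        assert medium_raster.values.max() <= 1.0

    def test_seasonal_cycle_peaks_in_summer(self, medium_raster):
        by_month = {}
        for k, d in enumerate(medium_raster.dates):
            by_month.setdefault(d.month, []).append(medium_raster.values[k].mean())
        means = {m: np.mean(v) for m, v in by_month.items()}
        assert means[7] > means[1]


class TestCohort:
    def test_determinism(self):
        cfg = small_config()
        r = simulate_raster(cfg)
        c1, t1 = simulate_cohort(cfg, r)
        c2, t2 = simulate_cohort(cfg, r)
        pd.testing.assert_frame_equal(
            c1.drop(columns="smoking_dates"), c2.drop(columns="smoking_dates"))
        assert np.array_equal(t1.exposed, t2.exposed)

    def test_true_conditional_or_built_in(self):
        cfg = small_config()
        r = simulate_raster(cfg)
        _, truth = simulate_cohort(cfg, r)
        p0 = truth.potential_probs["preterm_p0"].to_numpy()
        p1 = truth.potential_probs["preterm_p1"].to_numpy()
        implied = (p1 / (1 - p1)) / (p0 / (1 - p0))
        # city births carry the planted conditional OR; elsewhere it is null
        city = np.array([t == "city" for t in
                         simulate_cohort(cfg, r)[0]["community_type"]])
        assert np.allclose(implied[city], 0.78)
        assert np.allclose(implied[~city], 1.0)

    def test_null_model_crude_log_or_near_zero(self):
        eff = {t: {"preterm": 0.0, "sga": 0.0, "low_apgar": 0.0,
                   "term_weight": 0.0} for t in ("city", "borough", "township")}
        cfg = SimConfig(seed=11, confounding_strength=0.0, true_effects=eff,
                        n_births={"city": 20_000, "borough": 0, "township": 0},
                        n_communities={"city": 20, "borough": 0, "township": 0})
        r = simulate_raster(cfg)
        cohort, truth = simulate_cohort(cfg, r)
        y = (cohort["gestational_age_weeks"] < 37).to_numpy()
        a = truth.exposed.astype(bool)
        log_or = math.log((y[a].mean() / (1 - y[a].mean()))
                          / (y[~a].mean() / (1 - y[~a].mean())))
        # crude equals marginal oracle from the potential-outcome probabilities
        p1 = truth.potential_probs["preterm_p1"].to_numpy()
        p0 = truth.potential_probs["preterm_p0"].to_numpy()
        oracle = math.log((p1.mean() / (1 - p1.mean()))
                          / (p0.mean() / (1 - p0.mean())))
        assert log_or == pytest.approx(oracle, abs=0.12)
        assert abs(log_or) < 0.12

    def test_multiple_births_share_mother_and_address(self):
        cfg = small_config(multiple_birth_rate=0.2)
        r = simulate_raster(cfg)
        cohort, _ = simulate_cohort(cfg, r)
        per_mother = cohort.groupby("mother_id").agg(
            n=("birth_id", "size"), nx=("x", "nunique"))
        frac_two = (per_mother["n"] >= 2).mean()
        assert frac_two == pytest.approx(0.2, abs=0.02)
        assert (per_mother["nx"] == 1).all()

    def test_structural_violation_stratum_never_exposed(self):
        cfg = small_config(structural_overlap_violation=True,
                           n_births={"city": 1500, "borough": 0, "township": 0},
                           n_communities={"city": 8, "borough": 0,
                                          "township": 0})
        r = simulate_raster(cfg)
        cohort, truth = simulate_cohort(cfg, r)
        members = truth.overlap_stratum.astype(bool)
        assert members.sum() > 50
        # exhaustive count: exposure probability exactly zero in the stratum
        assert truth.exposed[members].sum() == 0
        assert (cohort.loc[members, "subsidized_housing"] == 1).all()

    def test_city_t1_prevalences_near_published(self, medium_cohort,
                                                medium_frame):
        cohort, truth = medium_cohort
        city_t1 = medium_frame[(medium_frame["community_type"] == "city")
                               & (medium_frame["tertile"] == 1)]
        assert city_t1["preterm"].mean() == pytest.approx(0.137, abs=0.03)
        assert city_t1["sga"].mean() == pytest.approx(0.136, abs=0.03)
        assert city_t1["low_apgar"].mean() == pytest.approx(0.018, abs=0.03)

    def test_addresses_inside_community_rectangles(self, medium_config,
                                                   medium_cohort):
        cohort, _ = medium_cohort
        layout = community_layout(medium_config).set_index("community_id")
        z = layout.loc[cohort["community_id"]]
        assert (cohort["x"].to_numpy() >= z["x0"].to_numpy()).all()
        assert (cohort["x"].to_numpy() <= z["x1"].to_numpy()).all()
        assert (cohort["y"].to_numpy() >= z["y0"].to_numpy()).all()
        assert (cohort["y"].to_numpy() <= z["y1"].to_numpy()).all()


class TestPointLayers:
    def test_zero_afos_background_exposure(self):
        from greenbirth.covariates import afo_exposure
        cfg = small_config(n_afos=0)
        layers = simulate_point_layers(cfg)
        assert afo_exposure((100.0, 100.0), layers["afo"]) == 0.0

    def test_wells_drilled_after_births_count_zero(self):
        from greenbirth.covariates import wells_within
        cfg = small_config()
        layers = simulate_point_layers(cfg)
        wells = layers["wells"].copy()
        wells["drill_date"] = date(2099, 1, 1)
        assert wells_within((0.0, 0.0), wells, date(2010, 1, 1)) == 0

    def test_layers_deterministic(self):
        cfg = small_config()
        l1 = simulate_point_layers(cfg)
        l2 = simulate_point_layers(cfg)
        for name in ("afo", "wells", "roads"):
            pd.testing.assert_frame_equal(l1[name], l2[name])

    def test_afos_carry_positive_animal_units(self):
        layers = simulate_point_layers(small_config())
        assert (layers["afo"]["animal_units"] > 0).all()
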