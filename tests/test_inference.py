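"""Outcome regression, LRT screening, semivariogram, sensitivity variants."""

import numpy as np
import pandas as pd
import pytest

from greenbirth import inference
from greenbirth.datasets import expand_2x2, table1_counts
from greenbirth.inference import (ModelSpec, continuous_ndvi_model,
                                  effect_modification, fit_outcome_model,
                                  lrt_select_interactions,
                                  residual_semivariogram)


def _unadjusted_spec(outcome="event"):
    return ModelSpec(outcome, "logistic", covariates=[], cluster=None)


class TestUnadjustedOddsRatios:
    def test_city_preterm_matches_published_table(self):
        t1 = table1_counts().set_index(["community_type", "tertile"])
        e = t1.loc[("city", "2-3")]
        u = t1.loc[("city", "1")]
        df = expand_2x2(e["n"], e["preterm"], u["n"], u["preterm"])
        est = fit_outcome_model(df, _unadjusted_spec(), "city")
        assert round(est.estimate, 2) == 0.85

    def test_township_preterm_matches_published_table(self):
        t1 = table1_counts().set_index(["community_type", "tertile"])
        e = t1.loc[("township", "2-3")]
        u = t1.loc[("township", "1")]
        df = expand_2x2(e["n"], e["preterm"], u["n"], u["preterm"])
        est = fit_outcome_model(df, _unadjusted_spec(), "township")
        assert round(est.estimate, 2) == 1.00

    def test_logistic_or_equals_cross_product_ratio(self):
        df = expand_2x2(300, 40, 500, 45)
        est = fit_outcome_model(df, _unadjusted_spec())
        cpr = (40 / 260) / (45 / 455)
        assert est.estimate == pytest.approx(cpr, abs=1e-6)


def test_one_cluster_per_row_matches_hc_robust():
    rng = np.random.default_rng(0)
    n = 300
    df = pd.DataFrame({"x": rng.normal(size=n), "g": np.arange(n)})
    df["event"] = (rng.random(n) < 1 / (1 + np.exp(-df["x"]))).astype(float)
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    m = smf.glm("event ~ x", data=df, family=sm.families.Binomial())
    se_cluster = m.fit(cov_type="cluster",
                       cov_kwds={"groups": df["g"]}).bse["x"]
    se_hc = m.fit(cov_type="HC1").bse["x"]
    assert se_cluster == pytest.approx(se_hc, rel=0.02)


class TestAdjustedModels:
    def test_binary_exposure_levels_required(self, medium_frame):
        df = medium_frame[medium_frame["exposed"] == 1]
        with pytest.raises(ValueError, match="exposure"):
            fit_outcome_model(df, ModelSpec("preterm", "logistic"))

    def test_birth_weight_model_includes_gestational_age(self):
        spec = ModelSpec("term_birth_weight_g", "linear")
        assert "gestational_age_weeks" in spec.covariates
        with pytest.raises(ValueError):
            ModelSpec("term_birth_weight_g", "logistic")

    def test_city_fit_returns_sane_estimate(self, medium_frame):
        df = medium_frame[medium_frame["community_type"] == "city"]
        est = fit_outcome_model(df, ModelSpec("preterm", "logistic"), "city")
        assert 0.2 < est.estimate < 2.0
        assert est.ci_low < est.estimate < est.ci_high
        assert est.n > 1000


class TestLrtSelection:
    def test_duplicate_column_not_retained(self, medium_frame):
        df = medium_frame[medium_frame["community_type"] == "township"]
        spec = ModelSpec("preterm", "logistic")
        out, log = lrt_select_interactions(df, spec, ["is_smoker"])
        # is_smoker duplicates C(smoking): zero LRT improvement
        assert log[0]["lr_stat"] == pytest.approx(0.0, abs=1e-6)
        assert not log[0]["retained"]
        assert out.interactions == []

    def test_no_candidates_leaves_spec_unchanged(self, medium_frame):
        df = medium_frame[medium_frame["community_type"] == "city"]
        spec = ModelSpec("preterm", "logistic")
        out, log = lrt_select_interactions(df, spec, [])
        assert out.covariates == spec.covariates
        assert log == []

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(1)
        n = 5000
        df = pd.DataFrame({
            "exposed": rng.integers(0, 2, n),
            "age_c": rng.normal(size=n),
            "is_smoker": rng.integers(0, 2, n).astype(float),
            "community_id": rng.integers(0, 20, n),
        })
        eta = -2 + 0.3 * df["age_c"] + 0.2 * df["is_smoker"] \
            + 0.8 * df["age_c"] * df["is_smoker"]
        df["preterm"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        spec = ModelSpec("preterm", "logistic",
                         covariates=["age_c", "is_smoker"])
        out, log = lrt_select_interactions(df, spec, ["age_c:is_smoker"])
        assert log[0]["retained"]
        assert log[0]["p"] < 0.001


class TestEffectModification:
    def test_constant_modifier_errors(self, medium_frame):
        df = medium_frame[medium_frame["community_type"] == "city"].copy()
        df["medical_assistance"] = "ever"
        with pytest.raises(ValueError, match="constant"):
            effect_modification(df, ModelSpec("preterm", "logistic"),
                                "medical_assistance")

    def test_planted_modification_detected(self):
        rng = np.random.default_rng(2)
        n = 10_000
        df = pd.DataFrame({
            "exposed": rng.integers(0, 2, n),
            "medical_assistance": rng.choice(["never", "ever"], n),
            "age_c": rng.normal(size=n),
            "community_id": rng.integers(0, 25, n),
        })
        ma = (df["medical_assistance"] == "ever").astype(float)
        eta = -2 + 0.2 * ma - 0.1 * df["exposed"] + 0.5 * df["exposed"] * ma
        df["preterm"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        spec = ModelSpec("preterm", "logistic",
                         covariates=["age_c", "C(medical_assistance)"])
        out = effect_modification(df, spec, "medical_assistance")
        assert out["lrt_p"] < 0.05
        assert out["wald_p"] < 0.05


class TestContinuousNdvi:
    def test_null_effect_near_zero(self, medium_frame):
        df = medium_frame[medium_frame["community_type"] == "township"]
        spec = ModelSpec("term_birth_weight_g", "linear")
        est = continuous_ndvi_model(df, spec, "township")
        # default township truth is a null weight effect
        assert est.ci_low < 0 < est.ci_high or abs(est.estimate) < 30

    def test_quadratic_truth_flagged_by_lrt(self, medium_frame):
        rng = np.random.default_rng(3)
        df = medium_frame[medium_frame["community_type"] == "township"].copy()
        df = df[df["gestational_age_weeks"] >= 37]
        x = df["ndvi"].to_numpy()
        df["term_birth_weight_g"] = (3300 + 25_000 * (x - x.mean()) ** 2
                                     + rng.normal(0, 300, len(df)))
        spec = ModelSpec("term_birth_weight_g", "linear")
        est = continuous_ndvi_model(df, spec, "township")
        assert est.extras["lrt_p_quadratic"] < 0.01


class TestSemivariogram:
    def test_iid_residuals_flat(self):
        rng = np.random.default_rng(4)
        n = 600
        coords = rng.uniform(0, 10_000, size=(n, 2))
        resid = rng.normal(size=n)
        edges = np.linspace(0, 8000, 9)
        sv = residual_semivariogram(resid, coords, edges, seed=0)
        good = sv.dropna(subset=["gamma"])
        good = good[good["n_pairs"] > 2000]
        rel_dev = (good["gamma"] - good["gamma"].mean()).abs() / good["gamma"].mean()
        assert rel_dev.max() < 0.15

    def test_smooth_spatial_signal_rises_with_lag(self):
        rng = np.random.default_rng(5)
        n = 500
        coords = rng.uniform(0, 10_000, size=(n, 2))
        resid = np.sin(coords[:, 0] / 3000.0) + rng.normal(0, 0.05, n)
        edges = np.array([0, 1500, 6000])
        sv = residual_semivariogram(resid, coords, edges, seed=0)
        assert sv["gamma"].iloc[0] < sv["gamma"].iloc[1]

    def test_duplicate_points_same_residual_zero_gamma(self):
        coords = np.zeros((10, 2))
        resid = np.full(10, 1.7)
        sv = residual_semivariogram(resid, coords, np.array([-0.5, 0.5, 1.5]))
        assert sv["gamma"].iloc[0] == 0.0
        assert sv["empty"].iloc[1]

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError):
            residual_semivariogram(np.zeros(5), np.zeros((5, 2)),
                                   np.array([0, 1]))


def test_sensitivity_suite_runs_all_variants(medium_frame, medium_cohort,
                                             medium_raster):
    cohort, _ = medium_cohort
    city = medium_frame[medium_frame["community_type"] == "city"]
    sub_cohort = cohort[cohort["birth_id"].isin(city["birth_id"])]
    spec = ModelSpec("preterm", "logistic")
    out = inference.sensitivity_suite(city, sub_cohort, medium_raster, spec,
                                      community_type="city", seed=0)
    assert len(out["variants"]) == 12  # {mean,max} x {250,1250} x 3 contrasts
    assert out["spearman"].loc["mean_250", "mean_1250"] > 0.7
    assert out["restricted"].n <= out["unrestricted"].n
    assert (out["variants"]["estimate"] > 0).all()
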