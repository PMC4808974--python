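"""Replicate-level simulation studies of the pipeline's operating
characteristics: parameter recovery under confounding, the structural-
confounding repair from common-support trimming, and the super-learner
risk guarantee. These are the package's own verification experiments, run
at desk scale."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, propensity, support
from .covariates import build_covariate_panel
from .exposure import assign_exposure
from .outcomes import apply_exclusions, build_growth_reference, classify_outcomes
from .synthetic_data import (SimConfig, simulate_cohort, simulate_point_layers,
                             simulate_raster)

__all__ = ["city_config", "run_city_replicate", "recovery_study",
           "null_calibration_study", "structural_confounding_study",
           "superlearner_study", "trim_oracle_study"]


def city_config(seed: int, n_births: int = 2500,
                violation: bool = False, null_effects: bool = False) -> SimConfig:
    """City-only study conditions used by the replicate experiments."""
    cfg = SimConfig(
        seed=seed,
        n_births={"city": n_births, "borough": 0, "township": 0},
        n_communities={"city": 24, "borough": 0, "township": 0},
        structural_overlap_violation=violation,
    )
    if null_effects:
        cfg.true_effects = {
            t: {"preterm": 0.0, "sga": 0.0, "low_apgar": 0.0,
                "term_weight": 0.0}
            for t in cfg.true_effects}
    return cfg


def _city_frame(cfg: SimConfig):
    raster = simulate_raster(cfg)
    cohort, truth = simulate_cohort(cfg, raster)
    included, _ = apply_exclusions(cohort)
    expo = assign_exposure(included, raster, 250.0, "mean", extra_radii=())
    layers = simulate_point_layers(cfg)
    panel = build_covariate_panel(included, layers["layout"], layers)
    reference = build_growth_reference(included)
    out = classify_outcomes(included, reference)
    frame = inference.build_model_frame(included, panel, expo, out)
    return frame, truth


def _structural_library(seed: int):
    """Logistic + shallow boosted trees: the trees isolate the no-overlap
    covariate cell that a main-effects logistic model cannot."""
    from sklearn.ensemble import GradientBoostingClassifier
    lib = propensity.fast_library()
    lib.append(("gbt", GradientBoostingClassifier(
        max_depth=2, n_estimators=80, random_state=int(seed) % 2**31)))
    return lib


def run_city_replicate(seed: int, n_births: int = 2500,
                       outcomes: tuple[str, ...] = ("preterm", "sga"),
                       violation: bool = False, V: int = 5,
                       library=None, null_effects: bool = False) -> dict:
    """One simulate->expose->propensity->trim->fit cycle on city births.

    Returns per-outcome trimmed (and, with a violation, untrimmed)
    estimates plus the generating truth.
    """
    cfg = city_config(seed, n_births, violation, null_effects)
    frame, truth = _city_frame(cfg)
    sub = frame[frame["community_type"] == "city"].reset_index(drop=True)
    X = sub[inference.PROPENSITY_COVARIATES]
    if library is None:
        library = propensity.fast_library()
    fit = propensity.fit_propensity(X, sub["exposed"].to_numpy(),
                                    library=library, V=V, seed=seed)
    retained, bounds = support.trim(fit.scores, sub["exposed"].to_numpy())

    res: dict = {"seed": seed, "bounds": bounds,
                 "truth": {o: truth.true_effects["city"][o] for o in outcomes}}
    for o in outcomes:
        spec = inference.ModelSpec(o, "logistic")
        est = inference.fit_outcome_model(sub[retained], spec, "city")
        res[f"{o}_or"] = est.estimate
        res[f"{o}_ci"] = (est.ci_low, est.ci_high)
        if violation:
            unres = inference.fit_outcome_model(sub, spec, "city")
            res[f"{o}_or_untrimmed"] = unres.estimate
    return res


def recovery_study(n_replicates: int = 200, n_births: int = 2500,
                   seed: int = 0,
                   outcomes: tuple[str, ...] = ("preterm", "sga"),
                   ) -> pd.DataFrame:
    """Recover the planted city preterm and SGA odds ratios with CIs."""
    rows = []
    for r in range(n_replicates):
        rep = run_city_replicate((seed * 100_003 + r + 1) % 2**31, n_births,
                                 outcomes=outcomes)
        row = {"replicate": r}
        for o in outcomes:
            true_or = math.exp(rep["truth"][o])
            lo, hi = rep[f"{o}_ci"]
            row[f"{o}_or"] = rep[f"{o}_or"]
            row[f"{o}_true_or"] = true_or
            row[f"{o}_covered"] = lo <= true_or <= hi
            row[f"{o}_rejects_null"] = not (lo <= 1.0 <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def null_calibration_study(n_replicates: int = 100, n_births: int = 2500,
                           seed: int = 0,
                           outcome: str = "preterm") -> pd.DataFrame:
    """Type-I error of the exposure test when every true effect is null.

    Preterm is the default calibration outcome: with ~11% prevalence its
    event count supports the full adjustment model, so rejection of the
    null measures the test's size rather than small-sample artefacts.
    """
    rows = []
    for r in range(n_replicates):
        rep = run_city_replicate((seed * 100_003 + r + 1) % 2**31, n_births,
                                 outcomes=(outcome,), null_effects=True)
        lo, hi = rep[f"{outcome}_ci"]
        rows.append({"replicate": r, "or": rep[f"{outcome}_or"],
                     "rejects": not (lo <= 1.0 <= hi)})
    return pd.DataFrame(rows)


def structural_confounding_study(n_replicates: int = 100,
                                 n_births: int = 3000,
                                 seed: int = 0) -> pd.DataFrame:
    """Trimmed vs untrimmed bias under a planted no-overlap stratum."""
    rows = []
    for r in range(n_replicates):
        rs = (seed * 100_003 + r + 1) % 2**31
        rep = run_city_replicate(rs, n_births, outcomes=("preterm",),
                                 violation=True,
                                 library=_structural_library(rs))
        true_log = rep["truth"]["preterm"]
        bias_trim = math.log(rep["preterm_or"]) - true_log
        bias_untrim = math.log(rep["preterm_or_untrimmed"]) - true_log
        rows.append({"replicate": r, "bias_trimmed": bias_trim,
                     "bias_untrimmed": bias_untrim,
                     "trim_better": abs(bias_trim) < abs(bias_untrim)})
    return pd.DataFrame(rows)


def _grid_search_weight(z0: np.ndarray, z1: np.ndarray, y: np.ndarray,
                        step: float = 0.001) -> float:
    """1-simplex grid-search oracle for the two-learner weight."""
    ws = np.arange(0.0, 1.0 + step / 2, step)
    best_w, best = 0.0, np.inf
    for w in ws:
        nll = propensity.binomial_nll(w * z0 + (1 - w) * z1, y)
        if nll < best:
            best, best_w = nll, w
    return best_w


def superlearner_study(n_datasets: int = 50, n: int = 400,
                       seed: int = 0) -> pd.DataFrame:
    """Risk-guarantee and oracle-weight checks on synthetic logistic data."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_datasets):
        X = rng.normal(size=(n, 4))
        beta = rng.normal(scale=0.8, size=4)
        p = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random(n) < p).astype(float)
        fit = propensity.fit_propensity(
            X, y, library=propensity.default_library(d), V=5, seed=d)
        gap = fit.ensemble_risk - min(fit.learner_risks.values())

        # two-learner weight vs the grid-search oracle
        z_true = np.clip(p + rng.normal(scale=0.02, size=n), 0.01, 0.99)
        z_flat = np.full(n, 0.5)
        Z = np.column_stack([z_true, z_flat])
        w = propensity.solve_weights(Z, y)
        w_oracle = _grid_search_weight(z_true, z_flat, y)
        rows.append({"dataset": d, "risk_gap": gap,
                     "weight_error": abs(w[0] - w_oracle)})
    return pd.DataFrame(rows)


def _trim_oracle(scores: np.ndarray, exposed: np.ndarray
                 ) -> tuple[np.ndarray, float, float]:
    lo = np.percentile(np.sort(scores[exposed.astype(bool)]), 1.0)
    hi = np.percentile(np.sort(scores[~exposed.astype(bool)]), 99.0)
    return (scores >= lo) & (scores <= hi), lo, hi


def trim_oracle_study(n_instances: int = 1000, seed: int = 0) -> dict:
    """trim() vs the brute-force sort/percentile/filter oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        n = int(rng.integers(20, 400))
        exposed = np.zeros(n, dtype=int)
        exposed[: int(rng.integers(5, n - 4))] = 1
        rng.shuffle(exposed)
        scores = rng.beta(2, 2, size=n)
        ret, bounds = support.trim(scores, exposed)
        ret_o, lo, hi = _trim_oracle(scores, exposed)
        if not (np.array_equal(ret, ret_o)
                and math.isclose(bounds.lower, lo)
                and math.isclose(bounds.upper, hi)):
            mismatches += 1

    # identical score distributions: ~1% trimmed per group
    n = 1000
    scores = np.concatenate([rng.beta(2, 2, n), rng.beta(2, 2, n)])
    exposed = np.repeat([1, 0], n)
    _, bounds = support.trim(scores, exposed)
    return {"n_instances": n_instances, "mismatches": mismatches,
            "frac_excluded_exposed": bounds.frac_exposed_own_tail,
            "frac_excluded_unexposed": bounds.frac_unexposed_own_tail}
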