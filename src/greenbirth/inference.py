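"""Community-stratified outcome models with cluster-robust inference.

Linear (term birth weight) and logistic (preterm, small-for-gestational-
age, low Apgar) regressions of each outcome on the greenness contrast and
the adjustment covariate set, fit on the common-support-restricted sample
per community type. Standard errors come from a one-way clustered sandwich
at the community level; interactions are screened by likelihood-ratio
tests; a residual semivariogram checks for leftover spatial structure; and
a sensitivity suite re-runs the contrast under alternative exposure
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import chi2, spearmanr

from . import propensity as ps
from . import support
from .exposure import RasterStack, assign_exposure, dichotomize_at_percentile

__all__ = [
    "ModelSpec", "EffectEstimate", "SeparationError",
    "DEFAULT_ADJUSTMENT", "PROPENSITY_COVARIATES",
    "build_model_frame", "fit_outcome_model", "lrt_select_interactions",
    "effect_modification", "continuous_ndvi_model",
    "residual_semivariogram", "sensitivity_suite",
]

# adjustment covariates of the primary models (formula terms)
DEFAULT_ADJUSTMENT = [
    "C(sex)", "C(year_band)", "C(season_of_birth)",
    "age_c", "age_c2",
    "C(race3)", "C(primary_care)", "C(smoking)", "C(bmi_class)",
    "C(parity)", "C(medical_assistance)", "antibiotic_orders",
    "road_distance_m", "C(water_source)", "wells_20km", "afo_exposure",
    "walkability", "C(csd_quartile)", "C(delivery_hospital)",
]

# columns fed to the propensity learners (numeric design)
PROPENSITY_COVARIATES = [
    "maternal_age", "is_black", "is_hispanic", "is_smoker", "is_ma",
    "prenatal_visits", "wells_20km", "afo_exposure", "road_distance_m",
    "walkability", "csd", "antibiotic_orders", "is_multiparous",
    "bmi", "is_winter", "is_spring", "is_summer",
]


class SeparationError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    outcome: str
    family: Literal["linear", "logistic"]
    exposure_term: Literal["binary", "continuous"] = "binary"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    interactions: list[str] = field(default_factory=list)
    cluster: str | None = "community_id"

    def __post_init__(self) -> None:
        if self.outcome == "term_birth_weight_g":
            if self.family != "linear":
                raise ValueError("birth-weight model must be linear")
            if "gestational_age_weeks" not in self.covariates:
                self.covariates = self.covariates + ["gestational_age_weeks"]

    @property
    def exposure_var(self) -> str:
        return "exposed" if self.exposure_term == "binary" else "ndvi_per01"

    def formula(self, extra: Sequence[str] = ()) -> str:
        terms = [self.exposure_var, *self.covariates, *self.interactions, *extra]
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class EffectEstimate:
    outcome: str
    community_type: str
    family: str
    term: str
    estimate: float          # OR for logistic, beta (grams) for linear
    ci_low: float
    ci_high: float
    se: float                # cluster-robust, on the coefficient scale
    coef: float              # raw coefficient (log-OR or grams)
    n: int
    n_dropped: int
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return (f"{self.community_type}/{self.outcome}: "
                f"{self.estimate:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})")


def build_model_frame(cohort: pd.DataFrame, panel: pd.DataFrame,
                      exposure_df: pd.DataFrame,
                      outcomes_df: pd.DataFrame) -> pd.DataFrame:
    """Merge cohort, covariate panel, exposure and outcomes on birth_id and
    derive the model columns (centered age, indicator recodes, NDVI/0.1)."""
    df = cohort.merge(panel.drop(columns=[c for c in panel.columns
                                          if c in cohort.columns and c != "birth_id"]),
                      on="birth_id")
    keep = [c for c in exposure_df.columns if c not in df.columns or c == "birth_id"]
    df = df.merge(exposure_df[keep], on="birth_id")
    keep = [c for c in outcomes_df.columns if c not in df.columns or c == "birth_id"]
    df = df.merge(outcomes_df[keep], on="birth_id")

    df["age_c"] = df["maternal_age"] - df["maternal_age"].mean()
    df["age_c2"] = df["age_c"] ** 2
    df["ndvi_per01"] = df["ndvi"] / 0.1
    # models use the 3-level race variable; the rare residual level joins
    # the reference category
    df["race3"] = df["race_ethnicity"].replace({"other": "white"})
    df["is_black"] = (df["race_ethnicity"] == "black").astype(float)
    df["is_hispanic"] = (df["race_ethnicity"] == "hispanic").astype(float)
    df["is_smoker"] = (df["smoking"] == "ever").astype(float)
    df["is_ma"] = (df["medical_assistance"] == "ever").astype(float)
    df["is_multiparous"] = (df["parity"] == "multiparous").astype(float)
    df["bmi"] = df["pre_pregnancy_bmi"].astype(float)
    for s in ("winter", "spring", "summer"):
        df[f"is_{s}"] = (df["season_of_birth"] == s).astype(float)
    return df


def _used_columns(df: pd.DataFrame, spec: ModelSpec,
                  extra: Sequence[str] = ()) -> list[str]:
    import re
    cols = set()
    for term in [spec.outcome, spec.exposure_var, *spec.covariates,
                 *spec.interactions, *extra]:
        for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term):
            if name in df.columns:
                cols.add(name)
    if spec.cluster:
        cols.add(spec.cluster)
    return sorted(cols)


def _fit_glm(df: pd.DataFrame, spec: ModelSpec, formula: str):
    fam = sm.families.Binomial() if spec.family == "logistic" \
        else sm.families.Gaussian()
    model = smf.glm(formula, data=df, family=fam)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    if spec.cluster:
        # t-based inference with G-1 df: the standard small-sample practice
        # for one-way clustered sandwich errors
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df[spec.cluster]}, use_t=True)
    else:
        res = model.fit()
    if spec.family == "logistic":
        big = np.abs(res.params) > 15
        if big.any():
            raise SeparationError(
                "possible separation in covariate(s): "
                + ", ".join(res.params.index[big]))
    return res


def _collapse_degenerate_levels(data: pd.DataFrame, spec: ModelSpec
                                ) -> tuple[pd.DataFrame, dict]:
    """Merge categorical adjustment levels with zero (or all) events into
    the variable's largest regular level.

    Such cells carry no information about the conditional exposure effect
    but drive their dummy coefficient to +/- infinity (quasi-separation);
    collapsing keeps the rows and stabilizes the fit. Collapses are
    reported in the model audit.
    """
    import re
    collapsed: dict[str, dict] = {}
    for term in spec.covariates:
        m = re.fullmatch(r"C\((\w+)\)", term)
        if not m:
            continue
        col = m.group(1)
        ev = data.groupby(col, observed=True)[spec.outcome].agg(["size", "sum"])
        bad = ev[(ev["sum"] == 0) | (ev["sum"] == ev["size"])].index
        if len(bad) == 0 or len(ev) - len(bad) < 1:
            continue
        good = ev.drop(bad)["size"].idxmax()
        if not collapsed:
            data = data.copy()
        data.loc[data[col].isin(bad), col] = good
        collapsed[col] = {str(b): str(good) for b in bad}
    return data, collapsed


def fit_outcome_model(df: pd.DataFrame, spec: ModelSpec,
                      community_type: str = "all") -> EffectEstimate:
    """Fit one outcome model on (a community-type slice of) the restricted
    sample and report the exposure effect with a cluster-robust 95% CI."""
    use = _used_columns(df, spec)
    data = df[use].dropna()
    n_dropped = len(df) - len(data)
    k_params = 2 + len(spec.covariates) + len(spec.interactions)
    if len(data) < 10 * k_params:
        raise ValueError(f"too few complete cases ({len(data)}) for "
                         f"~{k_params} parameters")
    if spec.exposure_term == "binary" and data[spec.exposure_var].nunique() < 2:
        raise ValueError("both exposure levels must be present")

    collapsed: dict[str, dict] = {}
    if spec.family == "logistic":
        data, collapsed = _collapse_degenerate_levels(data, spec)

    res = _fit_glm(data, spec, spec.formula())
    term = spec.exposure_var
    coef = float(res.params[term])
    se = float(res.bse[term])
    ci = res.conf_int()
    lo, hi = float(ci.loc[term, 0]), float(ci.loc[term, 1])
    if spec.family == "logistic":
        est, lo, hi = np.exp(coef), np.exp(lo), np.exp(hi)
    else:
        est = coef
    return EffectEstimate(
        outcome=spec.outcome, community_type=community_type,
        family=spec.family, term=term, estimate=float(est),
        ci_low=float(lo), ci_high=float(hi), se=se, coef=coef,
        n=int(res.nobs), n_dropped=n_dropped,
        extras={"llf": float(res.llf), "collapsed_levels": collapsed},
    )


def _lrt(df: pd.DataFrame, spec: ModelSpec, extra: Sequence[str]
         ) -> tuple[float, float, int]:
    """LRT p-value for adding ``extra`` terms (ML fit, identical rows)."""
    use = _used_columns(df, spec, extra)
    data = df[use].dropna()
    spec_plain = ModelSpec(spec.outcome, spec.family, spec.exposure_term,
                           list(spec.covariates), list(spec.interactions),
                           cluster=None)
    base = smf.glm(spec_plain.formula(),
                   data=data,
                   family=sm.families.Binomial() if spec.family == "logistic"
                   else sm.families.Gaussian()).fit()
    full = smf.glm(spec_plain.formula(extra),
                   data=data,
                   family=sm.families.Binomial() if spec.family == "logistic"
                   else sm.families.Gaussian()).fit()
    df_diff = int(full.df_model - base.df_model)
    stat = max(0.0, 2.0 * (full.llf - base.llf))
    if df_diff <= 0:
        return stat, 1.0, 0
    return stat, float(chi2.sf(stat, df_diff)), df_diff


def lrt_select_interactions(df: pd.DataFrame, spec: ModelSpec,
                            candidates: Sequence[str],
                            alpha: float = 0.05) -> tuple[ModelSpec, list[dict]]:
    """Greedy forward pass over candidate interaction terms in given order;
    retain each whose likelihood-ratio test improves fit at ``alpha``."""
    log = []
    current = ModelSpec(spec.outcome, spec.family, spec.exposure_term,
                        list(spec.covariates), list(spec.interactions),
                        spec.cluster)
    for cand in candidates:
        stat, p, df_diff = _lrt(df, current, [cand])
        keep = (p < alpha) and df_diff > 0
        log.append({"term": cand, "lr_stat": stat, "df": df_diff,
                    "p": p, "retained": keep})
        if keep:
            current.interactions.append(cand)
    return current, log


def effect_modification(df: pd.DataFrame, spec: ModelSpec,
                        modifier: str) -> dict:
    """Exposure-by-modifier interaction with cluster-robust Wald and LRT."""
    col = modifier if modifier in df.columns else None
    if col is None:
        raise ValueError(f"modifier {modifier!r} not in data")
    use = _used_columns(df, spec, [col])
    data = df[use].dropna()
    if data[col].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant")
    inter = f"{spec.exposure_var}:C({col})"
    res = _fit_glm(data, spec, spec.formula([inter]))
    names = [nm for nm in res.params.index if nm.startswith(f"{spec.exposure_var}:C(")]
    wald = res.wald_test(" = ".join(names) + " = 0" if len(names) > 1
                         else names[0] + " = 0", scalar=True)
    _, lrt_p, df_diff = _lrt(data, spec, [inter])
    return {
        "modifier": modifier,
        "interaction_terms": {nm: (float(res.params[nm]), float(res.bse[nm]))
                              for nm in names},
        "wald_p": float(wald.pvalue),
        "lrt_p": lrt_p,
        "df": df_diff,
        "n": int(res.nobs),
    }


def continuous_ndvi_model(df: pd.DataFrame, spec: ModelSpec,
                          community_type: str = "all") -> EffectEstimate:
    """Effect per 0.1-unit NDVI increase, plus nonlinearity LRT p-values."""
    cspec = ModelSpec(spec.outcome, spec.family, "continuous",
                      list(spec.covariates), list(spec.interactions),
                      spec.cluster)
    est = fit_outcome_model(df, cspec, community_type)
    _, p_quad, _ = _lrt(df, cspec, ["I(ndvi_per01**2)"])
    _, p_cubic, _ = _lrt(df, cspec, ["I(ndvi_per01**2)", "I(ndvi_per01**3)"])
    est.extras["lrt_p_quadratic"] = p_quad
    est.extras["lrt_p_cubic"] = p_cubic
    return est


def residual_semivariogram(residuals: np.ndarray, coords: np.ndarray,
                           bin_edges: np.ndarray,
                           max_pairs: int = 200_000,
                           seed: int = 0) -> pd.DataFrame:
    """Empirical semivariogram gamma(h) = sum (r_i - r_j)^2 / (2 |N(h)|).

    Pairs are subsampled uniformly when the full pair set exceeds
    ``max_pairs``. Empty bins yield NaN with a zero pair count.
    """
    residuals = np.asarray(residuals, float)
    coords = np.asarray(coords, float)
    bin_edges = np.asarray(bin_edges, float)
    if len(bin_edges) < 3:
        raise ValueError("need at least 2 distance bins")
    n = len(residuals)
    n_pairs = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    d = np.hypot(coords[ii, 0] - coords[jj, 0], coords[ii, 1] - coords[jj, 1])
    sq = (residuals[ii] - residuals[jj]) ** 2
    which = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        m = which == b
        cnt = int(m.sum())
        gamma = float(sq[m].sum() / (2.0 * cnt)) if cnt else np.nan
        rows.append({"bin_low": bin_edges[b], "bin_high": bin_edges[b + 1],
                     "gamma": gamma, "n_pairs": cnt, "empty": cnt == 0})
    return pd.DataFrame(rows)


def _estimate_variant(frame: pd.DataFrame, ndvi_col: str, exposed: pd.Series,
                      spec: ModelSpec, community_type: str,
                      library, V: int, seed: int,
                      trim_percentiles=(1.0, 99.0)) -> EffectEstimate:
    df = frame.copy()
    df["exposed"] = exposed.to_numpy()
    df["ndvi_per01"] = df[ndvi_col] / 0.1
    sub = df[df["community_type"] == community_type].reset_index(drop=True)
    X = sub[PROPENSITY_COVARIATES]
    fit = ps.fit_propensity(X, sub["exposed"].to_numpy(), library=library,
                            V=V, seed=seed)
    retained, _ = support.trim(fit.scores, sub["exposed"].to_numpy(),
                               *trim_percentiles)
    return fit_outcome_model(sub[retained], spec, community_type)


def sensitivity_suite(frame: pd.DataFrame, cohort: pd.DataFrame,
                      raster: RasterStack, spec: ModelSpec,
                      community_type: str = "city",
                      library=None, V: int = 5, seed: int = 0) -> dict:
    """Re-estimate the exposure effect under alternative exposure choices.

    Variants: {mean, max} NDVI x {250 m, 1250 m} buffers x {tertile 2-3 vs
    1, >=20th percentile, continuous per 0.1} contrasts, plus the original
    (untrimmed) vs restricted binary contrast, and the Spearman correlation
    matrix among the exposure metrics.
    """
    if library is None:
        library = ps.fast_library()
    metrics = {}
    assignments = {}
    for statistic in ("mean", "max"):
        expo = assign_exposure(cohort, raster, radius_m=250.0,
                               statistic=statistic, extra_radii=(1250.0,))
        for radius in (250, 1250):
            key = f"{statistic}_{radius}"
            col = f"ndvi_{statistic}_{radius}"
            metrics[key] = expo.set_index("birth_id")[col]
            assignments[key] = expo

    ids = frame["birth_id"]
    rows = []
    for key, vals in metrics.items():
        statistic, radius = key.rsplit("_", 1)
        expo = assignments[key].copy()
        expo["ndvi"] = metrics[key].reindex(expo["birth_id"]).to_numpy()
        # recompute tertiles on this metric
        from .exposure import tertile_cutpoints, _tertile_labels
        tert = pd.Series(0, index=expo.index)
        for _, grp in expo.groupby("community_type"):
            cuts = tertile_cutpoints(grp["ndvi"].to_numpy())
            tert.loc[grp.index] = _tertile_labels(grp["ndvi"].to_numpy(), cuts)
        expo["tertile"] = tert
        aligned = expo.set_index("birth_id").reindex(ids)
        base_cols = frame.copy()
        base_cols["ndvi"] = aligned["ndvi"].to_numpy()

        for contrast in ("tertile", "p20", "continuous"):
            if contrast == "tertile":
                exposed = pd.Series((aligned["tertile"] >= 2).astype(int).to_numpy(),
                                    index=frame.index)
                use_spec = spec
            elif contrast == "p20":
                tmp = pd.DataFrame({
                    "ndvi": aligned["ndvi"].to_numpy(),
                    "community_type": frame["community_type"].to_numpy()})
                exposed = dichotomize_at_percentile(tmp, 20.0)
                exposed.index = frame.index
                use_spec = spec
            else:
                exposed = pd.Series((aligned["tertile"] >= 2).astype(int).to_numpy(),
                                    index=frame.index)
                use_spec = ModelSpec(spec.outcome, spec.family, "continuous",
                                     list(spec.covariates), [], spec.cluster)
            est = _estimate_variant(base_cols, "ndvi", exposed, use_spec,
                                    community_type, library, V, seed)
            rows.append({"metric": key, "contrast": contrast,
                         "estimate": est.estimate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "n": est.n})

    # original (untrimmed) vs restricted contrast on the primary metric
    primary = assignments["mean_250"].set_index("birth_id").reindex(ids)
    orig = frame.copy()
    orig["exposed"] = (primary["tertile"] >= 2).astype(int).to_numpy()
    orig["ndvi_per01"] = primary["ndvi"].to_numpy() / 0.1
    sub = orig[orig["community_type"] == community_type]
    unrestricted = fit_outcome_model(sub, spec, community_type)
    restricted = _estimate_variant(orig, "ndvi", orig["exposed"], spec,
                                   community_type, library, V, seed)

    mat = pd.DataFrame({k: v.to_numpy() for k, v in metrics.items()})
    rho = pd.DataFrame(spearmanr(mat.to_numpy()).statistic,
                       index=mat.columns, columns=mat.columns)
    return {
        "variants": pd.DataFrame(rows),
        "unrestricted": unrestricted,
        "restricted": restricted,
        "spearman": rho,
    }
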