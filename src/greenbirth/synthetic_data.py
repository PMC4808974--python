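"""Synthetic cohorts, NDVI rasters and environmental point layers.

The generator reproduces the statistical structure the downstream analysis
assumes, with known ground truth, so every stage is testable without any
external data:

* a raster stack of 16-day NDVI composites on a 250 m grid with a summer-
  peaking seasonal cycle, community-type gradients (city < borough <
  township) and smooth spatial variation;
* a birth cohort whose covariates are drawn from community-type-specific
  mixtures tilted by the local (static) greenness of the address — the
  confounding channel — and whose outcomes are generated from logistic
  models with configurable true exposure effects per community type;
* point layers (animal feeding operations, unconventional wells, major
  roads, municipal water-service areas) feeding the covariate engineering.

Communities are axis-aligned rectangular zones in a local planar frame, so
containment and distance stay trivially testable. An optional structural
positivity violation plants a covariate stratum ("subsidized housing")
that exists only among low-greenness city residents and carries its own
outcome risk, emulating structural confounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import zoom
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._rng import substream
from .exposure import RasterStack, assign_exposure, season_of_date

__all__ = ["SimConfig", "GroundTruth", "community_layout", "simulate_raster",
           "simulate_cohort", "simulate_point_layers"]

COMMUNITY_TYPES = ("city", "borough", "township")

# log-odds coefficients shared by the binary-outcome models
_BINARY_COEFFS = {
    "medical_assistance": 0.28,
    "smoking": 0.38,
    "race_black": 0.35,
    "race_hispanic": 0.10,
    "race_other": 0.05,
    "bmi_underweight": 0.50,
    "bmi_overweight": 0.03,
    "bmi_obese": 0.15,
    "nulliparous": 0.18,
    "antibiotic_orders": 0.06,
    "age_quadratic": 0.0022,   # on (age - 27)^2
    "sex_male": 0.08,
    "season_winter": 0.06,
    "season_summer": -0.02,
}

_WEIGHT_COEFFS = {   # grams
    "medical_assistance": -55.0,
    "smoking": -170.0,
    "race_black": -140.0,
    "race_hispanic": -40.0,
    "race_other": -20.0,
    "bmi_underweight": -110.0,
    "bmi_overweight": 40.0,
    "bmi_obese": 80.0,
    "nulliparous": -105.0,
    "antibiotic_orders": -5.0,
    "age_quadratic": 0.0,
    "sex_male": 0.0,           # sex enters through the growth curve
    "season_winter": 0.0,
    "season_summer": 0.0,
}

# median birth-weight growth curve (grams) by completed week, male
_WEIGHT_WEEKS = np.array([22, 24, 26, 28, 30, 32, 34, 36, 37, 38, 39, 40, 41, 42, 44])
_WEIGHT_MEDIANS = np.array([530, 680, 880, 1150, 1470, 1850, 2280, 2750,
                            3000, 3200, 3350, 3480, 3560, 3600, 3620], float)


def _default_effects() -> dict:
    """True conditional exposure effects per community type.

    Binary outcomes on the log-OR scale; term weight in grams. Defaults
    follow the adjusted city findings (protective for preterm and small-
    for-gestational-age, null Apgar, suggestive weight gain) with null
    effects outside cities.
    """
    eff = {t: {"preterm": 0.0, "sga": 0.0, "low_apgar": 0.0, "term_weight": 0.0}
           for t in COMMUNITY_TYPES}
    eff["city"] = {"preterm": math.log(0.78), "sga": math.log(0.73),
                   "low_apgar": 0.0, "term_weight": 42.0}
    return eff


@dataclass
class SimConfig:
    """All knobs of the synthetic study region and cohort."""

    seed: int = 0
    n_births: dict = dc_field(default_factory=lambda: {
        "city": 3400, "borough": 4700, "township": 8800})
    n_communities: dict = dc_field(default_factory=lambda: {
        "city": 24, "borough": 30, "township": 40})
    community_block_px: int = 12          # each community is a square block
    resolution_m: float = 250.0
    raster_start: date = date(2005, 1, 1)
    raster_end: date = date(2013, 1, 31)
    composite_days: int = 16
    birth_start: date = date(2006, 1, 1)
    birth_end: date = date(2013, 1, 31)

    ndvi_base: dict = dc_field(default_factory=lambda: {
        "city": 0.45, "borough": 0.51, "township": 0.56})
    ndvi_between_community_sd: float = 0.045
    ndvi_within_community_sd: float = 0.03
    season_ndvi_amplitude: float = 0.16
    ndvi_noise_sd: float = 0.012

    # covariate mixtures per community type
    p_medical_assistance: dict = dc_field(default_factory=lambda: {
        "city": 0.60, "borough": 0.48, "township": 0.34})
    p_smoking: dict = dc_field(default_factory=lambda: {
        "city": 0.19, "borough": 0.23, "township": 0.22})
    race_props: dict = dc_field(default_factory=lambda: {
        "city": {"white": 0.730, "black": 0.150, "hispanic": 0.105, "other": 0.015},
        "borough": {"white": 0.920, "black": 0.041, "hispanic": 0.029, "other": 0.010},
        "township": {"white": 0.953, "black": 0.019, "hispanic": 0.015, "other": 0.013},
    })
    p_multiparous: dict = dc_field(default_factory=lambda: {
        "city": 0.53, "borough": 0.54, "township": 0.50})
    p_primary_care: dict = dc_field(default_factory=lambda: {
        "city": 0.37, "borough": 0.49, "township": 0.53})
    median_age: dict = dc_field(default_factory=lambda: {
        "city": 28.4, "borough": 26.9, "township": 25.3})

    confounding_strength: float = 1.0
    community_outcome_sd: float = 0.06    # shared community random intercept (logit)
    true_effects: dict = dc_field(default_factory=_default_effects)
    outcome_coeffs: dict = dc_field(default_factory=lambda: dict(_BINARY_COEFFS))
    weight_coeffs: dict = dc_field(default_factory=lambda: dict(_WEIGHT_COEFFS))
    target_prevalence: dict = dc_field(default_factory=lambda: {
        "preterm": 0.115, "sga": 0.10, "low_apgar": 0.02})

    structural_overlap_violation: bool = False
    violation_share: float = 0.35         # share of city tertile-1 births in the stratum
    violation_log_or: dict = dc_field(default_factory=lambda: {
        "preterm": 2.0, "sga": 2.0, "low_apgar": 0.8, "term_weight": -250.0})

    multiple_birth_rate: float = 0.15     # mothers with a second delivery

    # planted exclusion-cascade violations (fractions of raw records)
    exclusion_rates: dict = dc_field(default_factory=lambda: {
        "non_singleton": 0.049, "stillbirth": 0.0008, "birth_defect": 0.0036,
        "low_birth_weight": 0.0011, "low_gestational_age": 0.0005})

    n_afos: int = 40
    n_wells: int = 150
    n_roads: int = 60

    def validate(self) -> None:
        for t in COMMUNITY_TYPES:
            if self.n_births.get(t, 0) < 0 or self.n_communities.get(t, 0) < 0:
                raise ValueError("counts must be nonnegative")
            if self.n_births.get(t, 0) > 0 and self.n_communities.get(t, 0) <= 0:
                raise ValueError(f"{t}: births requested but no communities")
        if self.resolution_m <= 0 or self.community_block_px <= 0:
            raise ValueError("resolution and block size must be positive")
        if not 0 <= self.multiple_birth_rate <= 1:
            raise ValueError("multiple_birth_rate must be in [0, 1]")
        for p in (*self.p_medical_assistance.values(), *self.p_smoking.values(),
                  *self.p_multiparous.values(), *self.p_primary_care.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for t, props in self.race_props.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"race mixture for {t} must sum to 1")
        total_comms = sum(self.n_communities.get(t, 0) for t in COMMUNITY_TYPES)
        if total_comms == 0:
            raise ValueError("at least one community required")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_effects: dict
    outcome_coeffs: dict
    weight_coeffs: dict
    intercepts: dict
    exposed: np.ndarray               # generator-side binary exposure per birth
    overlap_stratum: np.ndarray       # structural-violation membership per birth
    potential_probs: pd.DataFrame     # per-birth P(outcome | A=0), P(. | A=1)
    cutpoints: dict


def community_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic rectangular community zones and their ACS-style components."""
    config.validate()
    rng = substream(config.seed, "layout")
    types: list[str] = []
    for t in COMMUNITY_TYPES:
        types += [t] * config.n_communities.get(t, 0)
    order = rng.permutation(len(types))
    types = [types[i] for i in order]

    n = len(types)
    ncols = int(math.ceil(math.sqrt(n)))
    block_m = config.community_block_px * config.resolution_m
    rows = []
    offsets = rng.normal(0.0, config.ndvi_between_community_sd, size=n)
    comp_rng = substream(config.seed, "community-components")
    csd_shift = {"city": 0.7, "borough": 0.1, "township": -0.35}
    walk_shift = {"city": 0.7, "borough": 0.25, "township": -0.45}
    for k, t in enumerate(types):
        r, c = divmod(k, ncols)
        row = {
            "community_id": k, "community_type": t,
            "x0": c * block_m, "y0": r * block_m,
            "x1": (c + 1) * block_m, "y1": (r + 1) * block_m,
            "ndvi_offset": offsets[k],
        }
        # deprivation components rise as community greenness falls
        dep = csd_shift[t] - 4.0 * offsets[k]
        for name in ("pct_less_than_hs", "pct_unemployed", "pct_not_in_labor_force",
                     "pct_poverty", "pct_public_assistance", "pct_no_car"):
            row[name] = dep + comp_rng.normal(0, 0.3)
        wk = walk_shift[t]
        for name in ("population_density", "land_use_mix", "street_connectivity"):
            row[name] = wk + comp_rng.normal(0, 0.3)
        rows.append(row)
    return pd.DataFrame(rows)


def _composite_dates(config: SimConfig) -> list[date]:
    out, d = [], config.raster_start
    while d <= config.raster_end:
        out.append(d)
        d = d + timedelta(days=config.composite_days)
    return out


def _base_field(config: SimConfig, layout: pd.DataFrame) -> np.ndarray:
    """Static spatial NDVI field: type base + community offset + smooth noise."""
    n = len(layout)
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    bp = config.community_block_px
    ny, nx = nrows * bp, ncols * bp
    base = np.full((ny, nx), config.ndvi_base["township"], float)
    for _, row in layout.iterrows():
        r, c = divmod(int(row["community_id"]), ncols)
        base[r * bp:(r + 1) * bp, c * bp:(c + 1) * bp] = (
            config.ndvi_base[row["community_type"]] + row["ndvi_offset"])
    if config.ndvi_within_community_sd > 0:
        rng = substream(config.seed, "raster-smooth")
        coarse = rng.normal(0, config.ndvi_within_community_sd,
                            size=(max(2, ny // 8), max(2, nx // 8)))
        smooth = zoom(coarse, (ny / coarse.shape[0], nx / coarse.shape[1]), order=1)
        base = base + smooth[:ny, :nx]
    return base


def _seasonal_term(d: date, amplitude: float) -> float:
    doy = d.timetuple().tm_yday
    return amplitude * math.cos(2 * math.pi * (doy - 196) / 365.25)


def simulate_raster(config: SimConfig) -> RasterStack:
    """NDVI composite stack over the community grid."""
    config.validate()
    layout = community_layout(config)
    dates = _composite_dates(config)
    if (config.raster_end - config.raster_start).days < 2 * 365:
        raise ValueError("need at least 2 years of composites")
    base = _base_field(config, layout)
    if base.shape[0] < 16 or base.shape[1] < 16:
        raise ValueError("grid must be at least 16x16")
    rng = substream(config.seed, "raster-noise")
    stack = np.empty((len(dates), *base.shape))
    for k, d in enumerate(dates):
        season = _seasonal_term(d, config.season_ndvi_amplitude)
        noise = rng.normal(0, config.ndvi_noise_sd, size=base.shape) \
            if config.ndvi_noise_sd > 0 else 0.0
        stack[k] = base + season + noise
    np.clip(stack, -1.0, 1.0, out=stack)
    return RasterStack(stack, 0.0, 0.0, config.resolution_m, dates)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a with mean(expit(a + eta)) == target."""
    def f(a: float) -> float:
        return float(np.mean(expit(a + eta))) - target
    return brentq(f, -12.0, 6.0, xtol=1e-10)


def _bernoulli(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    return (rng.random(len(p)) < p).astype(int)


def _growth_median(week: np.ndarray, male: np.ndarray) -> np.ndarray:
    mu = np.interp(week, _WEIGHT_WEEKS, _WEIGHT_MEDIANS)
    return np.where(male, mu, mu * 0.96)


def simulate_cohort(config: SimConfig,
                    raster: RasterStack) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the birth cohort and its ground truth.

    Returns a one-row-per-birth DataFrame carrying identifiers, address,
    raw covariate ingredients, planted exclusion flags, and outcomes, plus
    a GroundTruth record with true effects and potential-outcome
    probabilities.
    """
    config.validate()
    layout = community_layout(config)

    # --- mothers, addresses, dates -------------------------------------------
    rows = []
    mother_counter = 0
    for t in COMMUNITY_TYPES:
        B = config.n_births.get(t, 0)
        if B == 0:
            continue
        comms = layout[layout["community_type"] == t]
        rng = substream(config.seed, f"mothers-{t}")
        M = max(1, round(B / (1.0 + config.multiple_birth_rate)))
        n_two = B - M
        per_mother = np.ones(M, dtype=int)
        per_mother[:n_two] += 1
        comm_idx = rng.integers(0, len(comms), size=M)
        for m in range(M):
            comm = comms.iloc[comm_idx[m]]
            x = rng.uniform(comm["x0"] + 1.0, comm["x1"] - 1.0)
            y = rng.uniform(comm["y0"] + 1.0, comm["y1"] - 1.0)
            for _ in range(per_mother[m]):
                rows.append({
                    "mother_id": mother_counter,
                    "community_id": int(comm["community_id"]),
                    "community_type": t, "x": x, "y": y,
                })
            mother_counter += 1
    cohort = pd.DataFrame(rows)
    n = len(cohort)
    cohort.insert(0, "birth_id", np.arange(n))

    rng = substream(config.seed, "dates")
    span = (config.birth_end - config.birth_start).days
    cohort["birth_date"] = [config.birth_start + timedelta(days=int(d))
                            for d in rng.integers(0, span + 1, size=n)]
    rng_sex = substream(config.seed, "sex")
    cohort["sex"] = np.where(rng_sex.random(n) < 0.512, "male", "female")

    # planted exclusion-cascade violations, drawn up front so that tertile
    # cutpoints can be computed on the analysis (post-exclusion) sample
    rng_x = substream(config.seed, "exclusions")
    er = config.exclusion_rates
    plurality = np.where(rng_x.random(n) < er["non_singleton"], 2, 1)
    stillbirth = rng_x.random(n) < er["stillbirth"]
    defect = rng_x.random(n) < er["birth_defect"]
    low_w = rng_x.random(n) < er["low_birth_weight"]
    low_g = rng_x.random(n) < er["low_gestational_age"]
    planted_excluded = (plurality > 1) | stillbirth | defect | low_w | low_g

    # --- confounding channel: place-based disadvantage ------------------------
    base = _base_field(config, layout)
    j = (cohort["x"].to_numpy() // config.resolution_m).astype(int)
    i = (cohort["y"].to_numpy() // config.resolution_m).astype(int)
    static_ndvi = base[i, j]
    z_place = np.zeros(n)
    for t in COMMUNITY_TYPES:
        m = (cohort["community_type"] == t).to_numpy()
        if m.any():
            v = static_ndvi[m]
            sd = v.std() or 1.0
            z_place[m] = (v - v.mean()) / sd
    rng_l = substream(config.seed, "latent")
    L = -config.confounding_strength * z_place + rng_l.normal(0, 0.8, size=n)

    # --- covariates ------------------------------------------------------------
    rng_c = substream(config.seed, "covariates")
    ctype = cohort["community_type"].to_numpy()
    p_ma = expit(logit(np.array([config.p_medical_assistance[t] for t in ctype]))
                 + 0.5 * L)
    ma_ever = _bernoulli(rng_c, p_ma)
    p_sm = expit(logit(np.array([config.p_smoking[t] for t in ctype])) + 0.35 * L)
    smoke_ever = _bernoulli(rng_c, p_sm)

    race = np.empty(n, dtype=object)
    for t in COMMUNITY_TYPES:
        m = ctype == t
        if not m.any():
            continue
        props = config.race_props[t]
        logits = {k: math.log(max(v, 1e-6)) for k, v in props.items()}
        tilt = 0.4 * L[m]
        ls = np.column_stack([
            np.full(m.sum(), logits["white"]),
            logits["black"] + tilt,
            logits["hispanic"] + tilt,
            np.full(m.sum(), logits["other"]),
        ])
        p = np.exp(ls - ls.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = rng_c.random(m.sum())
        cum = np.cumsum(p, axis=1)
        race[m] = np.array(["white", "black", "hispanic", "other"])[
            (u[:, None] <= cum).argmax(axis=1)]

    bmi = np.exp(rng_c.normal(math.log(26.5), 0.20, size=n) + 0.04 * L)
    age = np.clip(np.array([config.median_age[t] for t in ctype])
                  + rng_c.normal(0, 5.5, size=n) - 0.4 * L, 14.0, 45.0)
    multiparous = _bernoulli(
        rng_c, np.array([config.p_multiparous[t] for t in ctype]))
    antibiotics = rng_c.poisson(np.clip(0.40 + 0.12 * np.maximum(L, 0), 0, None))
    primary_care = _bernoulli(
        rng_c, np.array([config.p_primary_care[t] for t in ctype]))
    prenatal = rng_c.poisson(10.0, size=n)
    alcohol = _bernoulli(rng_c, np.full(n, 0.025))
    hospital = np.where(
        (cohort["community_id"].to_numpy() % 2 == 0)
        ^ (rng_c.random(n) < 0.15), "hospital_a", "hospital_b")

    # --- generator-side exposure (the pipeline's default definition) ----------
    # cutpoints come from the post-exclusion sample, exactly as the analysis
    # computes them; planted-excluded births inherit the same cutpoints
    keep = ~planted_excluded
    expo_inc = assign_exposure(cohort[keep], raster, radius_m=250.0,
                               statistic="mean", extra_radii=())
    exposed = np.zeros(n, dtype=int)
    tertile = np.ones(n, dtype=int)
    exposed[keep] = expo_inc["exposed"].to_numpy()
    tertile[keep] = expo_inc["tertile"].to_numpy()
    if planted_excluded.any():
        expo_exc = assign_exposure(cohort[~keep], raster, radius_m=250.0,
                                   statistic="mean", extra_radii=())
        cuts = expo_inc.attrs["cutpoints"]
        for k, (idx, row) in enumerate(expo_exc.iterrows()):
            c1, c2 = cuts[row["community_type"]]
            t_lab = 1 + int(row["ndvi"] > c1) + int(row["ndvi"] > c2)
            pos = np.flatnonzero(~keep)[k]
            tertile[pos] = t_lab
            exposed[pos] = int(t_lab >= 2)

    # --- structural positivity violation --------------------------------------
    stratum = np.zeros(n, dtype=int)
    if config.structural_overlap_violation:
        rng_v = substream(config.seed, "violation")
        eligible = np.flatnonzero((ctype == "city") & (tertile == 1))
        k = int(round(config.violation_share * eligible.size))
        members = rng_v.choice(eligible, size=k, replace=False)
        stratum[members] = 1
        # stratum members carry an extreme measured-covariate profile,
        # including very low prenatal engagement (a covariate the propensity
        # model sees but the outcome adjustment set does not)
        ma_ever[members] = 1
        smoke_ever[members] = 1
        flip = rng_v.random(k) < 0.5
        race[members[flip]] = "black"
        antibiotics[members] = antibiotics[members] + 2
        prenatal[members] = rng_v.poisson(2.0, size=k)

    # --- outcome linear predictors ---------------------------------------------
    c = config.outcome_coeffs
    season = np.array([season_of_date(d).name for d in cohort["birth_date"]])
    male = (cohort["sex"] == "male").to_numpy()
    xb = (c["medical_assistance"] * ma_ever
          + c["smoking"] * smoke_ever
          + c["race_black"] * (race == "black")
          + c["race_hispanic"] * (race == "hispanic")
          + c["race_other"] * (race == "other")
          + c["bmi_underweight"] * (bmi < 18.5)
          + c["bmi_overweight"] * ((bmi >= 25) & (bmi < 30))
          + c["bmi_obese"] * (bmi >= 30)
          + c["nulliparous"] * (1 - multiparous)
          + c["antibiotic_orders"] * antibiotics
          + c["age_quadratic"] * (age - 27.0) ** 2
          + c["sex_male"] * male
          + c["season_winter"] * (season == "winter")
          + c["season_summer"] * (season == "summer"))

    rng_comm = substream(config.seed, "community-intercepts")
    u_comm = rng_comm.normal(0, config.community_outcome_sd, size=len(layout))
    xb = xb + u_comm[cohort["community_id"].to_numpy()]

    theta = {o: np.array([config.true_effects[t][o] for t in ctype])
             for o in ("preterm", "sga", "low_apgar")}
    v = config.violation_log_or

    rng_o = substream(config.seed, "outcomes")
    intercepts: dict[str, float] = {}
    flags: dict[str, np.ndarray] = {}
    pots = {}
    for o in ("preterm", "sga", "low_apgar"):
        eta = xb + theta[o] * exposed + v[o] * stratum \
            if config.structural_overlap_violation else xb + theta[o] * exposed
        a = _calibrate_intercept(eta, config.target_prevalence[o])
        intercepts[o] = a
        p = expit(a + eta)
        flags[o] = _bernoulli(rng_o, p)
        pots[f"{o}_p0"] = expit(a + eta - theta[o] * exposed)
        pots[f"{o}_p1"] = expit(a + eta + theta[o] * (1 - exposed))

    # --- gestational age consistent with the preterm flag ----------------------
    ga = np.empty(n)
    pre = flags["preterm"].astype(bool)
    ga[pre] = np.clip(37.0 - (0.15 + rng_o.gamma(1.5, 1.9, size=pre.sum())),
                      22.05, 36.95)
    n_term = (~pre).sum()
    draw = rng_o.normal(39.35, 1.15, size=n_term)
    ga[~pre] = np.clip(draw, 37.0, 42.9)

    # --- birth weight with the SGA flag in the lower decile ---------------------
    week = np.floor(ga).astype(int)
    wcoef = config.weight_coeffs
    wx = (wcoef["medical_assistance"] * ma_ever
          + wcoef["smoking"] * smoke_ever
          + wcoef["race_black"] * (race == "black")
          + wcoef["race_hispanic"] * (race == "hispanic")
          + wcoef["race_other"] * (race == "other")
          + wcoef["bmi_underweight"] * (bmi < 18.5)
          + wcoef["bmi_overweight"] * ((bmi >= 25) & (bmi < 30))
          + wcoef["bmi_obese"] * (bmi >= 30)
          + wcoef["nulliparous"] * (1 - multiparous)
          + wcoef["antibiotic_orders"] * antibiotics)
    theta_w = np.array([config.true_effects[t]["term_weight"] for t in ctype])
    if config.structural_overlap_violation:
        wx = wx + v["term_weight"] * stratum
    sigma = np.minimum(440.0, 120.0 + 28.0 * (week - 22))
    weight = (_growth_median(week, male) + wx + theta_w * exposed
              + rng_o.normal(0, 1, size=n) * sigma)
    weight = np.maximum(weight, 510.0)

    # swap weights within (sex, week) cells so SGA-flagged births occupy the
    # bottom ranks; preserves the marginal weight distribution per cell
    sga = flags["sga"].astype(bool)
    cell_key = pd.Series([f"{s}-{w}" for s, w in zip(cohort["sex"], week)])
    for _, idx in cell_key.groupby(cell_key).groups.items():
        idx = np.asarray(idx)
        k = int(sga[idx].sum())
        if k == 0 or k == idx.size:
            continue
        order = idx[np.argsort(weight[idx])]
        bottom = set(order[:k])
        flagged = set(idx[sga[idx]])
        move_up = np.array(sorted(bottom - flagged))
        move_down = np.array(sorted(flagged - bottom))
        if move_up.size:
            w_low = weight[move_up].copy()
            weight[move_up] = weight[move_down]
            weight[move_down] = w_low

    apgar = np.empty(n, dtype=int)
    low = flags["low_apgar"].astype(bool)
    apgar[low] = rng_o.choice([3, 4, 5, 6], size=low.sum(),
                              p=[0.1, 0.2, 0.3, 0.4])
    apgar[~low] = rng_o.choice([7, 8, 9, 10], size=(~low).sum(),
                               p=[0.05, 0.15, 0.45, 0.35])

    # --- raw covariate ingredients ---------------------------------------------
    rng_raw = substream(config.seed, "raw-ingredients")
    ma_enc = np.where(ma_ever, 3 + rng_raw.poisson(2.0, size=n),
                      rng_raw.choice([0, 1, 2], size=n, p=[0.5, 0.3, 0.2]))
    smoking_dates = []
    for ever, bdate, g in zip(smoke_ever, cohort["birth_date"], ga):
        gest_days = int(g * 7)
        if ever:
            smoking_dates.append(
                [bdate - timedelta(days=int(rng_raw.integers(0, gest_days + 1)))])
        elif rng_raw.random() < 0.3:
            smoking_dates.append(
                [bdate - timedelta(days=gest_days + int(rng_raw.integers(30, 400)))])
        else:
            smoking_dates.append([])

    # apply the planted low-weight / low-gestational-age overrides
    weight = np.where(low_w, rng_x.uniform(350, 495, size=n), weight)
    ga = np.where(low_g, rng_x.uniform(20.0, 21.9, size=n), ga)

    cohort["gestational_age_weeks"] = ga
    cohort["birth_weight_g"] = weight
    cohort["apgar5"] = apgar
    cohort["plurality"] = plurality
    cohort["stillbirth"] = stillbirth
    cohort["birth_defect"] = defect
    cohort["maternal_age"] = age
    cohort["race_ethnicity"] = race
    cohort["pre_pregnancy_bmi"] = bmi
    cohort["parity"] = np.where(multiparous == 1, "multiparous", "nulliparous")
    cohort["ma_qualifying_encounters"] = ma_enc
    cohort["smoking_dates"] = smoking_dates
    cohort["antibiotic_orders"] = antibiotics
    cohort["primary_care"] = np.where(primary_care == 1, "yes", "no")
    cohort["prenatal_visits"] = prenatal
    cohort["alcohol"] = np.where(alcohol == 1, "ever", "never")
    cohort["delivery_hospital"] = hospital
    cohort["subsidized_housing"] = stratum

    truth = GroundTruth(
        true_effects=config.true_effects,
        outcome_coeffs=dict(config.outcome_coeffs),
        weight_coeffs=dict(config.weight_coeffs),
        intercepts=intercepts,
        exposed=exposed,
        overlap_stratum=stratum,
        potential_probs=pd.DataFrame(pots, index=cohort.index),
        cutpoints=expo_inc.attrs["cutpoints"],
    )
    return cohort, truth


def simulate_point_layers(config: SimConfig) -> dict[str, object]:
    """AFO sites, unconventional wells, major roads and water-service areas."""
    config.validate()
    layout = community_layout(config)
    x_max = float(layout["x1"].max())
    y_max = float(layout["y1"].max())

    rng = substream(config.seed, "layers")
    afo = pd.DataFrame({
        "x": rng.uniform(0, x_max, config.n_afos),
        "y": rng.uniform(0, y_max, config.n_afos),
        "animal_units": np.exp(rng.normal(math.log(300), 0.8, config.n_afos)),
    })
    span = (config.raster_end - date(2004, 1, 1)).days
    wells = pd.DataFrame({
        "x": rng.uniform(0, x_max, config.n_wells),
        "y": rng.uniform(0, y_max, config.n_wells),
        "drill_date": [date(2004, 1, 1) + timedelta(days=int(d))
                       for d in rng.integers(0, span + 1, config.n_wells)],
    })
    x1 = rng.uniform(0, x_max, config.n_roads)
    y1 = rng.uniform(0, y_max, config.n_roads)
    angle = rng.uniform(0, 2 * math.pi, config.n_roads)
    length = rng.uniform(2000, 15000, config.n_roads)
    roads = pd.DataFrame({
        "x1": x1, "y1": y1,
        "x2": np.clip(x1 + length * np.cos(angle), 0, x_max),
        "y2": np.clip(y1 + length * np.sin(angle), 0, y_max),
        "major": True,
    })
    water_areas = [
        {"x0": row["x0"], "y0": row["y0"], "x1": row["x1"], "y1": row["y1"]}
        for _, row in layout.iterrows()
        if row["community_type"] in ("city", "borough")
    ]
    return {"afo": afo, "wells": wells, "roads": roads,
            "water_areas": water_areas, "layout": layout}
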