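"""End-to-end reproducible runs: simulate -> expose -> covariates ->
outcomes -> propensity -> trim -> infer, with persisted stage outputs and a
manifest for bitwise re-runs."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, propensity, support
from .covariates import build_covariate_panel
from .exposure import assign_exposure
from .outcomes import apply_exclusions, build_growth_reference, classify_outcomes
from .synthetic_data import (COMMUNITY_TYPES, SimConfig, simulate_cohort,
                             simulate_point_layers, simulate_raster)

__all__ = ["RunConfig", "run_pipeline", "analyze_community", "OUTCOME_SPECS",
           "save_cohort", "load_cohort", "load_layers"]

OUTCOME_SPECS = {
    "preterm": "logistic",
    "sga": "logistic",
    "low_apgar": "logistic",
    "term_birth_weight_g": "linear",
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    sim: SimConfig = dc_field(default_factory=SimConfig)
    radius_m: float = 250.0
    statistic: str = "mean"
    propensity_V: int = 10
    propensity_library: str = "default"  # "default" | "fast"
    trim_percentiles: tuple[float, float] = (1.0, 99.0)
    outcomes: list[str] = dc_field(default_factory=lambda: list(OUTCOME_SPECS))
    outdir: str | None = None
    seed: int | None = None  # overrides sim.seed when set

    def validate(self) -> None:
        self.sim.validate()
        if self.statistic not in ("mean", "max"):
            raise ValueError("statistic must be 'mean' or 'max'")
        if self.propensity_V < 2:
            raise ValueError("V must be >= 2")
        lo, hi = self.trim_percentiles
        if not (0 <= lo <= 100 and 0 <= hi <= 100):
            raise ValueError("trim percentiles must be in [0, 100]")
        unknown = set(self.outcomes) - set(OUTCOME_SPECS)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = SimConfig(**d.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in d.items()})
        if cfg.seed is not None:
            cfg.sim.seed = cfg.seed
        cfg.validate()
        return cfg


def save_cohort(cohort: pd.DataFrame, path) -> None:
    """Persist the cohort as CSV; list-valued smoking dates join with ';'."""
    out = cohort.copy()
    if "smoking_dates" in out.columns:
        out["smoking_dates"] = [";".join(d.isoformat() for d in ds)
                                for ds in out["smoking_dates"]]
    out.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    from datetime import date as _date
    df = pd.read_csv(path)
    df["birth_date"] = [_date.fromisoformat(s) for s in df["birth_date"]]
    if "smoking_dates" in df.columns:
        df["smoking_dates"] = [
            [] if (not isinstance(s, str) or not s)
            else [_date.fromisoformat(t) for t in s.split(";")]
            for s in df["smoking_dates"].fillna("")]
    return df


def load_layers(directory) -> dict:
    import json as _json
    from datetime import date as _date
    directory = Path(directory)
    layers = {}
    for name in ("afo", "wells", "roads", "layout"):
        layers[name] = pd.read_csv(directory / f"{name}.csv")
    layers["wells"]["drill_date"] = [
        _date.fromisoformat(s) for s in layers["wells"]["drill_date"]]
    layers["water_areas"] = _json.loads(
        (directory / "water_areas.json").read_text())
    return layers


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(
        df.select_dtypes(exclude=object), index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def analyze_community(frame: pd.DataFrame, community_type: str,
                      outcome: str, family: str, library, V: int, seed: int,
                      trim_percentiles=(1.0, 99.0)) -> dict:
    """Propensity -> trim -> fit for one community type and outcome."""
    sub = frame[frame["community_type"] == community_type].reset_index(drop=True)
    X = sub[inference.PROPENSITY_COVARIATES]
    fit = propensity.fit_propensity(X, sub["exposed"].to_numpy(),
                                    library=library, V=V, seed=seed)
    retained, bounds = support.trim(fit.scores, sub["exposed"].to_numpy(),
                                    *trim_percentiles)
    spec = inference.ModelSpec(outcome, family)
    est = inference.fit_outcome_model(sub[retained], spec, community_type)
    return {"propensity": fit, "bounds": bounds, "retained": retained,
            "estimate": est, "n_restricted": int(retained.sum())}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return (and optionally persist) the manifest."""
    config.validate()
    if config.seed is not None:
        config.sim.seed = config.seed
    t0 = time.time()
    stages: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def tick(name: str, start: float) -> None:
        stages[name] = round(time.time() - start, 3)

    s = time.time()
    raster = simulate_raster(config.sim)
    layers = simulate_point_layers(config.sim)
    cohort, truth = simulate_cohort(config.sim, raster)
    tick("simulate", s)

    s = time.time()
    included, ledger = apply_exclusions(cohort)
    tick("exclusions", s)

    s = time.time()
    expo = assign_exposure(included, raster, radius_m=config.radius_m,
                           statistic=config.statistic)
    tick("expose", s)

    s = time.time()
    panel = build_covariate_panel(included, layers["layout"], layers)
    tick("covariates", s)

    s = time.time()
    reference = build_growth_reference(included)
    outcome_df = classify_outcomes(included, reference)
    tick("outcomes", s)

    frame = inference.build_model_frame(included, panel, expo, outcome_df)

    lib = propensity.default_library(config.sim.seed) \
        if config.propensity_library == "default" else propensity.fast_library()

    s = time.time()
    results: dict[str, dict] = {}
    table_rows = []
    for ctype in COMMUNITY_TYPES:
        sub = frame[frame["community_type"] == ctype].reset_index(drop=True)
        if len(sub) == 0:
            continue
        X = sub[inference.PROPENSITY_COVARIATES]
        fit = propensity.fit_propensity(X, sub["exposed"].to_numpy(),
                                        library=lib, V=config.propensity_V,
                                        seed=config.sim.seed)
        retained, bounds = support.trim(fit.scores, sub["exposed"].to_numpy(),
                                        *config.trim_percentiles)
        results[ctype] = {"propensity": fit, "bounds": bounds,
                          "retained": retained, "estimates": {}}
        for outcome in config.outcomes:
            family = OUTCOME_SPECS[outcome]
            spec = inference.ModelSpec(outcome, family)
            est = inference.fit_outcome_model(sub[retained], spec, ctype)
            results[ctype]["estimates"][outcome] = est
            table_rows.append({
                "community_type": ctype, "outcome": outcome,
                "estimate": est.estimate, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "n": est.n,
                "n_restricted": int(retained.sum()),
                "trim_lower": bounds.lower,
                "trim_upper": bounds.upper,
            })
    tick("infer", s)

    table = pd.DataFrame(table_rows)
    manifest = {
        "seed": config.sim.seed,
        "n_raw": ledger["raw"],
        "n_included": ledger["included"],
        "exclusion_ledger": ledger,
        "cutpoints": expo.attrs["cutpoints"],
        "cohort_hash": _hash_frame(included),
        "exposure_hash": _hash_frame(expo),
        "stage_seconds": stages,
        "total_seconds": round(time.time() - t0, 3),
        "results": table.to_dict(orient="records"),
    }

    if outdir:
        from .outcomes import EXCLUSION_REASONS
        included.drop(columns=["smoking_dates"]).to_csv(
            outdir / "cohort.csv", index=False)
        expo.to_csv(outdir / "exposure.csv", index=False)
        panel.to_csv(outdir / "covariates.csv", index=False)
        outcome_df.to_csv(outdir / "outcomes.csv", index=False)
        table.to_csv(outdir / "estimates.csv", index=False)
        wide = table.assign(cell=[
            f"{r.estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            for r in table.itertuples()]).pivot(
            index="community_type", columns="outcome", values="cell")
        wide.to_csv(outdir / "estimates_wide.csv")
        (outdir / "exclusions.json").write_text(json.dumps(
            {"counts": ledger, "labels": dict(EXCLUSION_REASONS)}, indent=1))
        (outdir / "cutpoints.json").write_text(json.dumps(
            {"tertile_cutpoints": expo.attrs["cutpoints"],
             "pooled_cutpoints": list(expo.attrs["cutpoints_overall"]),
             "radius_m": expo.attrs["radius_m"],
             "statistic": expo.attrs["statistic"],
             "computed_on": "post-exclusion analysis sample"}, indent=1))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for ctype, out in results.items():
            (outdir / f"propensity_{ctype}.json").write_text(
                json.dumps(out["propensity"].to_json_dict(), indent=1))
            (outdir / f"trim_{ctype}.json").write_text(
                json.dumps(out["bounds"].to_json_dict(), indent=1))
            sub = frame[frame["community_type"] == ctype].reset_index(drop=True)
            pd.DataFrame({
                "birth_id": sub["birth_id"],
                "score": out["propensity"].scores,
                "exposed": sub["exposed"],
                "retained": out["retained"].astype(int),
            }).to_csv(outdir / f"propensity_{ctype}.csv", index=False)
            support.plot_overlap(
                out["propensity"].scores, sub["exposed"].to_numpy(),
                out["bounds"], outdir / f"overlap_{ctype}.png",
                title=f"propensity overlap: {ctype}")

    manifest["_objects"] = {"frame": frame, "results": results,
                            "raster": raster, "truth": truth,
                            "reference": reference}
    return manifest
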