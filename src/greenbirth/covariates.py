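"""Derived maternal, neonatal and environmental covariates.

Builds the adjustment/propensity covariate panel from raw ingredients:
z-sum composite indices (walkability from three block-group metrics,
community socioeconomic deprivation from six community-level ACS-style
variables), an inverse-square-distance animal-feeding-operation metric,
unconventional-well counts within 20 km before birth, distance to the
nearest major road, municipal vs non-municipal water source, Medical
Assistance and gestational-smoking status, season of birth, maternal age
terms, and a pre-pregnancy BMI class.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .exposure import season_of_date

__all__ = [
    "ZeroVarianceError",
    "zsum_index",
    "afo_exposure",
    "wells_within",
    "road_distance",
    "medical_assistance",
    "smoking_status",
    "bmi_class",
    "quartile_labels",
    "build_covariate_panel",
]

AFO_DISTANCE_FLOOR_KM = 0.1  # inverse-square metric is unbounded at zero distance

BMI_BOUNDS = (18.5, 25.0, 30.0)
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")


class ZeroVarianceError(ValueError):
    """A composite-index component has no variance across units."""


def zsum_index(components: pd.DataFrame,
               component_names: Sequence[str] | None = None) -> pd.Series:
    """Sum of per-component z-scores across units.

    Each column is standardized to mean 0, SD 1 (population SD, denominator
    n) over the study region, then the standardized columns are summed. The
    result has mean 0 by construction.
    """
    if component_names is not None:
        components = components[list(component_names)]
    if len(components) < 2:
        raise ValueError("need at least 2 units")
    z = pd.Series(0.0, index=components.index)
    for name in components.columns:
        col = components[name].to_numpy(float)
        sd = col.std()  # ddof=0
        if sd == 0:
            raise ZeroVarianceError(f"component {name!r} has zero variance")
        z = z + (col - col.mean()) / sd
    return z


def afo_exposure(home_xy: tuple[float, float], sites: pd.DataFrame,
                 floor_km: float = AFO_DISTANCE_FLOOR_KM) -> float:
    """Sum over operations of animal_units / distance_km^2.

    ``sites`` needs columns x, y (metres) and animal_units; distances below
    ``floor_km`` are clipped to it.
    """
    if len(sites) == 0:
        return 0.0
    dx = (sites["x"].to_numpy(float) - home_xy[0]) / 1000.0
    dy = (sites["y"].to_numpy(float) - home_xy[1]) / 1000.0
    d = np.maximum(np.hypot(dx, dy), floor_km)
    return float(np.sum(sites["animal_units"].to_numpy(float) / d**2))


def wells_within(home_xy: tuple[float, float], wells: pd.DataFrame,
                 birth_date: date, radius_km: float = 20.0) -> int:
    """Number of wells drilled on/before the birth date within radius."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if len(wells) == 0:
        return 0
    drilled = np.array([d <= birth_date for d in wells["drill_date"]])
    dx = (wells["x"].to_numpy(float) - home_xy[0]) / 1000.0
    dy = (wells["y"].to_numpy(float) - home_xy[1]) / 1000.0
    near = np.hypot(dx, dy) <= radius_km
    return int(np.sum(drilled & near))


def road_distance(home_xy: tuple[float, float], roads: pd.DataFrame) -> float:
    """Euclidean distance (m) from the home to the nearest major road segment.

    ``roads`` has one segment per row: x1, y1, x2, y2, and an optional
    boolean ``major`` flag (all segments treated as major when absent).
    """
    if len(roads) == 0:
        raise ValueError("empty road layer")
    if "major" in roads.columns:
        roads = roads[roads["major"].astype(bool)]
        if len(roads) == 0:
            raise ValueError("no major roads in layer")
    segs = shapely.linestrings(
        np.stack([
            np.column_stack([roads["x1"].to_numpy(float), roads["y1"].to_numpy(float)]),
            np.column_stack([roads["x2"].to_numpy(float), roads["y2"].to_numpy(float)]),
        ], axis=1)
    )
    pt = shapely.points(home_xy[0], home_xy[1])
    return float(np.min(shapely.distance(segs, pt)))


def medical_assistance(qualifying_encounters: int | Iterable) -> str:
    """'ever' iff strictly more than 2 encounters carried a qualifying code."""
    n = qualifying_encounters if isinstance(qualifying_encounters, (int, np.integer)) \
        else sum(1 for _ in qualifying_encounters)
    return "ever" if n > 2 else "never"


def smoking_status(record_dates: Iterable[date],
                   gestation: tuple[date, date]) -> str:
    """'ever' iff any smoking record falls inside the gestation interval.

    The interval is [conception, birth], inclusive at both ends.
    """
    start, end = gestation
    if end < start:
        raise ValueError("gestation interval end precedes start")
    return "ever" if any(start <= d <= end for d in record_dates) else "never"


def bmi_class(bmi: float) -> str:
    """WHO pre-pregnancy BMI class with boundaries 18.5 / 25 / 30."""
    if bmi < BMI_BOUNDS[0]:
        return "underweight"
    if bmi < BMI_BOUNDS[1]:
        return "normal"
    if bmi < BMI_BOUNDS[2]:
        return "overweight"
    return "obese"


def quartile_labels(values: np.ndarray) -> np.ndarray:
    """1..4 quartile labels (linear-interpolation cutpoints, ties go lower)."""
    v = np.asarray(values, float)
    cuts = np.percentile(v, [25, 50, 75])
    return (1 + (v > cuts[0]).astype(int) + (v > cuts[1]).astype(int)
            + (v > cuts[2]).astype(int))


def _point_in_rect(x: float, y: float, rect: Mapping[str, float]) -> bool:
    return rect["x0"] <= x <= rect["x1"] and rect["y0"] <= y <= rect["y1"]


def water_source(home_xy: tuple[float, float],
                 service_areas: Sequence[Mapping[str, float]]) -> str:
    """'municipal' iff the home falls in any public-water service rectangle."""
    x, y = home_xy
    for rect in service_areas:
        if _point_in_rect(x, y, rect):
            return "municipal"
    return "non-municipal"


def build_covariate_panel(
    cohort: pd.DataFrame,
    community_components: pd.DataFrame,
    layers: Mapping[str, object],
) -> pd.DataFrame:
    """Assemble the per-birth covariate panel.

    ``cohort`` carries birth-level raw fields (birth_id, community_id, x, y,
    birth_date, gestational_age_weeks, maternal_age, race_ethnicity,
    pre_pregnancy_bmi, parity, ma_qualifying_encounters, smoking_dates,
    antibiotic_orders, primary_care, delivery_hospital, prenatal_visits).
    ``community_components`` is one row per community with the walkability
    and deprivation component columns. ``layers`` holds the point layers
    from the generator: 'afo', 'wells', 'roads', 'water_areas'.
    """
    walk_components = ["population_density", "land_use_mix",
                       "street_connectivity"]
    csd_components = ["pct_less_than_hs", "pct_unemployed",
                      "pct_not_in_labor_force", "pct_poverty",
                      "pct_public_assistance", "pct_no_car"]
    comp = community_components.set_index("community_id")
    walk = zsum_index(comp, walk_components)
    csd = zsum_index(comp, csd_components)

    out = pd.DataFrame({"birth_id": cohort["birth_id"].to_numpy()},
                       index=cohort.index)
    cid = cohort["community_id"]
    out["walkability"] = walk.reindex(cid).to_numpy()
    out["csd"] = csd.reindex(cid).to_numpy()
    out["csd_quartile"] = quartile_labels(out["csd"].to_numpy())

    afo = layers["afo"]
    wells = layers["wells"]
    roads = layers["roads"]
    water_areas = layers["water_areas"]

    xy = list(zip(cohort["x"].to_numpy(float), cohort["y"].to_numpy(float)))
    bdates = list(cohort["birth_date"])
    out["afo_exposure"] = [afo_exposure(p, afo) for p in xy]
    out["wells_20km"] = [wells_within(p, wells, d) for p, d in zip(xy, bdates)]

    if len(roads):
        segs = shapely.linestrings(
            np.stack([
                np.column_stack([roads["x1"].to_numpy(float), roads["y1"].to_numpy(float)]),
                np.column_stack([roads["x2"].to_numpy(float), roads["y2"].to_numpy(float)]),
            ], axis=1))
        pts = shapely.points(np.array(xy))
        tree = shapely.STRtree(segs)
        nearest = tree.nearest(pts)
        out["road_distance_m"] = shapely.distance(pts, segs[nearest])
    else:
        raise ValueError("empty road layer")

    out["water_source"] = [water_source(p, water_areas) for p in xy]

    out["medical_assistance"] = [
        medical_assistance(int(n)) for n in cohort["ma_qualifying_encounters"]
    ]
    smoking = []
    for dates_i, bdate, ga in zip(cohort["smoking_dates"], bdates,
                                  cohort["gestational_age_weeks"]):
        conception = bdate - pd.Timedelta(days=round(float(ga) * 7))
        conception = conception.date() if hasattr(conception, "date") else conception
        bd = bdate.date() if hasattr(bdate, "date") and not isinstance(bdate, date) else bdate
        smoking.append(smoking_status(dates_i, (conception, bd)))
    out["smoking"] = smoking

    out["season_of_birth"] = [season_of_date(d).name for d in bdates]
    age = cohort["maternal_age"].to_numpy(float)
    out["maternal_age"] = age
    out["maternal_age_sq"] = age * age
    out["race_ethnicity"] = cohort["race_ethnicity"].to_numpy()
    out["bmi_class"] = [bmi_class(b) for b in cohort["pre_pregnancy_bmi"]]
    out["parity"] = cohort["parity"].to_numpy()
    out["antibiotic_orders"] = cohort["antibiotic_orders"].to_numpy(int)
    out["primary_care"] = cohort["primary_care"].to_numpy()
    out["delivery_hospital"] = cohort["delivery_hospital"].to_numpy()
    out["prenatal_visits"] = cohort["prenatal_visits"].to_numpy(int)
    years = pd.to_datetime(cohort["birth_date"]).dt.year
    out["year_band"] = pd.cut(years, bins=[2005, 2007, 2010, 2013],
                              labels=["2006-2007", "2008-2010", "2011-2013"]).astype(str)

    # z-standardization audit: component means/SDs behind the composite indices
    out.attrs["z_params"] = {
        name: {"components": comps,
               "mean": {c: float(comp[c].mean()) for c in comps},
               "sd": {c: float(comp[c].to_numpy().std()) for c in comps}}
        for name, comps in (("walkability", walk_components),
                            ("csd", csd_components))
    }
    return out
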