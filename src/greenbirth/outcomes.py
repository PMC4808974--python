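"""Exclusion cascade and birth-outcome derivation.

Four outcomes: term birth weight (grams, gestational age >= 37 weeks only),
small for gestational age (birth weight strictly below the sex-specific
10th percentile for completed gestational week in an internal reference
built from the included cohort itself), preterm birth (< 37 weeks), and low
5-minute Apgar score (< 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSION_REASONS",
    "apply_exclusions",
    "GrowthReference",
    "build_growth_reference",
    "classify_outcomes",
]

# one reason per record, assessed in this priority order
EXCLUSION_REASONS = (
    ("unlinked", "could not link mother and neonate"),
    ("not_geocoded", "address could not be geocoded"),
    ("non_singleton", "non-singleton birth"),
    ("stillbirth", "stillbirth"),
    ("birth_defect", "serious birth defect"),
    ("low_birth_weight", "birth weight <500 g"),
    ("low_gestational_age", "gestational age <22 weeks"),
)


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop ineligible births; count one reason per record in priority order.

    Flag columns are optional: a missing column means no record fails that
    criterion. Returns (included cohort, ledger) with the ledger keyed by
    reason code plus 'included' and 'raw' totals.
    """
    n = len(raw)
    reason = np.full(n, "", dtype=object)

    def mark(mask: np.ndarray, code: str) -> None:
        mask = np.asarray(mask, bool) & (reason == "")
        reason[mask] = code

    if "linked" in raw.columns:
        mark(~raw["linked"].astype(bool).to_numpy(), "unlinked")
    if "geocoded" in raw.columns:
        mark(~raw["geocoded"].astype(bool).to_numpy(), "not_geocoded")
    if "plurality" in raw.columns:
        mark(raw["plurality"].to_numpy() > 1, "non_singleton")
    if "stillbirth" in raw.columns:
        mark(raw["stillbirth"].astype(bool).to_numpy(), "stillbirth")
    if "birth_defect" in raw.columns:
        mark(raw["birth_defect"].astype(bool).to_numpy(), "birth_defect")
    mark(raw["birth_weight_g"].to_numpy(float) < 500.0, "low_birth_weight")
    mark(raw["gestational_age_weeks"].to_numpy(float) < 22.0, "low_gestational_age")

    included = raw.loc[reason == ""].copy()
    ledger = {code: int((reason == code).sum()) for code, _ in EXCLUSION_REASONS}
    ledger["raw"] = n
    ledger["included"] = len(included)
    return included, ledger


@dataclass
class GrowthReference:
    """Sex-specific 10th-percentile birth weight per completed week.

    ``table`` is indexed by (sex, week) with columns p10 and n; sparse cells
    were pooled with the nearest adequate week and any non-monotone
    percentile sequence repaired upward, with both events logged.
    """

    table: pd.DataFrame
    min_cell_size: int = 20
    pooled_cells: list[tuple[str, int, int]] = field(default_factory=list)
    monotonicity_repairs: list[tuple[str, int]] = field(default_factory=list)

    def p10(self, sex: str, week: int) -> float:
        key = (sex, int(week))
        if key in self.table.index:
            return float(self.table.loc[key, "p10"])
        # fall back to nearest available week for this sex
        weeks = np.array([w for s, w in self.table.index if s == sex])
        if weeks.size == 0:
            raise KeyError(f"no reference cells for sex {sex!r}")
        nearest = int(weeks[np.argmin(np.abs(weeks - int(week)))])
        return float(self.table.loc[(sex, nearest), "p10"])


def build_growth_reference(included: pd.DataFrame,
                           min_cell_size: int = 20) -> GrowthReference:
    """Internal 10th-percentile reference from the included cohort.

    Cells are (sex, completed gestational week); the percentile is the
    linear-interpolation empirical quantile. Cells below ``min_cell_size``
    are pooled with the nearest week (same sex) until adequate.
    """
    if len(included) == 0:
        raise ValueError("no data to build growth reference")
    df = included[["sex", "gestational_age_weeks", "birth_weight_g"]].dropna()
    df = df.assign(week=np.floor(df["gestational_age_weeks"].to_numpy(float)).astype(int))

    rows = []
    pooled: list[tuple[str, int, int]] = []
    for sex, grp in df.groupby("sex"):
        weeks = np.sort(grp["week"].unique())
        counts = grp.groupby("week").size()
        for wk in weeks:
            cell_weeks = [int(wk)]
            n_cell = int(counts.loc[wk])
            candidates = [int(w) for w in weeks if w != wk]
            candidates.sort(key=lambda w: (abs(w - wk), w))
            while n_cell < min_cell_size and candidates:
                nxt = candidates.pop(0)
                cell_weeks.append(nxt)
                n_cell += int(counts.loc[nxt])
                pooled.append((str(sex), int(wk), nxt))
            weights = grp.loc[grp["week"].isin(cell_weeks), "birth_weight_g"]
            rows.append({"sex": sex, "week": int(wk),
                         "p10": float(np.percentile(weights.to_numpy(float), 10)),
                         "n": int(counts.loc[wk])})
    table = pd.DataFrame(rows).set_index(["sex", "week"]).sort_index()

    repairs: list[tuple[str, int]] = []
    for sex in table.index.get_level_values(0).unique():
        sub = table.loc[sex]
        p10 = sub["p10"].to_numpy().copy()
        fixed = np.maximum.accumulate(p10)
        for wk, old, new in zip(sub.index, p10, fixed):
            if new != old:
                repairs.append((str(sex), int(wk)))
        table.loc[sex, "p10"] = fixed
    return GrowthReference(table, min_cell_size, pooled, repairs)


def classify_outcomes(included: pd.DataFrame,
                      reference: GrowthReference) -> pd.DataFrame:
    """Derive the four outcomes for every included birth.

    Missing source fields yield missing outcome flags; records are never
    dropped here. Idempotent: re-running on its own output changes nothing.
    """
    ga = included["gestational_age_weeks"].to_numpy(float)
    weight = included["birth_weight_g"].to_numpy(float)
    apgar = included["apgar5"].to_numpy(float) if "apgar5" in included.columns \
        else np.full(len(included), np.nan)
    sex = included["sex"].to_numpy()

    preterm = np.where(np.isnan(ga), np.nan, (ga < 37.0).astype(float))
    term_weight = np.where((~np.isnan(ga)) & (ga >= 37.0), weight, np.nan)
    low_apgar = np.where(np.isnan(apgar), np.nan, (apgar < 7.0).astype(float))

    sga = np.full(len(included), np.nan)
    ok = (~np.isnan(ga)) & (~np.isnan(weight))
    weeks = np.floor(ga[ok]).astype(int)
    cut = np.array([reference.p10(s, w) for s, w in zip(sex[ok], weeks)])
    sga[ok] = (weight[ok] < cut).astype(float)  # strictly below; boundary is not SGA

    out = pd.DataFrame({
        "birth_id": included["birth_id"].to_numpy(),
        "preterm": preterm,
        "sga": sga,
        "low_apgar": low_apgar,
        "term_birth_weight_g": term_weight,
    }, index=included.index)
    return out
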