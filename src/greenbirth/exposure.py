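"""Residential greenness exposure assignment.

Each birth receives an NDVI summary computed from a raster stack of 16-day
vegetation composites: the mean (or max) of all raster cells whose centre
lies within a buffer radius of the home, over the composites falling in a
three-season window anchored to the birth date. Summaries are then cut into
community-type-specific tertiles; the analysis contrast is tertiles 2-3
("greener") versus tertile 1.

Seasons are meteorological: winter = December-February (December counts
toward the winter labelled by the following January), spring = March-May,
summer = June-August, fall = September-November. A child born more than
halfway through a season is assigned the season of birth plus the two prior
seasons; otherwise the three seasons preceding the season of birth.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterStack",
    "SeasonInstance",
    "NoDataError",
    "season_of_date",
    "season_window",
    "buffer_mean",
    "assign_exposure",
    "dichotomize_at_percentile",
    "tertile_cutpoints",
]

SEASONS = ("winter", "spring", "summer", "fall")
_SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


class NoDataError(ValueError):
    """Raised when a buffer/window contains no usable raster cells."""


@dataclass(frozen=True, order=True)
class SeasonInstance:
    """One concrete season, e.g. spring 2009.

    Winter is labelled by the year of its January/February, so winter 2009
    spans 1 Dec 2008 - 28 Feb 2009.
    """

    year: int
    rank: int  # 0=winter, 1=spring, 2=summer, 3=fall

    @property
    def name(self) -> str:
        return SEASONS[self.rank]

    @property
    def start(self) -> date:
        if self.rank == 0:
            return date(self.year - 1, 12, 1)
        return date(self.year, 3 * self.rank, 1)

    @property
    def end(self) -> date:
        first_month = {0: 12, 1: 3, 2: 6, 3: 9}[self.rank]
        last_month = (first_month + 2 - 1) % 12 + 1
        year = self.year
        last_day = calendar.monthrange(year, last_month)[1]
        return date(year, last_month, last_day)

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def shift(self, k: int) -> "SeasonInstance":
        n = self.year * 4 + self.rank + k
        return SeasonInstance(n // 4, n % 4)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.name} {self.year}"


def season_of_date(d: date) -> SeasonInstance:
    """Season instance containing ``d`` (December -> next year's winter)."""
    name = _SEASON_OF_MONTH[d.month]
    year = d.year + 1 if d.month == 12 else d.year
    return SeasonInstance(year, SEASONS.index(name))


def season_window(birth_date: date) -> list[SeasonInstance]:
    """Three consecutive season instances assigned to a birth.

    Births in the first half of their season (including the midpoint day)
    get the three prior seasons; births more than halfway through get the
    two prior seasons plus the season of birth.
    """
    s = season_of_date(birth_date)
    day = (birth_date - s.start).days + 1
    half = -(-s.n_days // 2)  # ceil; the midpoint day is "not more than halfway"
    if day > half:
        return [s.shift(-2), s.shift(-1), s]
    return [s.shift(-3), s.shift(-2), s.shift(-1)]


@dataclass
class RasterStack:
    """NDVI composite time series on a regular grid.

    ``values`` has shape (n_dates, ny, nx); cell (i, j) of composite t has
    its centre at (x0 + (j + 0.5) * resolution, y0 + (i + 0.5) * resolution)
    in a local planar frame (metres). Missing cells are NaN.
    """

    values: np.ndarray
    x0: float
    y0: float
    resolution: float
    dates: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_dates, ny, nx)")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("dates length must match values.shape[0]")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("composite dates must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("NDVI values must lie in [-1, 1]")

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def nx(self) -> int:
        return self.values.shape[2]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0,
                self.x0 + self.nx * self.resolution,
                self.y0 + self.ny * self.resolution)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.extent
        return (x0 <= x < x1) and (y0 <= y < y1)

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        j = int((x - self.x0) // self.resolution)
        i = int((y - self.y0) // self.resolution)
        return i, j

    def date_indices(self, window: Sequence[SeasonInstance]) -> np.ndarray:
        lo, hi = window[0].start, window[-1].end
        return np.array([k for k, d in enumerate(self.dates) if lo <= d <= hi],
                        dtype=int)

    # --- plain-text persistence -------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "x0": self.x0, "y0": self.y0, "resolution": self.resolution,
            "dates": [d.isoformat() for d in self.dates],
            "shape": list(self.values.shape),
        }
        (directory / "raster.json").write_text(json.dumps(meta, indent=1))
        np.savez_compressed(directory / "stack.npz", values=self.values)

    @classmethod
    def load(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        meta = json.loads((directory / "raster.json").read_text())
        values = np.load(directory / "stack.npz")["values"]
        dates = [date.fromisoformat(s) for s in meta["dates"]]
        return cls(values, meta["x0"], meta["y0"], meta["resolution"], dates)


def _buffer_pixels(raster: RasterStack, x: float, y: float,
                   radius_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of cells whose centre is within radius of (x, y).

    The pixel containing the home is always included.
    """
    res = raster.resolution
    hi_i, hi_j = raster.pixel_of(x, y)
    r_px = int(radius_m // res) + 1
    ii = np.arange(max(0, hi_i - r_px), min(raster.ny, hi_i + r_px + 1))
    jj = np.arange(max(0, hi_j - r_px), min(raster.nx, hi_j + r_px + 1))
    cy = raster.y0 + (ii + 0.5) * res
    cx = raster.x0 + (jj + 0.5) * res
    d2 = (cy[:, None] - y) ** 2 + (cx[None, :] - x) ** 2
    mask = d2 <= radius_m ** 2 + 1e-6
    if 0 <= hi_i < raster.ny and 0 <= hi_j < raster.nx:
        mask[np.searchsorted(ii, hi_i), np.searchsorted(jj, hi_j)] = True
    rows, cols = np.nonzero(mask)
    return ii[rows], jj[cols]


def buffer_mean(raster: RasterStack, x: float, y: float, radius_m: float,
                dates: Iterable[date] | None = None) -> float:
    """Mean NDVI over all (cell, composite) pairs in the buffer.

    ``dates`` selects composites (default: all); missing cells are excluded
    from both numerator and denominator.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if not raster.contains(x, y):
        raise NoDataError(f"point ({x}, {y}) outside raster extent")
    if dates is None:
        t_idx = np.arange(len(raster.dates))
    else:
        wanted = set(dates)
        t_idx = np.array([k for k, d in enumerate(raster.dates) if d in wanted],
                         dtype=int)
    rows, cols = _buffer_pixels(raster, x, y, radius_m)
    if t_idx.size == 0 or rows.size == 0:
        raise NoDataError("empty buffer/date selection")
    block = raster.values[t_idx][:, rows, cols]
    if not np.isfinite(block).any():
        raise NoDataError("all cells missing in buffer")
    return float(np.nanmean(block))


def tertile_cutpoints(values: np.ndarray) -> tuple[float, float]:
    """Linear-interpolation empirical tertile boundaries."""
    v = np.asarray(values, float)
    c1, c2 = np.percentile(v, [100.0 / 3.0, 200.0 / 3.0])
    return float(c1), float(c2)


def _tertile_labels(values: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    v = np.asarray(values, float)
    # boundary values fall in the lower tertile
    return (1 + (v > cuts[0]).astype(int) + (v > cuts[1]).astype(int)).astype(int)


def _window_statistic(raster: RasterStack, x: float, y: float, radius_m: float,
                      t_idx: np.ndarray, statistic: str) -> float:
    rows, cols = _buffer_pixels(raster, x, y, radius_m)
    block = raster.values[t_idx][:, rows, cols]
    if not np.isfinite(block).any():
        raise NoDataError(f"all cells missing around ({x}, {y})")
    if statistic == "mean":
        return float(np.nanmean(block))
    if statistic == "max":
        per_date = np.nanmean(block, axis=1)
        return float(np.nanmax(per_date))
    raise ValueError(f"unknown statistic {statistic!r}")


def assign_exposure(
    cohort: pd.DataFrame,
    raster: RasterStack,
    radius_m: float = 250.0,
    statistic: Literal["mean", "max"] = "mean",
    extra_radii: Sequence[float] = (1250.0,),
) -> pd.DataFrame:
    """Assign per-birth NDVI summaries, tertiles, and the binary contrast.

    ``cohort`` needs columns birth_id, community_type, x, y, birth_date.
    Returns one row per birth: the primary summary (``ndvi``), summaries at
    the extra radii, community-type-specific and pooled tertile labels, and
    ``exposed`` = (community tertile >= 2).
    """
    required = {"birth_id", "community_type", "x", "y", "birth_date"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")

    bdates = [d.date() if hasattr(d, "date") and not isinstance(d, date) else d
              for d in cohort["birth_date"]]
    windows = [tuple(season_window(d)) for d in bdates]
    t_idx_cache: dict[tuple, np.ndarray] = {}
    for w in set(windows):
        idx = raster.date_indices(list(w))
        if idx.size == 0:
            raise NoDataError(f"no composites in season window {w[0]}..{w[-1]}")
        t_idx_cache[w] = idx

    radii = [float(radius_m)] + [float(r) for r in extra_radii if float(r) != float(radius_m)]
    xs = cohort["x"].to_numpy(float)
    ys = cohort["y"].to_numpy(float)
    for x, y in zip(xs, ys):
        if not raster.contains(x, y):
            raise NoDataError(f"address ({x}, {y}) outside raster")

    cols: dict[str, np.ndarray] = {}
    for r in radii:
        vals = np.empty(len(cohort))
        for k, (x, y, w) in enumerate(zip(xs, ys, windows)):
            vals[k] = _window_statistic(raster, x, y, r, t_idx_cache[w], statistic)
        cols[f"ndvi_{statistic}_{int(r)}"] = vals

    out = pd.DataFrame({"birth_id": cohort["birth_id"].to_numpy()})
    for name, vals in cols.items():
        out[name] = vals
    primary = f"ndvi_{statistic}_{int(radius_m)}"
    out["ndvi"] = out[primary]
    out["community_type"] = cohort["community_type"].to_numpy()

    out["tertile"] = 0
    cutpoints: dict[str, tuple[float, float]] = {}
    for ctype, grp in out.groupby("community_type"):
        cuts = tertile_cutpoints(grp["ndvi"].to_numpy())
        cutpoints[str(ctype)] = cuts
        out.loc[grp.index, "tertile"] = _tertile_labels(grp["ndvi"].to_numpy(), cuts)
    pooled_cuts = tertile_cutpoints(out["ndvi"].to_numpy())
    out["tertile_overall"] = _tertile_labels(out["ndvi"].to_numpy(), pooled_cuts)
    out["exposed"] = (out["tertile"] >= 2).astype(int)
    out.attrs["cutpoints"] = cutpoints
    out.attrs["cutpoints_overall"] = pooled_cuts
    out.attrs["radius_m"] = float(radius_m)
    out.attrs["statistic"] = statistic
    return out


def dichotomize_at_percentile(assignments: pd.DataFrame, p: float,
                              column: str = "ndvi") -> pd.Series:
    """Binary exposure: NDVI >= community-specific p-th percentile."""
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    exposed = pd.Series(0, index=assignments.index, dtype=int)
    for _, grp in assignments.groupby("community_type"):
        thr = np.percentile(grp[column].to_numpy(float), p)
        exposed.loc[grp.index] = (grp[column].to_numpy(float) >= thr).astype(int)
    return exposed
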