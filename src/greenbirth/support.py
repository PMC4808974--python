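"""Common-support restriction of a propensity-scored sample.

The analysis population is restricted, within community type, to subjects
whose propensity score lies between the 1st percentile of scores among the
exposed (greener tertiles) and the 99th percentile among the unexposed.
Subjects outside this interval have no comparable counterparts in the
other exposure group and would force model extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrimBounds", "NoCommonSupportError", "trim", "overlap_report",
           "plot_overlap"]


class NoCommonSupportError(ValueError):
    def __init__(self, lower: float, upper: float):
        super().__init__(
            f"no common support: lower bound {lower:.6f} exceeds upper bound "
            f"{upper:.6f}")
        self.lower = lower
        self.upper = upper


@dataclass
class TrimBounds:
    lower: float  # 1st percentile of scores among exposed
    upper: float  # 99th percentile of scores among unexposed
    lower_pct: float
    upper_pct: float
    n_exposed: int
    n_unexposed: int
    excluded_exposed: int
    excluded_unexposed: int
    # exclusions at each group's own defining bound: exposed below the
    # exposed 1st percentile, unexposed above the unexposed 99th percentile
    excluded_exposed_low: int = 0
    excluded_unexposed_high: int = 0

    @property
    def frac_excluded_exposed(self) -> float:
        return self.excluded_exposed / self.n_exposed

    @property
    def frac_excluded_unexposed(self) -> float:
        return self.excluded_unexposed / self.n_unexposed

    @property
    def frac_exposed_own_tail(self) -> float:
        return self.excluded_exposed_low / self.n_exposed

    @property
    def frac_unexposed_own_tail(self) -> float:
        return self.excluded_unexposed_high / self.n_unexposed

    def to_json_dict(self) -> dict:
        return {
            "lower": self.lower, "upper": self.upper,
            "percentiles": [self.lower_pct, self.upper_pct],
            "n_exposed": self.n_exposed, "n_unexposed": self.n_unexposed,
            "excluded_exposed": self.excluded_exposed,
            "excluded_unexposed": self.excluded_unexposed,
            "frac_excluded_exposed": self.frac_excluded_exposed,
            "frac_excluded_unexposed": self.frac_excluded_unexposed,
        }


def trim(scores: np.ndarray, exposed: np.ndarray,
         lower_pct: float = 1.0, upper_pct: float = 99.0,
         ) -> tuple[np.ndarray, TrimBounds]:
    """Retain subjects with lower <= score <= upper (inclusive bounds).

    Bounds are linear-interpolation empirical percentiles. Returns the
    boolean retained mask and the TrimBounds record.
    """
    scores = np.asarray(scores, float)
    exposed = np.asarray(exposed).astype(bool)
    if exposed.all() or (~exposed).all():
        raise ValueError("both exposure groups must be nonempty")
    lower = float(np.percentile(scores[exposed], lower_pct))
    upper = float(np.percentile(scores[~exposed], upper_pct))
    if lower > upper:
        raise NoCommonSupportError(lower, upper)
    retained = (scores >= lower) & (scores <= upper)
    bounds = TrimBounds(
        lower=lower, upper=upper, lower_pct=lower_pct, upper_pct=upper_pct,
        n_exposed=int(exposed.sum()), n_unexposed=int((~exposed).sum()),
        excluded_exposed=int((exposed & ~retained).sum()),
        excluded_unexposed=int(((~exposed) & ~retained).sum()),
        excluded_exposed_low=int((exposed & (scores < lower)).sum()),
        excluded_unexposed_high=int(((~exposed) & (scores > upper)).sum()),
    )
    return retained, bounds


def overlap_report(scores: np.ndarray, exposed: np.ndarray,
                   bounds: TrimBounds | None = None,
                   n_bins: int = 30) -> dict:
    """Score-distribution diagnostics per exposure group.

    Reports mirrored histograms, the trim bounds, and the share of each
    group lacking counterparts: exposed above the unexposed 99th-percentile
    bound and unexposed below the exposed 1st-percentile bound.
    """
    scores = np.asarray(scores, float)
    exposed = np.asarray(exposed).astype(bool)
    if bounds is None:
        lower = float(np.percentile(scores[exposed], 1.0)) if exposed.any() else np.nan
        upper = float(np.percentile(scores[~exposed], 99.0)) if (~exposed).any() else np.nan
    else:
        lower, upper = bounds.lower, bounds.upper
    edges = np.linspace(scores.min(), scores.max(), n_bins + 1)
    hist_exp, _ = np.histogram(scores[exposed], bins=edges)
    hist_une, _ = np.histogram(scores[~exposed], bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "hist_exposed": hist_exp.tolist(),
        "hist_unexposed": hist_une.tolist(),
        "lower": lower,
        "upper": upper,
        "share_exposed_no_counterpart": float(np.mean(scores[exposed] > upper)),
        "share_unexposed_no_counterpart": float(np.mean(scores[~exposed] < lower)),
    }


def plot_overlap(scores: np.ndarray, exposed: np.ndarray,
                 bounds: TrimBounds, path, title: str = "") -> None:
    """Mirrored propensity-score histograms with the trimmed regions shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = overlap_report(scores, exposed, bounds)
    edges = np.asarray(rep["bin_edges"])
    centers = (edges[:-1] + edges[1:]) / 2
    width = np.diff(edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, rep["hist_exposed"], width=width,
           color="#2a7d2e", alpha=0.8, label="tertiles 2-3")
    ax.bar(centers, -np.asarray(rep["hist_unexposed"]), width=width,
           color="#9ccc9c", alpha=0.8, label="tertile 1")
    for lo, hi in ((edges[0], bounds.lower), (bounds.upper, edges[-1])):
        if hi > lo:
            ax.axvspan(lo, hi, color="grey", alpha=0.35)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("propensity score (probability of tertiles 2-3)")
    ax.set_ylabel("births")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
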