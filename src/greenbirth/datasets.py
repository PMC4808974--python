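"""Published summary inputs used for descriptive reproduction.

The source study's restricted-sample descriptive table (counts by
community type and community-specific NDVI tertile) and the observed
tertile cutpoints. These printed numbers are inputs: the package
recomputes derived quantities (prevalences, tertile cross-tabulations,
unadjusted odds ratios) from them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["table1_counts", "OBSERVED_TERTILE_CUTPOINTS"]

# community-specific NDVI tertile cutpoint (tertile 1 vs 2-3) observed in
# the source cohort; shipped as a regression fixture for the audit format
OBSERVED_TERTILE_CUTPOINTS = {"city": 0.43, "borough": 0.49, "township": 0.54}

_TABLE1 = [
    # community_type, tertile group, group n, events by outcome, cross-tab
    dict(community_type="city", tertile="1", n=927,
         preterm=127, sga=126, low_apgar=17, overall_t1=927),
    dict(community_type="city", tertile="2-3", n=1636,
         preterm=195, sga=180, low_apgar=41, overall_t1=889),
    dict(community_type="borough", tertile="1", n=1253,
         preterm=117, sga=109, low_apgar=26, overall_t1=1253),
    dict(community_type="borough", tertile="2-3", n=2544,
         preterm=297, sga=237, low_apgar=39, overall_t1=10),
    dict(community_type="township", tertile="1", n=2249,
         preterm=248, sga=210, low_apgar=42, overall_t1=1195),
    dict(community_type="township", tertile="2-3", n=4212,
         preterm=465, sga=352, low_apgar=88, overall_t1=0),
]


def table1_counts() -> pd.DataFrame:
    """Restricted-sample counts by community type and NDVI tertile group.

    Columns: group size ``n``, event counts for preterm / small-for-
    gestational-age / low 5-min Apgar, and ``overall_t1`` — how many of the
    group's births fall in tertile 1 of the pooled (all-community) NDVI
    distribution.
    """
    return pd.DataFrame(_TABLE1)


def expand_2x2(n_exposed: int, events_exposed: int,
               n_unexposed: int, events_unexposed: int) -> pd.DataFrame:
    """Individual-level rows for a 2x2 table (for unadjusted model fits)."""
    rows = []
    for exposed, n, ev in ((1, n_exposed, events_exposed),
                           (0, n_unexposed, events_unexposed)):
        rows += [{"exposed": exposed, "event": 1}] * ev
        rows += [{"exposed": exposed, "event": 0}] * (n - ev)
    return pd.DataFrame(rows)
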