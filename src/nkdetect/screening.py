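"""Per-feature normality testing and Kruskal-Wallis group screening.

The normality screen runs the Lilliefors-corrected Kolmogorov-Smirnov test
(parameters estimated from the data, as statistics packages report in their
normality tables; the plain KS test with estimated parameters is
anticonservative) and the Shapiro-Wilk test on the pooled two-group values.

The group screen is the two-group Kruskal-Wallis rank test (tie-corrected,
one degree of freedom); features with p below alpha are nominated as the
statistically significant ("STAT") set.  No multiple-testing correction is
applied by default, matching a raw per-feature alpha = 0.05 selection; a
Bonferroni option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cohort import Cohort
from .registry import PSA_ID, feature_name

__all__ = [
    "NormalityRow",
    "KWRow",
    "normality_screen",
    "kruskal_wallis_screen",
]


@dataclass(frozen=True)
class NormalityRow:
    feature_id: int
    name: str
    ks_statistic: float
    ks_p: float
    sw_statistic: float
    sw_p: float
    df: int
    constant: bool = False


@dataclass(frozen=True)
class KWRow:
    feature_id: int
    name: str
    chi_sq: float
    p: float


def _columns(cohort: Cohort, include_psa: bool) -> dict[int, np.ndarray]:
    cols: dict[int, np.ndarray] = {}
    if include_psa:
        cols[PSA_ID] = cohort.psa
    for j, fid in enumerate(cohort.feature_ids):
        cols[fid] = cohort.values[:, j]
    return cols


def normality_screen(
    cohort: Cohort, lilliefors_correction: bool = True, pooled: bool = True
) -> list[NormalityRow]:
    """Both normality tests per feature on the pooled values (default) with
    df = n.  Constant features are flagged and their tests skipped."""
    if cohort.n < 8:
        raise ValueError("normality screen needs n >= 8")
    rows = []
    for fid, vec in _columns(cohort, include_psa=False).items():
        groups = [vec] if pooled else [vec[cohort.labels == g] for g in (0, 1)]
        # per-group mode tests each group and reports the worse (larger) stat
        ks_s = ks_p = sw_s = sw_p = -np.inf
        if np.ptp(vec) == 0:
            rows.append(
                NormalityRow(fid, feature_name(fid), np.nan, np.nan, np.nan,
                             np.nan, len(vec), constant=True)
            )
            continue
        for g in groups:
            if lilliefors_correction:
                s, p = lilliefors(g, dist="norm")
            else:
                s, p = stats.kstest(g, "norm", args=(g.mean(), g.std(ddof=1)))
            if s > ks_s:
                ks_s, ks_p = float(s), float(p)
            s, p = stats.shapiro(g)
            if s > sw_s or sw_p == -np.inf:
                sw_s, sw_p = float(s), float(p)
        rows.append(
            NormalityRow(fid, feature_name(fid), ks_s, ks_p, sw_s, sw_p, len(vec))
        )
    return rows


def normality_summary(rows: list[NormalityRow], alpha: float = 0.05) -> dict[str, int]:
    return {
        "normal_by_ks": sum(1 for r in rows if not r.constant and r.ks_p > alpha),
        "normal_by_sw": sum(1 for r in rows if not r.constant and r.sw_p > alpha),
        "constant": sum(1 for r in rows if r.constant),
    }


def kruskal_wallis_screen(
    cohort: Cohort,
    alpha: float = 0.05,
    correction: str | None = None,
    include_psa: bool = True,
) -> tuple[list[KWRow], list[int]]:
    """Two-group Kruskal-Wallis per feature (and PSA); returns the rows and
    the ids of features selected at ``alpha``.  ``correction='bonferroni'``
    divides alpha by the number of feature tests."""
    g0 = cohort.labels == 0
    g1 = cohort.labels == 1
    if not g0.any() or not g1.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for fid, vec in _columns(cohort, include_psa=include_psa).items():
        a, b = vec[g0], vec[g1]
        if np.ptp(vec) == 0:  # all pooled values tied
            rows.append(KWRow(fid, feature_name(fid), 0.0, 1.0))
            continue
        h, p = stats.kruskal(a, b)
        rows.append(KWRow(fid, feature_name(fid), float(h), float(p)))
    thresh = alpha
    n_feature_tests = sum(1 for r in rows if r.feature_id != PSA_ID)
    if correction == "bonferroni":
        thresh = alpha / n_feature_tests
    selected = [r.feature_id for r in rows if r.feature_id != PSA_ID and r.p < thresh]
    return rows, selected


def normality_table(rows: list[NormalityRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("feature_id")


def kw_table(rows: list[KWRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("feature_id")
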