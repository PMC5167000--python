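"""Per-region Early-vs-Late thickness comparison with per-hemisphere FDR.

Each region's mean thickness is compared between the Early and Late
stage groups with a two-sample t-test (Welch by default; pooled variance
available for sensitivity analysis).  The difference is oriented
Early - Late, so positive values mean the Late group is thinner.
Multiplicity is controlled separately within each hemisphere's set of
regions by the Benjamini-Hochberg step-up procedure at FDR level q
(0.1 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import EARLY, LATE, CohortTable, ThicknessMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR_Q = 0.1


@dataclass(frozen=True)
class RegionComparison:
    region: str
    hemisphere: str
    difference: float  # mean Early - mean Late, mm
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = float("nan")  # BH-adjusted, filled by fdr_by_hemisphere
    discovery: bool = False


def region_ttest(
    early_values,
    late_values,
    equal_var: bool = False,
    ci_level: float = 0.95,
) -> tuple[float, float, float, float]:
    """Two-sample t-test of Early vs Late values for one region.

    Returns ``(difference, ci_low, ci_high, p_value)`` with
    difference = mean(early) - mean(late) and a two-sided p.  Welch's
    unequal-variance statistic is the default.  If both groups have zero
    variance, p is 1 for equal means and 0 otherwise, with a width-zero CI.
    """
    a = np.asarray(early_values, dtype=float)
    b = np.asarray(late_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 values per group, got {a.size} and {b.size}")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return diff, diff, diff, 1.0 if diff == 0.0 else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(confidence_level=ci_level)
    return diff, float(ci.low), float(ci.high), float(res.pvalue)


def compare_regions(
    cohort: CohortTable,
    thickness: ThicknessMatrix,
    q: float = DEFAULT_FDR_Q,
    equal_var: bool = False,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Early-vs-Late comparison for every region, FDR-controlled per hemisphere.

    Returns one row per (region, hemisphere) with difference, CI, p,
    BH-adjusted q and the discovery flag.
    """
    early = cohort.stage_mask(EARLY)
    late = cohort.stage_mask(LATE)
    rows = []
    for hemi in ("left", "right"):
        for region in thickness.regions:
            v = thickness.values(region, hemi)
            diff, lo, hi, p = region_ttest(v[early], v[late], equal_var=equal_var, ci_level=ci_level)
            rows.append(
                RegionComparison(
                    region=region, hemisphere=hemi, difference=diff, ci_low=lo, ci_high=hi, p_value=p
                )
            )
    return fdr_by_hemisphere(pd.DataFrame([vars(r) for r in rows]), q=q)


def fdr_by_hemisphere(comparisons: pd.DataFrame, q: float = DEFAULT_FDR_Q) -> pd.DataFrame:
    """Benjamini-Hochberg step-up applied separately within each hemisphere.

    Fills ``q_value`` (BH-adjusted p) and ``discovery`` (adjusted <= q).
    An empty hemisphere set is a warned no-op.
    """
    if not 0 < q < 1:
        raise ValueError(f"FDR level q must be in (0, 1), got {q}")
    out = comparisons.copy()
    if "q_value" not in out.columns:
        out["q_value"] = np.nan
    if "discovery" not in out.columns:
        out["discovery"] = False
    for hemi in ("left", "right"):
        mask = out["hemisphere"] == hemi
        if not mask.any():
            logger.warning("no comparisons for %s hemisphere; FDR skipped", hemi)
            continue
        p = out.loc[mask, "p_value"].to_numpy(dtype=float)
        _, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        out.loc[mask, "q_value"] = q_adj
        # discovery <=> BH-adjusted value <= q (equivalent to the step-up rule)
        out.loc[mask, "discovery"] = q_adj <= q
    return out
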