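"""Hemispheric asymmetry analyses.

Three views of left-right asymmetry in stage-stratified cortical data:

* homologous-pair bookkeeping between the two hemispheres' columns;
* Pearson correlation between disease duration and regional thickness
  within a subgroup (e.g. left-handed patients), per hemisphere;
* the within-patient left-vs-right thickness comparison (paired t-test)
  for motor-lateralized subsets, reported as per-side "mean +/- SD";
* classification of a homologous pair by which hemisphere's bootstrapped
  Early-minus-Late slope contrast excludes zero (left-only / right-only /
  both / neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .atlas import thickness_column
from .cohort_io import CohortTable, ThicknessMatrix, subgroup_mask
from .rates import SlopeDifference

MIN_CORR_N = 3


@dataclass(frozen=True)
class HomologousPair:
    region: str
    left_column: str
    right_column: str


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    hemisphere: str
    subgroup: str
    n: int
    r: float
    p_value: float


@dataclass(frozen=True)
class PairedHemiResult:
    region: str
    subgroup: str
    n: int
    left_mean: float
    left_sd: float
    right_mean: float
    right_sd: float
    difference: float  # mean(left - right), mm
    p_value: float

    def side_summary(self, hemisphere: str, digits: int = 2) -> str:
        """Render one side as ``mean +/- SD``, e.g. ``'3.42 ± 0.34'``."""
        m, s = {
            "left": (self.left_mean, self.left_sd),
            "right": (self.right_mean, self.right_sd),
        }[hemisphere]
        return f"{m:.{digits}f} ± {s:.{digits}f}"


def homologous_pairs(thickness: ThicknessMatrix) -> list[HomologousPair]:
    """One pair per region, with the two hemispheres' flat column keys."""
    return [
        HomologousPair(
            region=r,
            left_column=thickness_column("left", r),
            right_column=thickness_column("right", r),
        )
        for r in thickness.regions
    ]


def _resolve_mask(cohort: CohortTable, subgroup) -> tuple[np.ndarray, str]:
    if subgroup is None:
        return np.ones(cohort.n, dtype=bool), "all"
    if isinstance(subgroup, str):
        return subgroup_mask(cohort, subgroup), subgroup
    if callable(subgroup):
        mask = np.asarray(subgroup(cohort), dtype=bool)
        label = getattr(subgroup, "__name__", "custom")
        return mask, label
    mask = np.asarray(subgroup, dtype=bool)
    return mask, "mask"


def duration_correlation(
    cohort: CohortTable,
    thickness: ThicknessMatrix,
    region: str,
    hemisphere: str,
    subgroup=None,
) -> CorrelationResult:
    """Pearson r (two-sided p) between duration and thickness in a subgroup.

    ``subgroup`` may be None (all patients), a named filter
    ('left-handed', 'right-handed', 'motor-left', 'motor-right'), a
    boolean mask, or a predicate on the cohort.
    """
    mask, label = _resolve_mask(cohort, subgroup)
    x = cohort.duration.to_numpy(dtype=float)[mask]
    y = thickness.values(region, hemisphere)[mask]
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if x.size < MIN_CORR_N:
        raise ValueError(
            f"subgroup {label!r} has {x.size} usable patients; need >= {MIN_CORR_N}"
        )
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in duration or thickness: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        region=region, hemisphere=hemisphere, subgroup=label, n=int(x.size),
        r=float(r), p_value=float(p),
    )


def paired_hemisphere_test(
    cohort: CohortTable,
    thickness: ThicknessMatrix,
    region: str,
    subgroup=None,
) -> PairedHemiResult:
    """Within-patient left-vs-right comparison for one region and subgroup.

    Per-side mean and SD plus a paired two-sided t-test on the
    within-patient left - right differences.  Identical columns give a
    zero difference with p = 1.
    """
    mask, label = _resolve_mask(cohort, subgroup)
    left = thickness.values(region, "left")[mask]
    right = thickness.values(region, "right")[mask]
    finite = np.isfinite(left) & np.isfinite(right)
    left, right = left[finite], right[finite]
    if left.size < 2:
        raise ValueError(
            f"subgroup {label!r} has {left.size} patients with both hemispheres; need >= 2"
        )
    d = left - right
    if np.allclose(d, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(left, right).pvalue)
    return PairedHemiResult(
        region=region,
        subgroup=label,
        n=int(left.size),
        left_mean=float(left.mean()),
        left_sd=float(left.std(ddof=1)),
        right_mean=float(right.mean()),
        right_sd=float(right.std(ddof=1)),
        difference=float(d.mean()),
        p_value=p,
    )


LATERALIZED_LEFT_ONLY = "left-only"
LATERALIZED_RIGHT_ONLY = "right-only"
LATERALIZED_BOTH = "both"
LATERALIZED_NEITHER = "neither"


def asymmetry_contrast(
    left: SlopeDifference, right: SlopeDifference
) -> tuple[SlopeDifference, SlopeDifference, str]:
    """Classify a homologous pair by which hemisphere's slope-difference CI excludes zero.

    Both inputs must come from matched settings (same region, n_boot,
    alpha, seed); a mismatch is an error, not a silent comparison.
    """
    if left.hemisphere != "left" or right.hemisphere != "right":
        raise ValueError("expected (left-hemisphere, right-hemisphere) slope differences")
    if left.region != right.region:
        raise ValueError(f"mismatched regions: {left.region!r} vs {right.region!r}")
    for attr in ("n_boot", "alpha", "seed"):
        if getattr(left, attr) != getattr(right, attr):
            raise ValueError(
                f"mismatched {attr}: {getattr(left, attr)!r} vs {getattr(right, attr)!r}"
            )
    sig_l = left.significant_early or left.significant_late
    sig_r = right.significant_early or right.significant_late
    label = {
        (True, False): LATERALIZED_LEFT_ONLY,
        (False, True): LATERALIZED_RIGHT_ONLY,
        (True, True): LATERALIZED_BOTH,
        (False, False): LATERALIZED_NEITHER,
    }[(sig_l, sig_r)]
    return left, right, label
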