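"""Tests for hemispheric asymmetry analyses: duration-thickness
correlations, paired left-vs-right tests and homologous-pair contrasts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cortasym import (
    SimulationConfig,
    SlopeDifference,
    asymmetry_contrast,
    duration_correlation,
    generate_cohort,
    homologous_pairs,
    paired_hemisphere_test,
)
from cortasym.cohort_io import ThicknessMatrix


def pearson_oracle(x, y):
    """Closed-form product-moment correlation, coded independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def _swap_hemispheres(thick: ThicknessMatrix) -> ThicknessMatrix:
    df = thick.df.copy()
    swapped = df.copy()
    for region in thick.regions:
        swapped[("left", region)] = df[("right", region)]
        swapped[("right", region)] = df[("left", region)]
    return ThicknessMatrix(swapped)


# -- duration correlation -------------------------------------------------

def test_perfect_linear_decline_gives_minus_one(small_cohort):
    cohort, thick, _ = small_cohort
    df = thick.df.copy()
    d = cohort.duration.to_numpy()
    df[("left", "G_insular_short")] = 4.0 - 0.05 * d
    res = duration_correlation(cohort, ThicknessMatrix(df), "G_insular_short", "left")
    assert res.r == pytest.approx(-1.0, abs=1e-12)


def test_five_point_toy_matches_pearson_oracle(small_cohort):
    cohort, thick, _ = small_cohort
    mask = np.zeros(cohort.n, dtype=bool)
    mask[:5] = True
    res = duration_correlation(cohort, thick, "G_insular_short", "left", subgroup=mask)
    x = cohort.duration.to_numpy()[:5]
    y = thick.values("G_insular_short", "left")[:5]
    assert res.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
    assert res.n == 5


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_correlation_matches_oracle_on_random_draws(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(2, 27, 12)
    y = 3.0 - 0.03 * x + rng.normal(0, 0.2, 12)
    r, p = stats.pearsonr(x, y)
    assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)


def test_correlation_invariant_to_affine_rescaling(small_cohort):
    cohort, thick, _ = small_cohort
    base = duration_correlation(cohort, thick, "G_insular_short", "left")
    df = thick.df.copy()
    # positive affine map of thickness: mm -> rescaled units within bounds
    df[("left", "G_insular_short")] = 0.5 * df[("left", "G_insular_short")] + 1.0
    scaled = duration_correlation(
        cohort, ThicknessMatrix(df), "G_insular_short", "left"
    )
    assert scaled.r == pytest.approx(base.r, abs=1e-12)
    assert scaled.p_value == pytest.approx(base.p_value, abs=1e-12)


def test_zero_variance_correlation_is_an_error(small_cohort):
    cohort, thick, _ = small_cohort
    df = thick.df.copy()
    df[("left", "G_insular_short")] = 2.5
    with pytest.raises(ValueError, match="zero variance"):
        duration_correlation(cohort, ThicknessMatrix(df), "G_insular_short", "left")


def test_too_small_subgroup_is_an_error(small_cohort):
    cohort, thick, _ = small_cohort
    mask = np.zeros(cohort.n, dtype=bool)
    mask[:2] = True
    with pytest.raises(ValueError, match="need >= 3"):
        duration_correlation(cohort, thick, "G_insular_short", "left", subgroup=mask)


def test_generating_correlation_recovered_in_left_handed_subgroup():
    """Noise SD solved from r = b*sd_x / sqrt(b^2 sd_x^2 + s^2) recovers
    the target population correlation in a left-handed-only cohort."""
    b, target_r = -0.063, -0.83
    lo, hi = 2.2, 9.9
    sd_x = (hi - lo) / np.sqrt(12)
    sigma = abs(b) * sd_x * np.sqrt(1 / target_r**2 - 1)
    cfg = SimulationConfig(
        n_early=4000, n_late=10, regions=("S_orbital_med-olfact",),
        rate_early=b, noise_sd=sigma,
        handed_proportions=(0.0, 1.0, 0.0), seed=77,
    )
    cohort, thick, _ = generate_cohort(cfg)
    mask = (cohort.df["handedness"] == "L").to_numpy() & cohort.stage_mask("Early")
    res = duration_correlation(
        cohort, thick, "S_orbital_med-olfact", "left", subgroup=mask
    )
    assert res.r == pytest.approx(target_r, abs=0.02)


# -- paired hemisphere test ----------------------------------------------

def test_identical_hemispheres_give_zero_difference_unit_p(small_cohort):
    cohort, thick, _ = small_cohort
    df = thick.df.copy()
    df[("right", "G_insular_short")] = df[("left", "G_insular_short")]
    res = paired_hemisphere_test(cohort, ThicknessMatrix(df), "G_insular_short")
    assert res.difference == 0.0
    assert res.p_value == 1.0


def test_six_patient_toy_matches_one_sample_t_on_differences(small_cohort):
    cohort, thick, _ = small_cohort
    mask = np.zeros(cohort.n, dtype=bool)
    mask[:6] = True
    res = paired_hemisphere_test(cohort, thick, "G_insular_short", subgroup=mask)
    left = thick.values("G_insular_short", "left")[:6]
    right = thick.values("G_insular_short", "right")[:6]
    oracle = stats.ttest_1samp(left - right, 0.0)
    assert res.p_value == pytest.approx(float(oracle.pvalue), abs=1e-12)
    assert res.difference == pytest.approx(float((left - right).mean()), abs=1e-12)


def test_paired_test_antisymmetric_under_hemisphere_swap(small_cohort):
    cohort, thick, _ = small_cohort
    base = paired_hemisphere_test(cohort, thick, "G_insular_short")
    swapped = paired_hemisphere_test(
        cohort, _swap_hemispheres(thick), "G_insular_short"
    )
    assert swapped.difference == pytest.approx(-base.difference, abs=1e-12)
    assert swapped.p_value == pytest.approx(base.p_value, abs=1e-12)
    assert swapped.left_mean == pytest.approx(base.right_mean)
    assert swapped.right_sd == pytest.approx(base.left_sd)


def test_side_summary_renders_mean_plus_minus_sd():
    r = _make_paired(left_mean=3.4213, left_sd=0.3391, right_mean=3.28, right_sd=0.33)
    assert r.side_summary("left") == "3.42 ± 0.34"
    assert r.side_summary("right") == "3.28 ± 0.33"


def _make_paired(**kw):
    from cortasym import PairedHemiResult

    defaults = dict(
        region="G_insular_short", subgroup="motor-right", n=10,
        left_mean=3.42, left_sd=0.34, right_mean=3.28, right_sd=0.33,
        difference=0.14, p_value=0.04,
    )
    defaults.update(kw)
    return PairedHemiResult(**defaults)


# -- homologous pairs and asymmetry contrast -----------------------------

def test_homologous_pairs_cover_all_regions(small_cohort):
    _, thick, _ = small_cohort
    pairs = homologous_pairs(thick)
    assert len(pairs) == len(thick.regions)
    assert pairs[0].left_column.startswith("lh_")
    assert pairs[0].right_column.startswith("rh_")


def _sd(hemi, sig_early=False, sig_late=False, **kw):
    defaults = dict(
        region="G_insular_short", hemisphere=hemi, difference=-0.05,
        ci_low=-0.08 if sig_early else -0.02,
        ci_high=-0.02 if sig_early else (0.08 if not sig_late else 0.02),
        significant_early=sig_early, significant_late=sig_late,
        slope_early=-0.07, slope_late=-0.02, n_early=60, n_late=50,
        n_boot=500, alpha=0.05, seed=1,
    )
    if sig_late:
        defaults.update(ci_low=0.01, ci_high=0.09, difference=0.05)
    defaults.update(kw)
    return SlopeDifference(**defaults)


@pytest.mark.parametrize(
    "left_kw, right_kw, label",
    [
        (dict(sig_early=True), dict(), "left-only"),
        (dict(), dict(sig_early=True), "right-only"),
        (dict(sig_early=True), dict(sig_late=True), "both"),
        (dict(), dict(), "neither"),
    ],
)
def test_asymmetry_contrast_classification(left_kw, right_kw, label):
    left = _sd("left", **left_kw)
    right = _sd("right", **right_kw)
    assert asymmetry_contrast(left, right)[2] == label


def test_asymmetry_contrast_rejects_mismatched_settings():
    left = _sd("left", sig_early=True)
    right = _sd("right", n_boot=1000)
    with pytest.raises(ValueError, match="n_boot"):
        asymmetry_contrast(left, right)
    with pytest.raises(ValueError, match="region"):
        asymmetry_contrast(left, _sd("right", region="G_cuneus"))


def test_mirrored_data_swaps_left_only_and_right_only():
    """A left-only generating contrast classified on hemisphere-swapped
    data becomes right-only."""
    from cortasym import slope_difference

    cfg = SimulationConfig(
        n_early=200, n_late=200, regions=("r",),
        rate_early={("left", "r"): -0.07, ("right", "r"): -0.02},
        rate_late=-0.02, noise_sd=0.1, seed=13,
    )
    cohort, thick, _ = generate_cohort(cfg)
    kw = dict(n_boot=500, seed=2)
    left = slope_difference(cohort, thick, "r", "left", **kw)
    right = slope_difference(cohort, thick, "r", "right", **kw)
    assert asymmetry_contrast(left, right)[2] == "left-only"

    mirrored = _swap_hemispheres(thick)
    left_m = slope_difference(cohort, mirrored, "r", "left", **kw)
    right_m = slope_difference(cohort, mirrored, "r", "right", **kw)
    assert asymmetry_contrast(left_m, right_m)[2] == "right-only"
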