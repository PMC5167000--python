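"""Synthetic cross-sectional PD cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
two-stage (Early / Late, split at a disease-duration cutoff) cohort in
which each region's thickness follows a piecewise-linear trajectory —
an independent linear segment per stage, ``baseline + rate * duration``
plus homoscedastic Gaussian measurement noise — alongside realistic
clinical covariates (age, sex, handedness, UPDRS-III Off/On totals and
per-extremity item scores with an optional lateralized shift).

The generator returns the ground-truth parameters it used so recovery
and calibration experiments can score the estimators against the truth.
All randomness flows from a single integer seed; identical config and
seed reproduce identical tables bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import DESTRIEUX_REGIONS, HEMISPHERES
from .cohort_io import (
    EARLY,
    LATE,
    N_EXTREMITY_ITEMS,
    CohortTable,
    ThicknessMatrix,
)

RegionKey = tuple[str, str]  # (hemisphere, region)

# Cohort-level clinical moments the covariate simulator draws from
# (age at assessment, UPDRS-III Off total, On-state improvement).
_AGE_MEAN, _AGE_SD = 62.2, 8.9
_UPDRS_OFF_MEAN, _UPDRS_OFF_SD = 41.1, 12.6
_IMPROVE_MEAN = {EARLY: 20.1, LATE: 24.5}
_IMPROVE_SD = {EARLY: 9.5, LATE: 10.6}
_MALE_FRACTION = 138 / 205


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _as_region_map(
    value, regions: tuple[str, ...], *, name: str
) -> dict[RegionKey, float]:
    """Broadcast a scalar / per-region / per-(hemi, region) value to a full map."""
    out: dict[RegionKey, float] = {}
    if isinstance(value, Mapping):
        for hemi in HEMISPHERES:
            for region in regions:
                if (hemi, region) in value:
                    out[(hemi, region)] = float(value[(hemi, region)])
                elif region in value:
                    out[(hemi, region)] = float(value[region])
                else:
                    raise SimulationConfigError(f"{name}: no value for ({hemi}, {region})")
    else:
        v = float(value)
        out = {(h, r): v for h in HEMISPHERES for r in regions}
    return out


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Rates are signed mm/year (negative = thinning); baselines are the
    thickness each stage segment extrapolates to at duration 0; noise is
    the per-region Gaussian measurement SD in mm.  Scalar values
    broadcast over all (hemisphere, region) pairs; mappings may be keyed
    by region name (both hemispheres) or by (hemisphere, region).
    """

    n_early: int = 109
    n_late: int = 96
    duration_range_early: tuple[float, float] = (2.2, 9.9)
    duration_range_late: tuple[float, float] = (10.1, 27.1)
    cutoff: float = 10.0
    regions: tuple[str, ...] = DESTRIEUX_REGIONS
    baseline_early: float | Mapping = 2.8
    baseline_late: float | Mapping = 2.8
    rate_early: float | Mapping = -0.005
    rate_late: float | Mapping = -0.03
    noise_sd: float | Mapping = 0.15
    handed_proportions: tuple[float, float, float] = (171 / 206, 21 / 206, 14 / 206)
    laterality_effect: float = 1.0
    lateralized_fractions: tuple[float, float] = (35 / 205, 32 / 205)  # (left, right)
    seed: int = 0

    def validate(self) -> None:
        if self.n_early < 0 or self.n_late < 0:
            raise SimulationConfigError("n_early/n_late: counts must be non-negative")
        for name, (lo, hi) in (
            ("duration_range_early", self.duration_range_early),
            ("duration_range_late", self.duration_range_late),
        ):
            if not (0 < lo <= hi):
                raise SimulationConfigError(f"{name}: need 0 < low <= high, got ({lo}, {hi})")
        if self.duration_range_early[1] > self.cutoff:
            raise SimulationConfigError(
                f"duration_range_early: high {self.duration_range_early[1]} exceeds "
                f"cutoff {self.cutoff}"
            )
        if self.duration_range_late[0] <= self.cutoff:
            raise SimulationConfigError(
                f"duration_range_late: low {self.duration_range_late[0]} must exceed "
                f"cutoff {self.cutoff}"
            )
        seen = set()
        for r in self.regions:
            if r in seen:
                raise SimulationConfigError(f"regions: duplicate region name {r!r}")
            seen.add(r)
        noise = _as_region_map(self.noise_sd, self.regions, name="noise_sd")
        if any(v < 0 for v in noise.values()):
            raise SimulationConfigError("noise_sd: must be >= 0")
        if abs(sum(self.handed_proportions) - 1.0) > 1e-8:
            raise SimulationConfigError(
                f"handed_proportions: must sum to 1, got {sum(self.handed_proportions)}"
            )
        if min(self.handed_proportions) < 0:
            raise SimulationConfigError("handed_proportions: must be non-negative")
        fl, fr = self.lateralized_fractions
        if fl < 0 or fr < 0 or fl + fr > 1:
            raise SimulationConfigError(
                "lateralized_fractions: need non-negative fractions summing to <= 1"
            )

    def region_map(self, which: str) -> dict[RegionKey, float]:
        return _as_region_map(getattr(self, which), self.regions, name=which)


@dataclass
class TrueParameters:
    """Ground truth behind one synthetic cohort (for recovery tests)."""

    rate_early: dict[RegionKey, float]
    rate_late: dict[RegionKey, float]
    #: mean Early thickness minus mean Late thickness, each stage evaluated
    #: at the midpoint of its duration range
    group_mean_difference: dict[RegionKey, float]
    null_region_flags: dict[RegionKey, bool]
    #: per-patient generating lateral side: 'left', 'right' or 'none'
    lateral_side: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def _clinical_covariates(
    rng: np.random.Generator, stages: np.ndarray, durations: np.ndarray, config: SimulationConfig
) -> pd.DataFrame:
    n = len(durations)
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 30.0, 85.0).round(1)
    # onset consistent with duration by construction
    age = np.maximum(age, durations + 26.0)
    onset = (age - durations).round(1)
    sex = np.where(rng.random(n) < _MALE_FRACTION, "M", "F")
    handed = rng.choice(["R", "L", "NR"], size=n, p=list(config.handed_proportions))
    off = np.clip(rng.normal(_UPDRS_OFF_MEAN, _UPDRS_OFF_SD, n), 5, 100).round().astype(int)
    early = stages == EARLY
    improve = rng.normal(
        np.where(early, _IMPROVE_MEAN[EARLY], _IMPROVE_MEAN[LATE]),
        np.where(early, _IMPROVE_SD[EARLY], _IMPROVE_SD[LATE]),
    )
    on = np.clip(off - improve.round().astype(int), 0, None)
    on = np.minimum(on, off)

    fl, fr = config.lateralized_fractions
    u = rng.random(n)
    lateral = np.where(u < fl, "left", np.where(u < fl + fr, "right", "none"))
    base = np.clip(rng.normal(1.5, 0.5, n), 0.2, 3.5)
    shift = config.laterality_effect
    left_mean = base + np.where(lateral == "left", shift, 0.0)
    right_mean = base + np.where(lateral == "right", shift, 0.0)
    k = N_EXTREMITY_ITEMS
    left_items = np.clip(
        np.rint(rng.normal(left_mean[:, None], 0.8, (n, k))), 0, 4
    ).astype(int)
    right_items = np.clip(
        np.rint(rng.normal(right_mean[:, None], 0.8, (n, k))), 0, 4
    ).astype(int)

    data = {
        "patient_id": [f"sub-{i + 1:04d}" for i in range(n)],
        "sex": sex,
        "age_assessment": age,
        "age_onset": onset,
        "duration": durations,
        "handedness": handed,
        "updrs3_off": off,
        "updrs3_on": on,
    }
    for i in range(k):
        data[f"left_ext_{i + 1}"] = left_items[:, i]
    for i in range(k):
        data[f"right_ext_{i + 1}"] = right_items[:, i]
    df = pd.DataFrame(data)
    df["_lateral_side"] = lateral
    return df


def generate_cohort(
    config: SimulationConfig,
) -> tuple[CohortTable, ThicknessMatrix, TrueParameters]:
    """Generate one synthetic cohort: clinical table, thickness matrix, truth.

    Durations are uniform within each stage's range; thickness for a
    patient in stage s is ``baseline_s + rate_s * duration + N(0, noise_sd)``
    per (hemisphere, region), with the two stage segments generated
    independently (no continuity constraint at the cutoff).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    d_early = rng.uniform(*config.duration_range_early, config.n_early)
    d_late = rng.uniform(*config.duration_range_late, config.n_late)
    durations = np.concatenate([d_early, d_late])
    stages = np.array([EARLY] * config.n_early + [LATE] * config.n_late)

    clinical = _clinical_covariates(rng, stages, durations, config)
    lateral = clinical.pop("_lateral_side")

    base_e = config.region_map("baseline_early")
    base_l = config.region_map("baseline_late")
    rate_e = config.region_map("rate_early")
    rate_l = config.region_map("rate_late")
    noise = config.region_map("noise_sd")

    early_mask = stages == EARLY
    dur = clinical["duration"].to_numpy()  # rounded durations are the observed data
    cols = {}
    for hemi in HEMISPHERES:
        for region in config.regions:
            key = (hemi, region)
            mean = np.where(
                early_mask,
                base_e[key] + rate_e[key] * dur,
                base_l[key] + rate_l[key] * dur,
            )
            cols[key] = mean + rng.normal(0.0, noise[key], len(dur))
    thick = pd.DataFrame(cols, index=pd.Index(clinical["patient_id"], name="subject"))
    thick.columns = pd.MultiIndex.from_tuples(thick.columns, names=["hemisphere", "region"])

    mid_e = sum(config.duration_range_early) / 2
    mid_l = sum(config.duration_range_late) / 2
    diff = {
        k: (base_e[k] + rate_e[k] * mid_e) - (base_l[k] + rate_l[k] * mid_l)
        for k in rate_e
    }
    truth = TrueParameters(
        rate_early=rate_e,
        rate_late=rate_l,
        group_mean_difference=diff,
        null_region_flags={k: diff[k] == 0.0 and rate_e[k] == rate_l[k] for k in rate_e},
        lateral_side=pd.Series(lateral.to_numpy(), index=clinical["patient_id"].to_numpy()),
    )
    cohort = CohortTable.from_frame(clinical, cutoff=config.cutoff)
    return cohort, ThicknessMatrix.from_frame(thick), truth


def generate_null_cohort(
    config: SimulationConfig,
    n_null_regions: int,
    n_signal_regions: int,
    contrast: float = 0.1,
) -> tuple[CohortTable, ThicknessMatrix, TrueParameters]:
    """Null / signal mixture cohort for false-discovery calibration.

    The first ``n_null_regions`` regions (per hemisphere) are generated
    with identical distributions in both stages (zero rates, equal
    baselines); the next ``n_signal_regions`` get an Early-minus-Late
    mean contrast of ``contrast`` mm (Late thinner for positive values).
    Remaining configured regions, if any, are also null.
    """
    config.validate()
    if n_null_regions + n_signal_regions > len(config.regions):
        raise SimulationConfigError(
            f"regions: {n_null_regions} null + {n_signal_regions} signal regions "
            f"exceed the {len(config.regions)} configured per hemisphere"
        )
    signal = set(config.regions[n_null_regions : n_null_regions + n_signal_regions])
    base = _as_region_map(config.baseline_early, config.regions, name="baseline_early")
    base_late = {
        k: base[k] - (contrast if k[1] in signal else 0.0) for k in base
    }
    null_cfg = replace(
        config,
        rate_early=0.0,
        rate_late=0.0,
        baseline_early=base,
        baseline_late=base_late,
    )
    cohort, thick, truth = generate_cohort(null_cfg)
    truth.null_region_flags = {k: k[1] not in signal for k in truth.rate_early}
    return cohort, thick, truth
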