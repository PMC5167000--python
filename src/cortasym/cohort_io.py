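"""Clinical and thickness table I/O, stage assignment, motor laterality.

The clinical table is a CSV with one row per patient (demographics,
disease duration, UPDRS-III Off/On totals and per-extremity Off item
scores); the thickness table is a TSV in the FreeSurfer
``aparcstats2table`` dialect (first column subject id, then one
``<hemi>_<region>_thickness`` column per region per hemisphere, mm).

Patients with disease duration <= cutoff (10 years by default) are the
Early stage; the rest are Late.  The motor laterality index is
mean(right-extremity Off scores) - mean(left-extremity Off scores), so a
negative index marks predominantly left-sided symptoms; patients more
than ``threshold_sd`` cohort standard deviations from the cohort mean
index form the lateralized subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, parse_thickness_column, thickness_column

logger = logging.getLogger(__name__)

STAGE_CUTOFF_YEARS = 10.0
EARLY, LATE = "Early", "Late"
HANDEDNESS_CODES = ("R", "L", "NR")

#: Extremity UPDRS-III Off items per side: 4 items per limb x 2 limbs.
N_EXTREMITY_ITEMS = 8

THICKNESS_MIN_MM = 0.0
THICKNESS_MAX_MM = 6.0

_BASE_CLINICAL_COLUMNS = (
    "patient_id",
    "sex",
    "age_assessment",
    "age_onset",
    "duration",
    "handedness",
    "updrs3_off",
    "updrs3_on",
)


class CohortValidationError(ValueError):
    """A clinical or thickness table failed validation."""


def assign_stage(duration: float, cutoff: float = STAGE_CUTOFF_YEARS) -> str:
    """Stage label for a disease duration: Early iff duration <= cutoff.

    The boundary itself (duration == cutoff) is Early.
    """
    if not duration > 0:
        raise CohortValidationError(f"duration must be positive, got {duration}")
    return EARLY if duration <= cutoff else LATE


def _ext_columns(side: str, k: int) -> list[str]:
    return [f"{side}_ext_{i}" for i in range(1, k + 1)]


@dataclass
class CohortTable:
    """Validated per-patient clinical table with derived stage labels.

    ``df`` is indexed by ``patient_id`` and carries the clinical columns
    plus ``left_ext_1..k`` / ``right_ext_1..k`` item scores and the
    derived ``stage`` column.
    """

    df: pd.DataFrame
    cutoff: float = STAGE_CUTOFF_YEARS
    n_extremity_items: int = field(default=N_EXTREMITY_ITEMS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cutoff: float = STAGE_CUTOFF_YEARS) -> "CohortTable":
        df = df.copy()
        missing = [c for c in _BASE_CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing required column(s): {', '.join(missing)}")
        k = 0
        while f"left_ext_{k + 1}" in df.columns:
            k += 1
        right_k = 0
        while f"right_ext_{right_k + 1}" in df.columns:
            right_k += 1
        if k == 0 or right_k == 0:
            raise CohortValidationError("missing required column(s): left_ext_1/right_ext_1")
        if k != right_k:
            raise CohortValidationError(
                f"unequal extremity score lists: {k} left vs {right_k} right columns"
            )
        if df["patient_id"].duplicated().any():
            dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")
        durations = pd.to_numeric(df["duration"], errors="coerce")
        if durations.isna().any():
            bad = df.loc[durations.isna(), "patient_id"].tolist()
            raise CohortValidationError(f"non-numeric duration for patient(s): {bad}")
        if (durations <= 0).any():
            bad = df.loc[durations <= 0, "patient_id"].tolist()
            raise CohortValidationError(f"non-positive duration for patient(s): {bad}")
        df["duration"] = durations.astype(float)
        onset_known = df["age_onset"].notna() & df["age_assessment"].notna()
        bad_age = onset_known & (df["age_onset"] >= df["age_assessment"])
        if bad_age.any():
            raise CohortValidationError(
                f"age_onset >= age_assessment for patient(s): {df.loc[bad_age, 'patient_id'].tolist()}"
            )
        unknown = ~df["handedness"].isin(("R", "L"))
        n_mapped = int((unknown & (df["handedness"] != "NR")).sum())
        if n_mapped:
            logger.warning(
                "mapped %d handedness value(s) outside {R, L} to NR (not recorded)", n_mapped
            )
        df.loc[unknown, "handedness"] = "NR"
        df["stage"] = np.where(df["duration"] <= cutoff, EARLY, LATE)
        df = df.set_index("patient_id", drop=False)
        df.index.name = "patient_id"
        return cls(df=df, cutoff=cutoff, n_extremity_items=k)

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> pd.Index:
        return self.df.index

    @property
    def stage(self) -> pd.Series:
        return self.df["stage"]

    @property
    def duration(self) -> pd.Series:
        return self.df["duration"]

    def stage_mask(self, stage: str) -> np.ndarray:
        if stage not in (EARLY, LATE):
            raise ValueError(f"unknown stage {stage!r}; expected {EARLY!r} or {LATE!r}")
        return (self.df["stage"] == stage).to_numpy()

    def extremity_scores(self, side: str) -> np.ndarray:
        """(n_patients, k) array of per-item Off scores for one side."""
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        cols = _ext_columns(side, self.n_extremity_items)
        return self.df[cols].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, lineterminator="\n")


def read_clinical(path, cutoff: float = STAGE_CUTOFF_YEARS) -> CohortTable:
    """Read and validate the clinical CSV; derive the stage column."""
    df = pd.read_csv(path)
    return CohortTable.from_frame(df, cutoff=cutoff)


@dataclass
class ThicknessMatrix:
    """Subjects x (hemisphere, region) regional thickness matrix (mm).

    ``df`` has the subject id index (aligned to the cohort when both are
    loaded) and a two-level column index (hemisphere, region).
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThicknessMatrix":
        if not isinstance(df.columns, pd.MultiIndex):
            raise CohortValidationError("thickness frame must have (hemisphere, region) columns")
        values = df.to_numpy(dtype=float)
        bad = ~((values > THICKNESS_MIN_MM) & (values < THICKNESS_MAX_MM))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"implausible thickness {values[i, j]:.3f} mm for subject "
                f"{df.index[i]!r}, column {df.columns[j]}; expected "
                f"({THICKNESS_MIN_MM}, {THICKNESS_MAX_MM}) mm"
            )
        for hemi, other in (("left", "right"), ("right", "left")):
            if hemi not in df.columns.get_level_values(0):
                continue
            for region in df[hemi].columns:
                if (other, region) not in df.columns:
                    raise CohortValidationError(
                        f"region {region!r} present in {hemi} hemisphere only; "
                        "homologous column missing"
                    )
        return cls(df=df)

    @property
    def subjects(self) -> pd.Index:
        return self.df.index

    @property
    def regions(self) -> tuple[str, ...]:
        """Region names (identical per hemisphere by construction)."""
        return tuple(self.df["left"].columns)

    def values(self, region: str, hemisphere: str) -> np.ndarray:
        try:
            return self.df[(hemisphere, region)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"no thickness column for ({hemisphere!r}, {region!r})") from None

    def to_tsv(self, path) -> None:
        flat = self.df.copy()
        flat.columns = [thickness_column(h, r) for h, r in self.df.columns]
        flat.index.name = "subject"
        flat.to_csv(path, sep="\t", lineterminator="\n")


def read_thickness(path, clinical: CohortTable | None = None) -> ThicknessMatrix:
    """Read the thickness TSV; optionally check subject ids against the cohort.

    Subjects present in only one of the two tables are an error, reported
    explicitly — never silently dropped.
    """
    flat = pd.read_csv(path, sep="\t", index_col=0)
    pairs = [parse_thickness_column(c) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(pairs, names=["hemisphere", "region"])
    matrix = ThicknessMatrix.from_frame(flat)
    if clinical is not None:
        match_subjects(clinical, matrix)
    return matrix


def match_subjects(cohort: CohortTable, thickness: ThicknessMatrix) -> None:
    """Raise unless both tables cover exactly the same subjects."""
    clin = set(map(str, cohort.patient_ids))
    thick = set(map(str, thickness.subjects))
    only_clin = sorted(clin - thick)
    only_thick = sorted(thick - clin)
    if only_clin or only_thick:
        raise CohortValidationError(
            f"subject mismatch between tables: {only_clin} only in clinical, "
            f"{only_thick} only in thickness"
        )


# -- motor laterality ----------------------------------------------------

SIDE_LEFT = "left-predominant"
SIDE_RIGHT = "right-predominant"
SIDE_NONE = "none"


def motor_laterality(cohort: CohortTable, threshold_sd: float = 1.0) -> pd.DataFrame:
    """Per-patient motor laterality index, side, and subgroup selection.

    index = mean(right extremity Off scores) - mean(left extremity Off
    scores); negative indicates predominant left-sided symptoms.  A
    patient is selected into a lateralized subgroup when the index lies
    more than ``threshold_sd`` standard deviations from the mean index of
    the full cohort (all patients with score data).

    Returns a DataFrame indexed by patient_id with columns
    ``index``, ``side``, ``selected``.
    """
    left = cohort.extremity_scores("left")
    right = cohort.extremity_scores("right")
    if left.shape[1] == 0:
        raise CohortValidationError("empty extremity score lists")
    index = right.mean(axis=1) - left.mean(axis=1)
    sd = float(np.std(index, ddof=1)) if index.size > 1 else 0.0
    if sd == 0.0:
        # a perfectly symmetric cohort (all indices zero) trivially selects
        # nobody; any other zero-spread cohort makes SD selection undefined
        if not np.all(index == 0.0):
            raise CohortValidationError(
                "cohort SD of the laterality index is zero; SD-based selection is undefined"
            )
        selected = np.zeros(index.shape, dtype=bool)
    else:
        mean = float(np.mean(index))
        selected = np.abs(index - mean) > threshold_sd * sd
    side = np.where(selected, np.where(index < 0, SIDE_LEFT, SIDE_RIGHT), SIDE_NONE)
    return pd.DataFrame(
        {"index": index, "side": side, "selected": selected}, index=cohort.patient_ids
    )


def subgroup_mask(
    cohort: CohortTable, name: str, threshold_sd: float = 1.0
) -> np.ndarray:
    """Boolean patient mask for a named subgroup.

    Known names: ``left-handed``, ``right-handed``, ``motor-left``,
    ``motor-right`` (the latter two via the SD-based laterality selection).
    """
    if name == "left-handed":
        return (cohort.df["handedness"] == "L").to_numpy()
    if name == "right-handed":
        return (cohort.df["handedness"] == "R").to_numpy()
    if name in ("motor-left", "motor-right"):
        lat = motor_laterality(cohort, threshold_sd=threshold_sd)
        side = SIDE_LEFT if name == "motor-left" else SIDE_RIGHT
        return (lat["side"] == side).to_numpy()
    raise ValueError(
        f"unknown subgroup {name!r}; expected one of "
        "'left-handed', 'right-handed', 'motor-left', 'motor-right'"
    )
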