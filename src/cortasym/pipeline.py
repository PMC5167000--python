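"""End-to-end orchestration: stage -> compare -> rates -> differences -> laterality.

``run_pipeline`` drives the full analysis over a clinical CSV and a
thickness TSV and returns a :class:`ResultBundle` of tidy frames shaped
like the study's publication tables: a cohort summary, per-region group
comparisons with per-hemisphere FDR, per-stage atrophy rates, the
bootstrapped Early-minus-Late slope contrasts with their asymmetry
classification, and the handedness / motor-laterality sub-analyses.
Every analysis constant left open by convention (bootstrap size, CI
method, t-test variant, FDR procedure) is logged at INFO so a run is
auditable, and every result row carries the hash of the configuration
that produced it.  A fixed master seed makes the whole run
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    EARLY,
    LATE,
    CohortTable,
    ThicknessMatrix,
    motor_laterality,
    read_clinical,
    read_thickness,
    subgroup_mask,
)
from .comparison import compare_regions
from .laterality import (
    asymmetry_contrast,
    duration_correlation,
    paired_hemisphere_test,
)
from .rates import SlopeDifference, estimate_rates, slope_differences

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Analysis constants plus input/output locations for one run."""

    clinical_path: str | None = None
    thickness_path: str | None = None
    out_dir: str | None = None
    cutoff: float = 10.0
    q: float = 0.1
    alpha: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    threshold_sd: float = 1.0
    equal_var: bool = False
    subgroups: tuple[str, ...] = (
        "left-handed",
        "right-handed",
        "motor-left",
        "motor-right",
    )
    laterality_regions: tuple[str, ...] = ("G_insular_short", "S_orbital_med-olfact")

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_boot < 200:
            raise ValueError(f"n_boot must be >= 200, got {self.n_boot}")
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("subgroups", "laterality_regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable hash of the analysis constants (paths excluded)."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("clinical_path", "thickness_path", "out_dir")
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All pipeline outputs plus run metadata."""

    cohort_summary: pd.DataFrame
    comparisons: pd.DataFrame
    rates: pd.DataFrame
    slope_diffs: pd.DataFrame
    asymmetry: pd.DataFrame
    correlations: pd.DataFrame
    paired: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _mean_sd_range(values: pd.Series) -> tuple[str, str]:
    v = values.to_numpy(dtype=float)
    return f"{v.mean():.1f} ({v.std(ddof=1):.1f})", f"{v.min():.1f}–{v.max():.1f}"


def cohort_summary(cohort: CohortTable, threshold_sd: float = 1.0) -> pd.DataFrame:
    """Demographic/clinical summary table: Total, Early and Late columns."""
    df = cohort.df
    groups = {
        "Total": df,
        EARLY: df[df["stage"] == EARLY],
        LATE: df[df["stage"] == LATE],
    }
    rows: dict[str, dict[str, str]] = {}
    for name, g in groups.items():
        col: dict[str, str] = {"n": str(len(g))}
        col["Gender (M:F)"] = f"{(g['sex'] == 'M').sum()}:{(g['sex'] == 'F').sum()}"
        for label, series in (
            ("Age-assessment (years)", g["age_assessment"]),
            ("Age-Motor Onset (years)", g["age_onset"]),
            ("Disease Duration (years)", g["duration"]),
            ("UPDRS III- Off", g["updrs3_off"]),
            ("UPDRS III- On", g["updrs3_on"]),
            ("UPDRS Difference", g["updrs3_off"] - g["updrs3_on"]),
        ):
            mean_sd, rng = _mean_sd_range(series)
            col[label] = mean_sd
            col[f"{label} Range"] = rng
        h = g["handedness"].value_counts()
        col["Handedness (R:L:NR)"] = f"{h.get('R', 0)}:{h.get('L', 0)}:{h.get('NR', 0)}"
        rows[name] = col
    return pd.DataFrame(rows).rename_axis("statistic")


def _stage_tag(stage_name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("pipeline stage: %s", stage_name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{stage_name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    cohort: CohortTable | None = None,
    thickness: ThicknessMatrix | None = None,
) -> ResultBundle:
    """Run the full analysis; deterministic under a fixed master seed.

    ``cohort``/``thickness`` may be passed in-memory; otherwise they are
    read from the configured paths.
    """
    config.validate()
    logger.info(
        "analysis defaults: n_boot=%d (percentile bootstrap CI), alpha=%g, "
        "t-test=%s, FDR=Benjamini-Hochberg step-up per hemisphere at q=%g, "
        "cutoff=%g years, laterality threshold=%g SD",
        config.n_boot, config.alpha,
        "pooled" if config.equal_var else "Welch",
        config.q, config.cutoff, config.threshold_sd,
    )
    with _stage_tag("read"):
        if cohort is None:
            if config.clinical_path is None:
                raise ValueError("no clinical table: set clinical_path or pass cohort")
            cohort = read_clinical(config.clinical_path, cutoff=config.cutoff)
        if thickness is None:
            if config.thickness_path is None:
                raise ValueError("no thickness table: set thickness_path or pass thickness")
            thickness = read_thickness(config.thickness_path, clinical=cohort)

    with _stage_tag("summary"):
        summary = cohort_summary(cohort, threshold_sd=config.threshold_sd)

    with _stage_tag("compare"):
        comparisons = compare_regions(
            cohort, thickness, q=config.q, equal_var=config.equal_var
        )

    with _stage_tag("rates"):
        rates = pd.concat(
            [
                estimate_rates(
                    cohort, thickness, stage,
                    n_boot=config.n_boot, alpha=config.alpha, seed=config.seed,
                )
                for stage in (EARLY, LATE)
            ],
            ignore_index=True,
        )

    with _stage_tag("differences"):
        diffs = slope_differences(
            cohort, thickness, n_boot=config.n_boot, alpha=config.alpha, seed=config.seed
        )
        asym_rows = []
        for region in thickness.regions:
            pair = {
                row["hemisphere"]: SlopeDifference(**row)
                for _, row in diffs[diffs["region"] == region].iterrows()
            }
            _, _, label = asymmetry_contrast(pair["left"], pair["right"])
            asym_rows.append({"region": region, "lateralized": label})
        asymmetry = pd.DataFrame(asym_rows)

    with _stage_tag("laterality"):
        correlations = _subgroup_correlations(cohort, thickness, config)
        paired = _paired_tests(cohort, thickness, config)

    config_hash = config.config_hash()
    bundle = ResultBundle(
        cohort_summary=summary,
        comparisons=comparisons,
        rates=rates,
        slope_diffs=diffs,
        asymmetry=asymmetry,
        correlations=correlations,
        paired=paired,
        metadata={
            "config": asdict(config),
            "config_hash": config_hash,
            "n_patients": cohort.n,
            "n_regions": len(thickness.regions),
            "versions": {
                "cortasym": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        },
    )
    for frame in (bundle.comparisons, bundle.rates, bundle.slope_diffs,
                  bundle.asymmetry, bundle.correlations, bundle.paired):
        frame["config_hash"] = config_hash
    return bundle


def _present_regions(thickness: ThicknessMatrix, config: PipelineConfig) -> list[str]:
    present = [r for r in config.laterality_regions if r in thickness.regions]
    missing = sorted(set(config.laterality_regions) - set(present))
    if missing:
        logger.info("laterality region(s) absent from the thickness table, skipped: %s", missing)
    return present


def _early_subgroup(name: str, cohort: CohortTable, threshold_sd: float) -> np.ndarray:
    return subgroup_mask(cohort, name, threshold_sd=threshold_sd) & cohort.stage_mask(EARLY)


def _subgroup_correlations(
    cohort: CohortTable, thickness: ThicknessMatrix, config: PipelineConfig
) -> pd.DataFrame:
    """Duration-thickness correlations per subgroup x region x hemisphere.

    Correlations are computed within Early-stage members of each
    subgroup (the asymmetry question is about the first disease decade);
    subgroups too small for a correlation are skipped with a log entry.
    """
    rows = []
    for name in config.subgroups:
        mask = _early_subgroup(name, cohort, config.threshold_sd)
        for region in _present_regions(thickness, config):
            for hemi in ("left", "right"):
                try:
                    res = duration_correlation(cohort, thickness, region, hemi, subgroup=mask)
                except ValueError as err:
                    logger.info("correlation skipped (%s, %s, %s): %s", name, region, hemi, err)
                    continue
                row = vars(res).copy()
                row["subgroup"] = f"{name}+Early"
                rows.append(row)
    cols = ["region", "hemisphere", "subgroup", "n", "r", "p_value"]
    return pd.DataFrame(rows, columns=cols)


def _paired_tests(
    cohort: CohortTable, thickness: ThicknessMatrix, config: PipelineConfig
) -> pd.DataFrame:
    """Within-patient left-vs-right tests in the motor-lateralized subsets."""
    rows = []
    for name in ("motor-left", "motor-right"):
        if name not in config.subgroups:
            continue
        try:
            mask = subgroup_mask(cohort, name, threshold_sd=config.threshold_sd)
        except ValueError as err:
            logger.info("paired test skipped (%s): %s", name, err)
            continue
        for region in _present_regions(thickness, config):
            try:
                res = paired_hemisphere_test(cohort, thickness, region, subgroup=mask)
            except ValueError as err:
                logger.info("paired test skipped (%s, %s): %s", name, region, err)
                continue
            row = vars(res).copy()
            row["subgroup"] = name
            row["left_summary"] = res.side_summary("left")
            row["right_summary"] = res.side_summary("right")
            rows.append(row)
    cols = ["region", "subgroup", "n", "left_mean", "left_sd", "right_mean",
            "right_sd", "left_summary", "right_summary", "difference", "p_value"]
    return pd.DataFrame(rows, columns=cols)


_BUNDLE_FILES = {
    "cohort_summary": "cohort_summary.csv",
    "comparisons": "comparisons.csv",
    "rates": "rates.csv",
    "slope_diffs": "slope_differences.csv",
    "asymmetry": "asymmetry.csv",
    "correlations": "correlations.csv",
    "paired": "paired_hemisphere.csv",
}


def write_bundle(bundle: ResultBundle, out_dir) -> Path:
    """Write all bundle frames as CSV plus a metadata JSON; return the dir.

    ``metadata.json`` is written first with ``complete: false`` and
    rewritten last, so an interrupted run is detectably incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "metadata.json"
    meta = dict(bundle.metadata, complete=False)
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    for attr, fname in _BUNDLE_FILES.items():
        frame: pd.DataFrame = getattr(bundle, attr)
        frame.to_csv(out / fname, index=(attr == "cohort_summary"), lineterminator="\n")
    meta["complete"] = True
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return out


#: metric name -> (bundle frame attribute, value column, row filter)
_EXPORT_METRICS = {
    "rate_early": ("rates", "slope", ("stage", EARLY)),
    "rate_late": ("rates", "slope", ("stage", LATE)),
    "slope_difference": ("slope_diffs", "difference", None),
    "difference": ("comparisons", "difference", None),
    "p_value": ("comparisons", "p_value", None),
    "q_value": ("comparisons", "q_value", None),
}


def export_region_values(bundle: ResultBundle, metric: str) -> pd.DataFrame:
    """Per-region CSV-ready export of one metric, keyed by region + hemisphere.

    One row per region x hemisphere, suitable for joining to any
    parcellation lookup (a stand-in for surface rendering).
    """
    if metric not in _EXPORT_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid metrics: {', '.join(sorted(_EXPORT_METRICS))}"
        )
    attr, column, flt = _EXPORT_METRICS[metric]
    frame: pd.DataFrame = getattr(bundle, attr)
    if flt is not None:
        frame = frame[frame[flt[0]] == flt[1]]
    out = frame[["region", "hemisphere", column]].rename(columns={column: metric})
    return out.reset_index(drop=True)
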