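"""End-to-end orchestration: (phantom cohort | ROI manifest) -> filtering ->
entropy + GLCM feature table -> grade statistics -> threshold detection.

The feature table is long (tidy): one row per
(horse, tooth, grade, filter, measure). With all three filters and both
texture families enabled each ROI contributes 15 entropy rows and 18 GLCM
rows. Undefined entropies are serialized as the literal token "NA" with the
reason kept in a ``note`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .detection import ThresholdRule, detection_table
from .entropy2d import (
    MEASURE_NAMES,
    EntropyParams,
    disp_en_2d,
    dist_en_2d,
    fuzz_en_2d,
    perm_en_2d,
    samp_en_2d,
)

_ENTROPY_FUNCS = {
    "SampEn2D": samp_en_2d,
    "FuzzEn2D": fuzz_en_2d,
    "PermEn2D": perm_en_2d,
    "DispEn2D": disp_en_2d,
    "DistEn2D": dist_en_2d,
}
from .exceptions import ValidationError
from .filters import DEFAULT_FILTERS, FilterSpec, apply_filter
from .glcm import GLCM_FEATURE_NAMES, GLCMParams, glcm_suite
from .gradestats import GroupComparison, RegressionComparison, StatsConfig, compare_groups, compare_slopes
from .imageio_roi import GradedROI, extract_roi, load_radiograph, read_manifest
from .phantom import DEFAULT_GROUP_SIZES, PhantomDataset, generate_cohort

logger = logging.getLogger("eotrh_texture")

FEATURE_COLUMNS = ("horse_id", "tooth", "grade", "filter", "measure", "value", "note")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; serializable to/from YAML."""

    mode: str = "phantom"  # or "manifest"
    manifest_path: str | None = None
    group_sizes: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    filters: tuple[FilterSpec, ...] = DEFAULT_FILTERS
    entropy: EntropyParams = field(default_factory=EntropyParams)
    glcm: GLCMParams = field(default_factory=GLCMParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    entropy_enabled: bool = True
    entropy_measures: tuple[str, ...] = MEASURE_NAMES  # subset to compute
    glcm_enabled: bool = True
    detect_measures: tuple[str, ...] = ("DistEn2D",)
    detect_filter: str = "normalize"
    regression_entropy: str = "DistEn2D"
    regression_filter: str = "normalize"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = tuple(FilterSpec.from_dict(f) for f in d["filters"])
        if "entropy" in d:
            d["entropy"] = EntropyParams(**d["entropy"])
        if "glcm" in d:
            glcm = dict(d["glcm"])
            if "directions" in glcm:
                glcm["directions"] = tuple(glcm["directions"])
            d["glcm"] = GLCMParams(**glcm)
        if "stats" in d:
            d["stats"] = StatsConfig(**d["stats"])
        if "threshold" in d:
            d["threshold"] = ThresholdRule(**d["threshold"])
        if "group_sizes" in d:
            d["group_sizes"] = {int(k): int(v) for k, v in d["group_sizes"].items()}
        for key in ("detect_measures", "entropy_measures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def load_rois(cfg: RunConfig) -> list[GradedROI]:
    """Resolve the configured input into graded ROI matrices."""
    if cfg.mode == "phantom":
        return generate_cohort(cfg.group_sizes, base_seed=cfg.seed).rois
    if cfg.mode != "manifest":
        raise ValidationError(f"unknown input mode {cfg.mode!r}")
    if not cfg.manifest_path:
        raise ValidationError("manifest mode requires manifest_path")
    records = read_manifest(cfg.manifest_path)
    base = Path(cfg.manifest_path).parent
    rois = []
    for rec in records:
        img = load_radiograph(base / rec.image_path)
        rois.append(
            GradedROI(
                horse_id=rec.horse_id,
                tooth=rec.tooth,
                grade=rec.grade,
                pixels=extract_roi(img, rec.rect),
            )
        )
    return rois


def run_extract(cfg: RunConfig, rois: list[GradedROI] | None = None) -> pd.DataFrame:
    """Compute the long feature table for every ROI and filter.

    Per-ROI failures are logged and skipped; the failure count is attached
    as ``df.attrs['failures']``.
    """
    if rois is None:
        rois = load_rois(cfg)
    if not rois:
        logger.warning("no ROIs to extract; returning empty feature table")
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
        df.attrs["failures"] = 0
        return df

    rows: list[dict[str, Any]] = []
    failures = 0
    for roi in rois:
        try:
            for spec in cfg.filters:
                filtered = apply_filter(np.asarray(roi.pixels, dtype=np.float64), spec)
                if cfg.entropy_enabled:
                    results = [
                        _ENTROPY_FUNCS[name](filtered, cfg.entropy)
                        for name in cfg.entropy_measures
                    ]
                    for res in results:
                        rows.append(
                            {
                                "horse_id": roi.horse_id,
                                "tooth": roi.tooth,
                                "grade": roi.grade,
                                "filter": spec.name,
                                "measure": res.measure,
                                "value": res.value if res.defined else None,
                                "note": res.note,
                            }
                        )
                if cfg.glcm_enabled:
                    for name, value in glcm_suite(filtered, cfg.glcm).as_dict().items():
                        rows.append(
                            {
                                "horse_id": roi.horse_id,
                                "tooth": roi.tooth,
                                "grade": roi.grade,
                                "filter": spec.name,
                                "measure": name,
                                "value": value,
                                "note": "",
                            }
                        )
        except Exception:  # keep going; a bad ROI must not kill the cohort
            failures += 1
            logger.exception("feature extraction failed for %s/%s", roi.horse_id, roi.tooth)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.attrs["failures"] = failures
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV serialization; undefined values become 'NA'."""
    out = df.copy()
    out["value"] = out["value"].map(lambda v: "NA" if pd.isna(v) else f"{v:.12g}")
    out.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=["NA"])
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def run_stats(
    table: pd.DataFrame, cfg: RunConfig
) -> tuple[list[GroupComparison], list[RegressionComparison]]:
    """One group comparison per (filter, measure); regression similarity of
    the configured entropy measure against each GLCM feature under the
    configured filter."""
    comparisons: list[GroupComparison] = []
    for (flt, measure), sub in table.groupby(["filter", "measure"], sort=False):
        sub = sub.dropna(subset=["value"])
        grades = sorted(sub["grade"].unique())
        if len(grades) < 2:
            logger.warning("skipping %s/%s: fewer than 2 grades", flt, measure)
            continue
        groups = {int(g): sub.loc[sub["grade"] == g, "value"].to_numpy() for g in grades}
        if any(len(v) < 3 for v in groups.values()):
            logger.warning("skipping %s/%s: a grade group has n < 3", flt, measure)
            continue
        comp = compare_groups(groups, cfg.stats, measure=f"{flt}/{measure}")
        comparisons.append(comp)

    regressions: list[RegressionComparison] = []
    flt = cfg.regression_filter
    ent = cfg.regression_entropy
    sub_e = table.query("filter == @flt and measure == @ent").dropna(subset=["value"])
    if len(sub_e) >= 2 and sub_e["grade"].nunique() >= 2:
        series_e = list(zip(sub_e["grade"].astype(float), sub_e["value"].astype(float)))
        for feat in GLCM_FEATURE_NAMES:
            sub_g = table.query("filter == @flt and measure == @feat").dropna(subset=["value"])
            if len(sub_g) < 2 or sub_g["grade"].nunique() < 2:
                continue
            series_g = list(zip(sub_g["grade"].astype(float), sub_g["value"].astype(float)))
            regressions.append(
                compare_slopes(series_e, series_g, cfg.stats, label_a=ent, label_b=feat)
            )
    return comparisons, regressions


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        grades = sorted(c.group_n)
        row: dict[str, Any] = {
            "measure": c.measure,
            "branch": c.branch,
            "omnibus_p": c.omnibus_p,
            "monotone_increase": c.monotone_increase_flag,
        }
        for g in grades:
            row[f"n_{g}"] = c.group_n[g]
            row[f"mean_{g}"] = c.group_mean[g]
            row[f"sd_{g}"] = c.group_sd[g]
            row[f"letters_{g}"] = c.letters.get(g, "")
        rows.append(row)
    return pd.DataFrame(rows)


def regressions_frame(regressions: list[RegressionComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entropy": r.label_a,
                "glcm_feature": r.label_b,
                "slope_entropy": r.slope_a,
                "slope_glcm": r.slope_b,
                "slope_equality_p": r.slope_equality_p,
                "common_slope": r.common_slope,
                "intercept_equality_p": r.intercept_equality_p,
                "common_intercept": r.common_intercept,
            }
            for r in regressions
        ]
    )


def run_detect(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Three-threshold accuracy table (EOTRH 0 vs 3) for each configured
    measure under the configured filter."""
    sub = table[table["filter"] == cfg.detect_filter]
    present = set(sub["grade"].unique())
    if not {0, 3} <= present:
        raise ValidationError(f"detection needs grades 0 and 3; found {sorted(present)}")
    values = {}
    for measure in cfg.detect_measures:
        ms = sub[sub["measure"] == measure].dropna(subset=["value"])
        pos = ms.loc[ms["grade"] == 3, "value"].to_numpy()
        neg = ms.loc[ms["grade"] == 0, "value"].to_numpy()
        if pos.size == 0 or neg.size == 0:
            raise ValidationError(f"measure {measure}: missing grade 0 or 3 values")
        values[measure] = (pos, neg)
    return detection_table(values, cfg.threshold)
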