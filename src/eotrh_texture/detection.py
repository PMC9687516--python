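"""Threshold-based detection of severe disease (EOTRH 3 vs EOTRH 0) and
diagnostic accuracy metrics.

Three threshold rules are supported for grade-increasing measures: the mean,
mean + SD and mean + 2SD of a reference population (sample SD). With the
default direction a value strictly above the threshold calls the positive
class (EOTRH 3); ties go to the negative class. Sensitivity, specificity and
predictive values are reported rounded half-up to two decimals, with
undefined ratios (empty denominators) rendered as "-".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

THRESHOLD_KINDS = ("mean", "mean_plus_sd", "mean_plus_2sd")


@dataclass(frozen=True)
class ThresholdRule:
    kind: str = "mean"
    reference_population: str = "pooled_0_and_3"  # | grade0_only | all_grades
    direction: str = "positive_above"  # | positive_below

    def __post_init__(self) -> None:
        if self.kind not in THRESHOLD_KINDS:
            raise ParameterError(f"kind must be one of {THRESHOLD_KINDS}")
        if self.reference_population not in ("pooled_0_and_3", "grade0_only", "all_grades"):
            raise ParameterError("unknown reference population")
        if self.direction not in ("positive_above", "positive_below"):
            raise ParameterError("unknown direction")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion matrix entries must be non-negative")


@dataclass
class DetectionReport:
    rule: ThresholdRule
    threshold_value: float
    cm: ConfusionMatrix
    Se: float | None
    Sp: float | None
    PPV: float | None
    NPV: float | None

    def rounded(self) -> dict[str, str]:
        """Metrics rounded half-up to 2 decimals; undefined rendered '-'."""
        return {k: round_half_up(v) for k, v in
                (("Se", self.Se), ("Sp", self.Sp), ("PPV", self.PPV), ("NPV", self.NPV))}


def round_half_up(v: float | None, places: int = 2) -> str:
    if v is None:
        return "-"
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))


def compute_threshold(values: np.ndarray, rule: ThresholdRule) -> float:
    """mean, mean + SD, or mean + 2*SD of the reference values (sample SD)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValidationError("empty reference population for threshold")
    mu = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {"mean": mu, "mean_plus_sd": mu + sd, "mean_plus_2sd": mu + 2 * sd}[rule.kind]


def classify(
    values_pos: np.ndarray, values_neg: np.ndarray, rule: ThresholdRule
) -> tuple[ConfusionMatrix, float]:
    """Tally the confusion matrix of the threshold rule.

    ``values_pos`` are the true severe (EOTRH 3) measures, ``values_neg`` the
    true normal (EOTRH 0) ones. Returns (matrix, threshold used).
    """
    values_pos = np.asarray(values_pos, dtype=np.float64)
    values_neg = np.asarray(values_neg, dtype=np.float64)
    if values_pos.size == 0 or values_neg.size == 0:
        raise ValidationError("both class value lists must be non-empty")
    ref = {
        "pooled_0_and_3": np.concatenate([values_neg, values_pos]),
        "grade0_only": values_neg,
        "all_grades": np.concatenate([values_neg, values_pos]),
    }[rule.reference_population]
    thr = compute_threshold(ref, rule)
    if rule.direction == "positive_above":
        called_pos = lambda v: v > thr  # strict: ties -> negative
    else:
        called_pos = lambda v: v < thr
    tp = int(called_pos(values_pos).sum())
    fp = int(called_pos(values_neg).sum())
    cm = ConfusionMatrix(TP=tp, FP=fp, FN=values_pos.size - tp, TN=values_neg.size - fp)
    return cm, thr


def accuracy_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Se, Sp, PPV, NPV at full precision; None where the denominator is 0."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return {
        "Se": ratio(cm.TP, cm.TP + cm.FN),
        "Sp": ratio(cm.TN, cm.TN + cm.FP),
        "PPV": ratio(cm.TP, cm.TP + cm.FP),
        "NPV": ratio(cm.TN, cm.TN + cm.FN),
    }


def detection_report(
    values_pos: np.ndarray, values_neg: np.ndarray, rule: ThresholdRule
) -> DetectionReport:
    cm, thr = classify(values_pos, values_neg, rule)
    m = accuracy_metrics(cm)
    return DetectionReport(rule=rule, threshold_value=thr, cm=cm, **m)


def detection_table(
    values_by_measure: dict[str, tuple[np.ndarray, np.ndarray]],
    base_rule: ThresholdRule = ThresholdRule(),
) -> pd.DataFrame:
    """Accuracy table across measures and the three threshold rules, shaped
    like the reporting convention: rows (threshold kind, metric), one column
    per measure, values rounded to 2 decimals ('-' when undefined)."""
    rows = []
    for kind in THRESHOLD_KINDS:
        rule = ThresholdRule(
            kind=kind,
            reference_population=base_rule.reference_population,
            direction=base_rule.direction,
        )
        reports = {
            name: detection_report(pos, neg, rule)
            for name, (pos, neg) in values_by_measure.items()
        }
        for metric in ("Se", "Sp", "PPV", "NPV"):
            row: dict[str, object] = {"threshold": kind, "metric": metric}
            for name, rep in reports.items():
                row[name] = rep.rounded()[metric]
            rows.append(row)
    return pd.DataFrame(rows)
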