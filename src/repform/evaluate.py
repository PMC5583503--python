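"""Classification scoring with acceptable-as-positive semantics.

The convention follows the biofeedback use case: "Acceptable" is the
positive class, so sensitivity is the rate at which acceptable technique
is recognized and specificity the rate at which aberrant technique is
caught.  Percentages mirror the two-decimal presentation customary in
this literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "per_group_report"]

POSITIVE_LABEL = "Acceptable"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with acceptable technique as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricReport:
    """Accuracy / sensitivity / specificity in percent.

    A metric whose denominator is empty is ``None`` (undefined), never
    coerced to zero.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion(truth, predicted, positive_label: str = POSITIVE_LABEL) -> ConfusionCounts:
    """Count TP/FN/TN/FP over aligned truth and predicted label sequences.

    TP: both positive ("Acceptable"); FN: truth positive, predicted
    negative; TN: both negative; FP: truth negative, predicted positive.
    Requires exactly two distinct labels overall, with the positive label
    named explicitly.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    observed = set(truth) | set(predicted)
    if len(observed - {positive_label}) > 1:
        raise ValueError(
            f"binary scoring needs exactly two labels; got {sorted(observed)}"
        )
    tp = fn = tn = fp = 0
    for t, p in zip(truth, predicted):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(c: ConfusionCounts) -> MetricReport:
    """accuracy = 100 (TP+TN)/total; sensitivity = 100 TP/(TP+FN);
    specificity = 100 TN/(TN+FP)."""
    if c.total == 0:
        raise ValueError("metrics undefined for zero scored repetitions")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    sensitivity = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return MetricReport(accuracy=accuracy, sensitivity=sensitivity, specificity=specificity)


def per_group_report(
    df: pd.DataFrame,
    grouping: str = "participant",
    unit: str = "participant",
    truth_col: str = "truth",
    predicted_col: str = "predicted",
    positive_label: str = POSITIVE_LABEL,
) -> pd.DataFrame:
    """Mean and SD of the three metrics per group.

    ``df`` holds one row per scored repetition with a grouping column
    (e.g. participant, exercise, experience), a unit column identifying
    the individual over which means are taken (a participant), and truth
    and predicted labels.  Within each group the metrics are computed per
    unit and summarized as mean and population SD across units; a pooled
    "All" row over every unit is appended.  Empty groups are omitted
    with a warning; a metric undefined for some unit is skipped in that
    unit's contribution.
    """
    for col in (grouping, unit, truth_col, predicted_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    group_values = list(dict.fromkeys(df[grouping]))
    for group in group_values + ["All"]:
        sub = df if group == "All" else df[df[grouping] == group]
        if len(sub) == 0:
            logger.warning("group %r has no repetitions; omitted", group)
            continue
        per_unit = {"accuracy": [], "sensitivity": [], "specificity": []}
        n_units = 0
        for _, unit_df in sub.groupby(unit, sort=False):
            report = metrics(
                confusion(unit_df[truth_col], unit_df[predicted_col], positive_label)
            )
            n_units += 1
            for name, value in report.as_dict().items():
                if value is not None:
                    per_unit[name].append(value)
        row = {grouping: group, "n_units": n_units}
        for name, values in per_unit.items():
            row[f"{name}_mean"] = float(np.mean(values)) if values else np.nan
            row[f"{name}_sd"] = float(np.std(values)) if values else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
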