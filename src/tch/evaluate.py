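"""Accuracy assessment of a calibrated model on withheld testing points.

Reports overall accuracy, Cohen's kappa and per-class sensitivity, but
only when every crown class has at least five testing points — below
that the estimates are too unstable and the report is marked ineligible
with its metrics withheld.  Each report also tallies the dominant
confusion pattern (the lowest-sensitivity class and where its points
went), the standard error taxonomy for this model family
(shadow→gray, gray↔red, green→shadow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .color_model import ModelConstants, classify_array
from .metrics import (CLASS_LABELS, cohens_kappa, confusion_matrix,
                      overall_accuracy, per_class_tpr)

__all__ = ["EvaluationReport", "evaluate_model", "summarize_reports"]

MIN_TEST_POINTS = 5


@dataclass
class EvaluationReport:
    """Evaluation metrics for one stratum (or the global model)."""

    eligible: bool
    confusion: pd.DataFrame
    accuracy: float | None = None
    kappa: float | None = None
    tpr: dict | None = None
    lowest_tpr_class: str | None = None
    dominant_confusion: str | None = None
    n_test: int = 0
    class_counts: dict = field(default_factory=dict)
    constants: ModelConstants | None = None
    stratum: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "n_test": self.n_test,
            "class_counts": self.class_counts,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "tpr": self.tpr,
            "lowest_tpr_class": self.lowest_tpr_class,
            "dominant_confusion": self.dominant_confusion,
            "constants": self.constants.to_dict() if self.constants else None,
            "stratum": self.stratum,
            "confusion": {t: {p: int(self.confusion.loc[t, p])
                              for p in self.confusion.columns}
                          for t in self.confusion.index},
        }

    def write(self, path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _confusion_pattern(cm: pd.DataFrame, tpr: dict):
    """Lowest-TPR class and the prediction that absorbed most of its errors."""
    lowest = min(tpr, key=lambda k: (tpr[k], k))
    row = cm.loc[lowest].drop(labels=[lowest])
    if int(row.sum()) == 0:
        return lowest, None
    return lowest, str(row.idxmax())


def evaluate_model(test_points: pd.DataFrame,
                   constants: ModelConstants,
                   t: float | None = None,
                   bits: int = 8,
                   min_points_per_class: int = MIN_TEST_POINTS,
                   include_unclassified_in_kappa: bool = True,
                   stratum: dict | None = None) -> EvaluationReport:
    """Classify withheld points and report agreement with their labels.

    ``t`` overrides the threshold stored in ``constants`` when given.
    Unclassified predictions always count as errors in overall accuracy;
    ``include_unclassified_in_kappa=False`` drops them from the kappa
    marginals instead of carrying them as a fifth category.
    """
    if len(test_points) == 0:
        raise ValueError("empty test set")
    if t is not None:
        constants = constants.replace(t=t)

    rgb = test_points[["r", "g", "b"]].to_numpy().astype(np.uint32)
    pred = classify_array(rgb, constants, bits=bits)
    truth = test_points["class"].astype(str).str.strip().str.lower().to_numpy()
    cm = confusion_matrix(truth, pred)

    counts = {label: int(cm.loc[label].sum()) for label in CLASS_LABELS}
    eligible = all(c >= min_points_per_class for c in counts.values())
    report = EvaluationReport(
        eligible=eligible, confusion=cm, n_test=len(test_points),
        class_counts=counts, constants=constants, stratum=dict(stratum or {}))
    if not eligible:
        return report

    kcm = cm if include_unclassified_in_kappa else cm[list(CLASS_LABELS)]
    report.accuracy = overall_accuracy(cm)
    report.kappa = cohens_kappa(kcm)
    report.tpr = per_class_tpr(cm)
    report.lowest_tpr_class, report.dominant_confusion = \
        _confusion_pattern(cm, report.tpr)
    return report


def summarize_reports(reports) -> dict:
    """Median and 5th-percentile accuracy/kappa across eligible reports."""
    acc = [r.accuracy for r in reports if r.eligible]
    kap = [r.kappa for r in reports if r.eligible]
    if not acc:
        raise ValueError("no eligible reports to summarize")
    return {
        "n_models": len(acc),
        "median_accuracy": float(np.median(acc)),
        "median_kappa": float(np.median(kap)),
        "p05_accuracy": float(np.percentile(acc, 5)),
        "p05_kappa": float(np.percentile(kap, 5)),
        "min_accuracy": float(np.min(acc)),
        "min_kappa": float(np.min(kap)),
    }
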