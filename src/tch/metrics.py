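"""Confusion matrices and agreement statistics for crown classifications.

Truth labels are always one of the four crown classes; predictions may
additionally be UNCLASSIFIED (maximum score at or below the threshold),
which is tallied in a fifth prediction column and counts against both
sensitivity and overall accuracy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .color_model import CrownClass

__all__ = ["confusion_matrix", "per_class_tpr", "overall_accuracy", "cohens_kappa"]

CLASS_ORDER = (CrownClass.GREEN, CrownClass.RED, CrownClass.GRAY, CrownClass.SHADOW)
CLASS_LABELS = tuple(c.label for c in CLASS_ORDER)
PRED_LABELS = CLASS_LABELS + ("unclassified",)


def _to_labels(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, CrownClass):
            out.append(v.label)
        elif isinstance(v, (int, np.integer)):
            out.append(CrownClass(int(v)).label)
        else:
            out.append(str(v).strip().lower())
    return np.asarray(out, dtype=object)


def confusion_matrix(truth, predicted) -> pd.DataFrame:
    """Count (truth, prediction) pairs.

    Rows are the four crown classes (truth); columns are the four classes
    plus ``unclassified`` (prediction).  Labels may be given as
    :class:`CrownClass`, integer codes, or strings.
    """
    truth = _to_labels(truth)
    predicted = _to_labels(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {truth.shape[0]} truths vs {predicted.shape[0]} predictions")
    bad = set(truth) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"truth labels must be crown classes, got {sorted(bad)}")
    bad = set(predicted) - set(PRED_LABELS)
    if bad:
        raise ValueError(f"unknown prediction labels {sorted(bad)}")
    cm = pd.DataFrame(0, index=list(CLASS_LABELS), columns=list(PRED_LABELS),
                      dtype=np.int64)
    for t, p in zip(truth, predicted):
        cm.loc[t, p] += 1
    cm.index.name = "truth"
    cm.columns.name = "predicted"
    return cm


def _as_frame(cm) -> pd.DataFrame:
    if isinstance(cm, pd.DataFrame):
        return cm
    arr = np.asarray(cm)
    if arr.ndim != 2:
        raise ValueError("confusion matrix must be 2-D")
    return pd.DataFrame(arr)


def per_class_tpr(cm) -> dict:
    """Per-class sensitivity: diagonal over row sum.

    Classes with no truth points are reported as ``nan`` with a warning
    (their sensitivity is undefined).
    """
    cm = _as_frame(cm)
    out = {}
    for label in cm.index:
        row = cm.loc[label]
        total = int(row.sum())
        if total == 0:
            warnings.warn(f"class {label!r} has no truth points; TPR undefined")
            out[label] = float("nan")
        else:
            correct = int(row[label]) if label in cm.columns else 0
            out[label] = correct / total
    return out


def overall_accuracy(cm) -> float:
    """Proportion of correctly classified points (trace over total).

    Predictions in columns without a matching truth row (e.g.
    ``unclassified``) count as errors.
    """
    cm = _as_frame(cm)
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    trace = sum(int(cm.loc[l, l]) for l in cm.index if l in cm.columns)
    return trace / total


def cohens_kappa(cm) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    The expected agreement p_e comes from row/column marginals.  Extra
    prediction categories (``unclassified``) enter the marginals as truth
    rows with zero counts.  Returns ``nan`` (with a warning) when p_e = 1.
    """
    cm = _as_frame(cm)
    labels = list(cm.index) + [c for c in cm.columns if c not in cm.index]
    sq = cm.reindex(index=labels, columns=labels, fill_value=0).to_numpy(dtype=np.float64)
    total = sq.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(sq) / total
    p_e = float((sq.sum(axis=1) * sq.sum(axis=0)).sum()) / total ** 2
    if p_e == 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa undefined")
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)
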