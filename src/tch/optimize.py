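"""Exhaustive grid-search calibration of the four model constants.

Every combination in the Cartesian product of the candidate grids
(13 x 13 x 10 x 10 = 16,900) is evaluated by classifying every training
pixel and scoring the combination by its mean per-class sensitivity
(TPR).  The combination with the highest mean TPR wins; ties go to the
first combination in ascending lexicographic (c_g, c_r, c_y, c_d) order.
A calibration is "retained" only when its minimum class TPR is >= 0.7 —
lower values indicate imagery or training data too inconsistent to trust.

Hue, saturation and value do not depend on the constants, so they are
computed once per pixel and reused across all combinations
(``cache=True``); results are identical to naively re-classifying under
every combination (``cache=False``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_model import (CrownClass, ModelConstants, DEFAULT_THRESHOLD,
                          classify_array, pixel_features, _scores_from_features,
                          _assign)
from .metrics import CLASS_ORDER, confusion_matrix, per_class_tpr

__all__ = ["DEFAULT_GRID", "ConstantGrid", "OptimizationResult",
           "optimize_constants", "median_constants", "constants_table"]

MIN_RETAINED_TPR = 0.7


@dataclass(frozen=True)
class ConstantGrid:
    """Candidate values for the four constants; all must be >= 2."""

    c_g: tuple = (2, 5, 10, 20, 30, 40, 50, 60, 100, 1000, 10000, 100000, 1000000)
    c_r: tuple = (2, 5, 10, 20, 30, 40, 50, 60, 100, 1000, 10000, 100000, 1000000)
    c_y: tuple = (2, 5, 10, 100, 1000, 10000, 100000, 1000000, 10000000, 100000000)
    c_d: tuple = (2, 5, 10, 100, 1000, 10000, 100000, 1000000, 10000000, 100000000)

    def __post_init__(self):
        for name in ("c_g", "c_r", "c_y", "c_d"):
            vals = getattr(self, name)
            if not vals or any(v < 2 for v in vals):
                raise ValueError(f"grid values for {name} must be >= 2")

    @property
    def size(self) -> int:
        return len(self.c_g) * len(self.c_r) * len(self.c_y) * len(self.c_d)


DEFAULT_GRID = ConstantGrid()


@dataclass
class OptimizationResult:
    """Outcome of a grid search for one stratum."""

    constants: ModelConstants
    mean_tpr: float
    per_class_tpr: dict
    confusion: pd.DataFrame
    retained: bool
    n_combinations: int
    stratum: dict = field(default_factory=dict)
    trace: pd.DataFrame | None = None

    @property
    def min_tpr(self) -> float:
        return min(self.per_class_tpr.values())


def _truth_codes(points: pd.DataFrame) -> np.ndarray:
    labels = points["class"].astype(str).str.strip().str.lower()
    return labels.map({c.label: int(c) for c in CLASS_ORDER}).to_numpy()


def _mean_tpr_vec(pred: np.ndarray, truth: np.ndarray, class_masks) -> tuple:
    tprs = [float(np.mean(pred[m] == code)) for code, m in class_masks]
    return float(np.mean(tprs)), tprs


def optimize_constants(points: pd.DataFrame,
                       grid: ConstantGrid = DEFAULT_GRID,
                       t: float = DEFAULT_THRESHOLD,
                       bits: int = 8,
                       cache: bool = True,
                       keep_trace: bool = False,
                       stratum: dict | None = None) -> OptimizationResult:
    """Scan the full constant grid and return the best calibration.

    Parameters
    ----------
    points
        Training points with columns class, r, g, b; all four crown
        classes must be present.
    t
        Classification threshold held fixed during the scan.
    cache
        Reuse constant-independent per-pixel features across combinations
        (default); ``False`` re-runs the full classifier per combination.
        Both paths give identical results.
    keep_trace
        Also return the per-combination mean-TPR table.
    """
    if len(points) == 0:
        raise ValueError("empty training set")
    truth = _truth_codes(points)
    if np.any(pd.isna(truth)):
        raise ValueError("invalid class labels in training set")
    present = set(int(v) for v in np.unique(truth))
    needed = {int(c) for c in CLASS_ORDER}
    if present != needed:
        missing = [CrownClass(c).label for c in sorted(needed - present)]
        raise ValueError(f"training set missing classes: {missing}")

    rgb = points[["r", "g", "b"]].to_numpy()
    class_masks = [(int(c), truth == int(c)) for c in CLASS_ORDER]

    if cache:
        hg, hr, s, v, ach = pixel_features(rgb.astype(np.uint32), bits=bits)

        def predict(consts: ModelConstants) -> np.ndarray:
            G, R, Y, D = _scores_from_features(hg, hr, s, v, ach, consts)
            codes, _ = _assign(G, R, Y, D, consts.t)
            return codes
    else:
        def predict(consts: ModelConstants) -> np.ndarray:
            return classify_array(rgb.astype(np.uint32), consts, bits=bits)

    best = None
    best_mean = -1.0
    trace_rows = [] if keep_trace else None
    n_eval = 0
    for cg, cr, cy, cd in itertools.product(sorted(grid.c_g), sorted(grid.c_r),
                                            sorted(grid.c_y), sorted(grid.c_d)):
        consts = ModelConstants(c_g=cg, c_r=cr, c_y=cy, c_d=cd, t=t)
        pred = predict(consts)
        mean_tpr, tprs = _mean_tpr_vec(pred, truth, class_masks)
        n_eval += 1
        if trace_rows is not None:
            trace_rows.append((cg, cr, cy, cd, mean_tpr))
        if mean_tpr > best_mean:  # strict: first lexicographic combo wins ties
            best_mean = mean_tpr
            best = consts

    pred = predict(best)
    cm = confusion_matrix(truth, pred)
    tpr = per_class_tpr(cm)
    result = OptimizationResult(
        constants=best,
        mean_tpr=best_mean,
        per_class_tpr=tpr,
        confusion=cm,
        retained=min(tpr.values()) >= MIN_RETAINED_TPR,
        n_combinations=n_eval,
        stratum=dict(stratum or {}),
        trace=(pd.DataFrame(trace_rows,
                            columns=["c_g", "c_r", "c_y", "c_d", "mean_tpr"])
               if keep_trace else None),
    )
    return result


def median_constants(results, t: float = DEFAULT_THRESHOLD) -> ModelConstants:
    """Per-parameter median across a collection of optimization results.

    Reproduces the "global model" workflow: a single transferable
    constant set taken as the elementwise median of the per-stratum
    optima.
    """
    results = list(results)
    if not results:
        raise ValueError("no optimization results")
    med = {name: float(np.median([getattr(r.constants, name) for r in results]))
           for name in ("c_g", "c_r", "c_y", "c_d")}
    return ModelConstants(t=t, **med)


def constants_table(results) -> pd.DataFrame:
    """One row per stratum: selected constants, mean/per-class TPR, retained."""
    rows = []
    for r in results:
        row = dict(r.stratum)
        row.update(r.constants.to_dict())
        row["mean_tpr"] = r.mean_tpr
        for label, v in r.per_class_tpr.items():
            row[f"tpr_{label}"] = v
        row["retained"] = r.retained
        rows.append(row)
    return pd.DataFrame(rows)
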