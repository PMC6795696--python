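"""Exhaustive one-ROI-per-class cross-validation and model comparison.

Each validation cycle holds out one ROI per class (the Cartesian product of
the per-class ROI lists defines the cycles), trains on the remaining ROIs and
scores the percentage of pooled validation voxels classified correctly. The
hyperparameter with the highest median cycle accuracy wins; ties break toward
the smaller value, favoring the smoother model. Families are compared with a
two-tailed Welch t-test flagged at p < 0.05 / 0.005 / 0.0005.

A class contributing a single ROI keeps that ROI in the training set while it
also serves as validation — the only way to keep a full class taxonomy in
every cycle — and each affected cycle is flagged as leaky.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import FAMILIES, HYPERPARAMETER_RANGES, fit_classifier
from .training_data import TrainingSet

__all__ = [
    "CVCycleResult",
    "HyperparameterCurve",
    "ComparisonReport",
    "enumerate_validation_combinations",
    "run_cv",
    "select_hyperparameter",
    "compare_families",
    "evaluate_on_test",
    "default_hp_grid",
]


@dataclass
class CVCycleResult:
    """Accuracy of one training/validation cycle."""

    validation_roi_ids: tuple
    family: str
    hyperparameter: float | None
    accuracy: float                       # % pooled validation voxels correct
    per_class_accuracy: dict = field(default_factory=dict)
    leaky_classes: tuple = ()             # single-ROI classes also in training


@dataclass
class HyperparameterCurve:
    family: str
    values: list                          # hyperparameter grid (or [None])
    medians: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    optimum: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hyperparameter": self.values, "median": self.medians,
            "q25": self.q25, "q75": self.q75, "p5": self.p5, "p95": self.p95,
        })


@dataclass
class ComparisonReport:
    t_statistic: float | None
    p_value: float | None
    significant: bool
    annotation: str        # "", "*", "**", "***" at 0.05 / 0.005 / 0.0005
    degenerate: bool = False


def enumerate_validation_combinations(cv_set: TrainingSet) -> list[tuple]:
    """All one-ROI-per-class validation tuples, in lexicographic order.

    The count is the product of the per-class ROI counts. Classes iterate in
    ascending id; ROIs within a class in ascending roi_id.
    """
    by_class = cv_set.rois_by_class()
    if not by_class:
        raise ValueError("cross-validation set has no ROIs")
    class_ids = sorted(by_class)
    per_class = []
    for c in class_ids:
        ids = sorted(r.roi_id for r in by_class[c])
        if not ids:
            raise ValueError(f"class {c} has no ROIs")
        per_class.append(ids)
    return [tuple(combo) for combo in itertools.product(*per_class)]


def _single_roi_classes(cv_set: TrainingSet) -> set[int]:
    return {c for c, rois in cv_set.rois_by_class().items() if len(rois) == 1}


def _cycle(cv_set: TrainingSet, family, hp, combo, seed):
    roi_by_id = {r.roi_id: r for r in cv_set.rois}
    single = _single_roi_classes(cv_set)
    leaky = tuple(sorted(roi_by_id[rid].class_id for rid in combo
                         if roi_by_id[rid].class_id in single))
    # single-ROI classes stay in training even while validating on them
    exclude = [rid for rid in combo if roi_by_id[rid].class_id not in single]
    X_train, y_train = cv_set.matrices(exclude_roi_ids=exclude)
    model = fit_classifier(family, hp, (X_train, y_train), seed=seed)

    X_val = np.vstack([roi_by_id[rid].samples for rid in combo])
    y_val = np.concatenate([
        np.full(roi_by_id[rid].voxel_count, roi_by_id[rid].class_id) for rid in combo
    ])
    y_hat = model.predict(X_val)
    accuracy = 100.0 * float((y_hat == y_val).mean())
    per_class = {
        int(c): 100.0 * float((y_hat[y_val == c] == c).mean())
        for c in np.unique(y_val)
    }
    return CVCycleResult(validation_roi_ids=combo, family=family, hyperparameter=hp,
                         accuracy=accuracy, per_class_accuracy=per_class,
                         leaky_classes=leaky)


def run_cv(cv_set: TrainingSet, family: str, hp_grid=None,
           seed: int = 0) -> tuple[list[CVCycleResult], HyperparameterCurve]:
    """Run the exhaustive CV over a hyperparameter grid for one family.

    ``hp_grid`` defaults to the family's 25-point log-spaced search range, or
    ``[None]`` for the hyperparameter-free families (NB, aKDE).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if hp_grid is None:
        hp_grid = default_hp_grid(family)
    if HYPERPARAMETER_RANGES[family] is None:
        if list(hp_grid) != [None]:
            raise ValueError(f"{family} takes no hyperparameter grid")
    elif any(h is None for h in hp_grid):
        raise ValueError(f"{family} requires numeric hyperparameters")

    combos = enumerate_validation_combinations(cv_set)
    results: list[CVCycleResult] = []
    medians, q25, q75, p5, p95 = [], [], [], [], []
    for hp in hp_grid:
        accs = []
        for combo in combos:
            res = _cycle(cv_set, family, hp, combo, seed)
            results.append(res)
            accs.append(res.accuracy)
        accs = np.asarray(accs)
        medians.append(np.median(accs))
        q25.append(np.percentile(accs, 25))
        q75.append(np.percentile(accs, 75))
        p5.append(np.percentile(accs, 5))
        p95.append(np.percentile(accs, 95))
    curve = HyperparameterCurve(family=family, values=list(hp_grid),
                                medians=np.asarray(medians), q25=np.asarray(q25),
                                q75=np.asarray(q75), p5=np.asarray(p5),
                                p95=np.asarray(p95))
    curve.optimum = select_hyperparameter(curve)
    return results, curve


def select_hyperparameter(curve: HyperparameterCurve):
    """Pick the grid value with the highest median accuracy.

    On a plateau of equal medians the smallest hyperparameter wins (the
    smoother / simpler model).
    """
    if not curve.values:
        raise ValueError("empty hyperparameter curve")
    if curve.values == [None]:
        return None
    best_median = curve.medians.max()
    candidates = [v for v, m in zip(curve.values, curve.medians) if m == best_median]
    return min(candidates)


def default_hp_grid(family: str, n_points: int = 25):
    """Log-spaced grid across the family's search range (integer-valued for
    RF trees and kNN neighbors); ``[None]`` for NB and aKDE."""
    bounds = HYPERPARAMETER_RANGES[family]
    if bounds is None:
        return [None]
    lo, hi = bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), n_points)
    if family in ("RF", "kNN"):
        grid = np.unique(np.round(grid).astype(int))
        return [int(g) for g in grid]
    return [float(g) for g in grid]


def compare_families(results_a, results_b) -> ComparisonReport:
    """Two-tailed Welch t-test between two families' cycle accuracies."""
    a = np.asarray([r.accuracy if isinstance(r, CVCycleResult) else r
                    for r in results_a], dtype=float)
    b = np.asarray([r.accuracy if isinstance(r, CVCycleResult) else r
                    for r in results_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 accuracies per arm")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return ComparisonReport(t_statistic=None, p_value=None, significant=False,
                                annotation="", degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    annotation = ("***" if p < 0.0005 else "**" if p < 0.005
                  else "*" if p < 0.05 else "")
    return ComparisonReport(t_statistic=float(t), p_value=float(p),
                            significant=bool(p < 0.05), annotation=annotation)


def evaluate_on_test(models: dict, test_set: TrainingSet) -> dict[str, float]:
    """Pooled-voxel test accuracy (%) per fitted family on held-out ROIs."""
    if test_set.n_rois == 0:
        raise ValueError("test set is empty")
    X, y = test_set.matrices()
    return {name: 100.0 * float((model.predict(X) == y).mean())
            for name, model in models.items()}
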