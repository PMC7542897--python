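"""Confusion-matrix metrics with macro one-vs-rest averaging, and CV grid search.

Multiclass performance is scored the one-vs-rest way: each class in turn is
taken as positive, the rest as negative, the four binary measures

    Acc    = (TP + TN) / (TP + FN + FP + TN)
    Pre    = TP / (TP + FP)
    Recall = TP / (TP + FN)
    F      = 2 Pre Recall / (Pre + Recall)

are computed from that binary confusion table, and the per-class values are
arithmetically averaged ("macro").  An undefined ratio (0/0, e.g. precision
when nothing was predicted positive) is reported as 0 with a warning — the
conservative convention.  Plain multiclass accuracy is exposed alongside.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "BinaryCounts",
    "MetricReport",
    "confusion_counts",
    "classification_metrics",
    "grid_search_cv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest confusion counts for a single positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricReport:
    """Macro (or plain) classification metrics plus the per-class breakdown."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    averaging: str
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }


def confusion_counts(y_true, y_pred, positive_class) -> BinaryCounts:
    """Binary confusion counts with ``positive_class`` vs everything else."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp_mask = y_true == positive_class
    pp_mask = y_pred == positive_class
    return BinaryCounts(
        TP=int(np.sum(tp_mask & pp_mask)),
        FP=int(np.sum(~tp_mask & pp_mask)),
        FN=int(np.sum(tp_mask & ~pp_mask)),
        TN=int(np.sum(~tp_mask & ~pp_mask)),
    )


def _safe_ratio(num: float, den: float, name: str, cls) -> float:
    if den == 0:
        logger.warning("undefined %s for class %r (0/0); reporting 0", name, cls)
        return 0.0
    return num / den


def _binary_metrics(c: BinaryCounts, cls) -> dict:
    acc = _safe_ratio(c.TP + c.TN, c.total, "accuracy", cls)
    pre = _safe_ratio(c.TP, c.TP + c.FP, "precision", cls)
    rec = _safe_ratio(c.TP, c.TP + c.FN, "recall", cls)
    f = _safe_ratio(2 * pre * rec, pre + rec, "F-measure", cls)
    return {"accuracy": acc, "precision": pre, "recall": rec, "f_measure": f}


def classification_metrics(y_true, y_pred, averaging: str = "macro_ovr") -> MetricReport:
    """Score predictions.

    ``averaging="macro_ovr"`` averages the one-vs-rest binary metrics over
    the classes present in ``y_true``; ``averaging="plain"`` reports the
    ordinary multiclass accuracy (macro precision/recall/F are kept, since
    they have no "plain" analogue).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if averaging not in ("macro_ovr", "plain"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    classes = np.unique(y_true)
    per_class = {}
    for cls in classes:
        counts = confusion_counts(y_true, y_pred, cls)
        per_class[cls] = {"counts": counts, **_binary_metrics(counts, cls)}
    macro = {
        k: float(np.mean([per_class[c][k] for c in classes]))
        for k in ("accuracy", "precision", "recall", "f_measure")
    }
    if averaging == "plain":
        macro["accuracy"] = float(np.mean(y_true == y_pred))
    return MetricReport(
        accuracy=macro["accuracy"],
        precision=macro["precision"],
        recall=macro["recall"],
        f_measure=macro["f_measure"],
        averaging=averaging,
        per_class=per_class,
    )


def _grid_combinations(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, values)) for values in itertools.product(*(grid[k] for k in keys))]


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    grid: dict,
    n_folds: int = 10,
    seed: int = 0,
):
    """Exhaustive grid search by seeded stratified K-fold cross-validation.

    Every combination in the cartesian product of ``grid`` (a mapping from
    hyperparameter name to a list of candidate values) is scored by mean
    macro one-vs-rest accuracy over the folds; the best combination (ties:
    first in grid order) is returned together with the full per-combination
    table.  If the rarest class has fewer members than ``n_folds`` the fold
    count is reduced to that size so stratification stays valid.

    Returns ``(best_params, report)`` where ``report`` is a DataFrame with
    one row per combination: the parameters, and mean and variance of each
    macro metric across folds.
    """
    from .model import fit, predict  # late import to avoid a cycle

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    combos = _grid_combinations(grid)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < n_folds:
        warnings.warn(
            f"reducing n_folds from {n_folds} to {min_class} "
            "(smallest class size)", stacklevel=2
        )
        n_folds = min_class
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    classes = tuple(np.unique(y).tolist())

    rows = []
    best = None
    for combo in combos:
        fold_metrics = []
        for train_idx, val_idx in folds:
            model = fit(X[train_idx], y[train_idx], method=method,
                        classes=classes, **combo)
            rep = classification_metrics(y[val_idx], predict(model, X[val_idx]))
            fold_metrics.append(rep.as_dict())
        frame = pd.DataFrame(fold_metrics)
        row = dict(combo)
        for k in frame.columns:
            row[f"mean_{k}"] = float(frame[k].mean())
            row[f"var_{k}"] = float(frame[k].var(ddof=1)) if len(frame) > 1 else 0.0
        rows.append(row)
        if best is None or row["mean_accuracy"] > best[1]["mean_accuracy"]:
            best = (combo, row)
    report = pd.DataFrame(rows)
    return best[0], report
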