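"""Balanced linear-SVM evaluation under repeated stratified cross-validation.

Active mounting is rare (21 of 415 events), so the majority class is
randomly undersampled to the minority count before training. A
linear-kernel SVM (one-vs-rest reduction: mount vs everything else) is
grid-searched over the regularization parameter C and then scored with
stratified 5-fold cross-validation repeated 20 times — 100 fits — so the
reported metrics are a distribution, not a single split. Features are
standardized inside each fold (fit on the training portion only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: default search grid for the SVM regularization parameter
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("no evaluated samples")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class CVResult:
    """Per-iteration metrics across the repeated-CV fits."""

    metrics: pd.DataFrame  # columns: iteration, fold, repeat, accuracy, ...
    C: float
    seed: int
    frame: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.metrics)

    def mean(self, metric: str = "f1") -> float:
        return float(self.metrics[metric].mean())

    def summary(self) -> dict:
        out = {}
        for m in ("accuracy", "precision", "recall", "f1"):
            col = self.metrics[m]
            out[m] = {"mean": float(col.mean()), "median": float(col.median()),
                      "std": float(col.std(ddof=1))}
        out["C"] = self.C
        out["n_iterations"] = self.n_iterations
        return out


def make_svm(C: float = 1.0, standardize: bool = True) -> Pipeline:
    """Linear-kernel SVM with (optional) per-fold feature standardization."""
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="linear", C=C)))
    return Pipeline(steps)


def balance_classes(X, y, seed: int):
    """Undersample the majority class to the minority count, without
    replacement; the minority class is kept whole. Returns (X', y', idx)
    with idx the selected row positions in the original order."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for c, n in zip(classes, counts):
        pos = np.flatnonzero(y == c)
        if n > n_min:
            pos = rng.choice(pos, size=n_min, replace=False)
        keep.append(pos)
    idx = np.sort(np.concatenate(keep))
    Xb = X.iloc[idx] if hasattr(X, "iloc") else np.asarray(X)[idx]
    return Xb, y[idx], idx


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, F1 from confusion counts.

    Zero denominators give 0 for precision/recall/F1.
    """
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return MetricSet(accuracy=accuracy, precision=precision,
                     recall=recall, f1=f1)


def _as_array(X):
    return X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)


def grid_search_C(X, y, grid=DEFAULT_C_GRID, folds: int = 5, seed: int = 0,
                  standardize: bool = True) -> float:
    """Exhaustive search of C by stratified-CV mean F1; ties -> smallest C."""
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty C grid")
    X = _as_array(X)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_C, best_f1 = grid[0], -1.0
    for C in grid:
        f1s = []
        for tr, te in splits:
            model = make_svm(C=C, standardize=standardize)
            model.fit(X[tr], y[tr])
            f1s.append(compute_metrics(confusion_counts(y[te], model.predict(X[te]))).f1)
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1 + 1e-12:
            best_C, best_f1 = C, mean_f1
    return best_C


def repeated_stratified_cv(X, y, C: float = 1.0, folds: int = 5,
                           repeats: int = 20, seed: int = 0,
                           standardize: bool = True, frame: str = "") -> CVResult:
    """folds x repeats stratified train/test fits of the linear SVM.

    Each of the 100 (default) iterations records the four metrics of its
    held-out fold. Deterministic under ``seed``.
    """
    X = _as_array(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed)
    rows = []
    for it, (tr, te) in enumerate(rskf.split(X, y)):
        model = make_svm(C=C, standardize=standardize)
        model.fit(X[tr], y[tr])
        m = compute_metrics(confusion_counts(y[te], model.predict(X[te])))
        rows.append({"iteration": it, "fold": it % folds, "repeat": it // folds,
                     "accuracy": m.accuracy, "precision": m.precision,
                     "recall": m.recall, "f1": m.f1})
    return CVResult(metrics=pd.DataFrame(rows), C=C, seed=seed, frame=frame)


def confusion_by_behavior(model, X, behaviors) -> pd.DataFrame:
    """False-positive rate of each non-mount behavior against a fitted
    binary model: per behavior (n, false positives, percent)."""
    X = _as_array(X)
    behaviors = np.asarray(behaviors)
    pred = np.asarray(model.predict(X)).astype(int)
    rows = []
    for b in pd.unique(behaviors):
        if b == "active_mounting":
            continue
        mask = behaviors == b
        n = int(mask.sum())
        if n == 0:
            continue
        fp = int(pred[mask].sum())
        rows.append({"behavior": b, "n": n, "false_positives": fp,
                     "confusion_rate_pct": false_positive_rate_pct(n, fp)})
    return pd.DataFrame(rows)


def false_positive_rate_pct(n: int, fp: int) -> float:
    """Percentage of n non-mount windows misclassified as mounts."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= fp <= n:
        raise ValueError("false-positive count outside [0, n]")
    return 100.0 * fp / n
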