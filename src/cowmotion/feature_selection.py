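"""Sequential Backward Selection and permutation importance.

SBS starts from the full feature set and greedily removes, at each step,
the feature whose removal leaves the highest cross-validated F1, recording
the whole elimination path; the best subset is the argmax of F1 over the
visited sizes. Permutation importance measures each feature's relevance as
the mean drop in F1 when that column is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model_eval import compute_metrics, confusion_counts, make_svm


@dataclass
class SelectionTrace:
    """Elimination path of one SBS run."""

    removals: pd.DataFrame  # columns: step, removed_feature, n_remaining, f1_after
    best_subset: list
    best_f1: float
    start_f1: float

    def subset_of_size(self, k: int) -> list:
        """Feature names still present when k features remained."""
        removed = list(self.removals["removed_feature"])
        start = list(self.removals.attrs["start_features"])
        n_removed = len(start) - k
        if not 0 <= n_removed <= len(removed):
            raise ValueError(f"no visited subset of size {k}")
        gone = set(removed[:n_removed])
        return [f for f in start if f not in gone]


def cv_f1_evaluator(C: float = 1.0, folds: int = 5, repeats: int = 1,
                    seed: int = 0, standardize: bool = True):
    """Stratified-CV mean-F1 functional used to score candidate subsets.

    Single-repeat 5-fold by default: a full 112-feature elimination is
    ~6000 subset evaluations, so the heavier repeated scheme is reserved
    for the final model.
    """
    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        f1s = []
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed + r)
            for tr, te in skf.split(X, y):
                model = make_svm(C=C, standardize=standardize)
                model.fit(X[tr], y[tr])
                m = compute_metrics(confusion_counts(y[te], model.predict(X[te])))
                f1s.append(m.f1)
        return float(np.mean(f1s))

    return evaluate


def sbs(X, y, evaluator, stop_size: int = 1) -> SelectionTrace:
    """Greedy backward elimination driven by the evaluator's F1.

    At each step every single-feature removal is scored and the one whose
    absence yields the highest F1 is dropped (ties -> first in column
    order). Returns the full trace and the best subset over all visited
    sizes (the start set included).
    """
    if hasattr(X, "columns"):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if not 1 <= stop_size < len(names):
        raise ValueError("stop_size must be in [1, n_features)")

    current = list(range(len(names)))
    start_f1 = evaluator(X[:, current], y)
    best_subset, best_f1 = list(current), start_f1
    rows = []
    step = 0
    while len(current) > stop_size:
        scores = []
        for j in current:
            cand = [c for c in current if c != j]
            scores.append(evaluator(X[:, cand], y))
        k = int(np.argmax(scores))  # ties -> first (column order)
        removed = current.pop(k)
        f1_after = scores[k]
        rows.append({"step": step, "removed_feature": names[removed],
                     "n_remaining": len(current), "f1_after": f1_after})
        if f1_after > best_f1:
            best_subset, best_f1 = list(current), f1_after
        step += 1
    removals = pd.DataFrame(rows)
    removals.attrs["start_features"] = names
    return SelectionTrace(
        removals=removals,
        best_subset=[names[i] for i in best_subset],
        best_f1=best_f1,
        start_f1=start_f1,
    )


def permutation_importance(model, X, y, repeats: int = 10, seed: int = 0) -> pd.Series:
    """Mean F1 drop per feature when its column is shuffled.

    The model must already be fitted on (X, y)-compatible data; the
    baseline F1 is measured on (X, y) as given.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if hasattr(X, "columns"):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    baseline = compute_metrics(confusion_counts(y, model.predict(X))).f1
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            f1 = compute_metrics(confusion_counts(y, model.predict(Xp))).f1
            drops[j] += baseline - f1
    return pd.Series(drops / repeats, index=names, name="f1_drop")
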