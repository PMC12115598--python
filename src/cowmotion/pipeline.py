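"""End-to-end experiment: data -> features -> balance -> SVM -> comparison.

One experiment reads (or receives) a labeled event database, builds the
112-feature design matrix for each requested reference frame, balances the
mount / non-mount classes once with a shared seed so the body-frame and
world-frame runs are paired on identical events, grid-searches the SVM's C
on a stratified 80% training split, scores the model with repeated
stratified cross-validation, and compares the two frames' F1 distributions.
Optionally, sequential backward selection reduces each frame's feature set
and the evaluation and comparison are repeated on the selected subsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import feature_selection, model_eval, stats_compare
from .config import RunConfig, substream_seeds
from .features import build_design_matrix
from .io_dataset import load_database
from .model_eval import CVResult

logger = logging.getLogger(__name__)


@dataclass
class ExperimentBundle:
    """Everything one experiment produced."""

    config: RunConfig
    design: dict            # frame -> (X, y, meta) on the full database
    balanced_idx: np.ndarray
    cv_results: dict        # frame -> CVResult
    chosen_C: dict          # frame -> float
    comparison: stats_compare.FrameComparison | None
    confusion: dict = field(default_factory=dict)   # frame -> DataFrame
    sbs_traces: dict = field(default_factory=dict)  # frame -> SelectionTrace
    sbs_cv_results: dict = field(default_factory=dict)
    sbs_comparison: stats_compare.FrameComparison | None = None
    seeds: dict = field(default_factory=dict)


def run_experiment(cfg: RunConfig, db=None) -> ExperimentBundle:
    """Run the full pipeline; ``db`` may be a pre-loaded recording list."""
    seeds = substream_seeds(cfg.seed)
    if db is None:
        db = load_database(cfg.database)
    if not db:
        raise ValueError("empty database")

    design, balanced = {}, {}
    balanced_idx = None
    for frame in cfg.frames:
        X, y, meta = build_design_matrix(db, frame=frame, mode=cfg.window_mode,
                                         window_s=cfg.window_s)
        design[frame] = (X, y, meta)
        if cfg.balance:
            if balanced_idx is None:
                # one undersampling, shared across frames: paired comparison
                _, _, balanced_idx = model_eval.balance_classes(
                    X, y, seed=seeds["balance"])
            Xb = X.iloc[balanced_idx].reset_index(drop=True)
            yb = y[balanced_idx]
        else:
            balanced_idx = np.arange(len(y))
            Xb, yb = X, y
        balanced[frame] = (Xb, yb)
        logger.info("frame=%s: %d windows, %d after balancing (%d positive)",
                    frame, len(y), len(yb), int(yb.sum()))

    cv_results, chosen_C, confusion = {}, {}, {}
    for frame in cfg.frames:
        Xb, yb = balanced[frame]
        X_tr, _, y_tr, _ = train_test_split(
            Xb, yb, train_size=0.8, stratify=yb, random_state=seeds["grid"])
        C = model_eval.grid_search_C(X_tr, y_tr, grid=cfg.c_grid,
                                     folds=cfg.folds, seed=seeds["grid"],
                                     standardize=cfg.standardize)
        chosen_C[frame] = C
        logger.info("frame=%s: grid search chose C=%g", frame, C)
        cv_results[frame] = model_eval.repeated_stratified_cv(
            Xb, yb, C=C, folds=cfg.folds, repeats=cfg.repeats,
            seed=seeds["folds"], standardize=cfg.standardize, frame=frame)

        # per-behavior confusion of a model fit on the balanced set,
        # evaluated on every non-mount window of the full database
        model = model_eval.make_svm(C=C, standardize=cfg.standardize)
        model.fit(Xb.to_numpy(dtype=float), yb)
        X, y, meta = design[frame]
        non_mount = y == 0
        confusion[frame] = model_eval.confusion_by_behavior(
            model, X[non_mount], meta.loc[non_mount, "behavior"].to_numpy())

    comparison = None
    if {"body", "world"} <= set(cfg.frames):
        comparison = stats_compare.compare_frames(
            cv_results["body"].metrics["f1"].to_numpy(),
            cv_results["world"].metrics["f1"].to_numpy())
    else:
        logger.warning("single frame requested; no frame comparison emitted")

    bundle = ExperimentBundle(
        config=cfg, design=design, balanced_idx=balanced_idx,
        cv_results=cv_results, chosen_C=chosen_C, comparison=comparison,
        confusion=confusion, seeds=seeds,
    )

    if cfg.run_sbs:
        for frame in cfg.frames:
            Xb, yb = balanced[frame]
            evaluator = feature_selection.cv_f1_evaluator(
                C=chosen_C[frame], folds=cfg.folds,
                repeats=cfg.sbs_cv_repeats, seed=seeds["sbs"],
                standardize=cfg.standardize)
            trace = feature_selection.sbs(Xb, yb, evaluator,
                                          stop_size=cfg.sbs_stop_size)
            bundle.sbs_traces[frame] = trace
            logger.info("frame=%s: SBS best subset of %d features (F1=%.3f)",
                        frame, len(trace.best_subset), trace.best_f1)
            bundle.sbs_cv_results[frame] = model_eval.repeated_stratified_cv(
                Xb[trace.best_subset], yb, C=chosen_C[frame], folds=cfg.folds,
                repeats=cfg.repeats, seed=seeds["folds"],
                standardize=cfg.standardize, frame=frame)
        if {"body", "world"} <= set(cfg.frames):
            bundle.sbs_comparison = stats_compare.compare_frames(
                bundle.sbs_cv_results["body"].metrics["f1"].to_numpy(),
                bundle.sbs_cv_results["world"].metrics["f1"].to_numpy())
    return bundle


def _metric_table(cv_results: dict) -> pd.DataFrame:
    rows = []
    for frame, cv in cv_results.items():
        s = cv.summary()
        rows.append({"frame": frame,
                     **{m: 100 * s[m]["mean"] for m in
                        ("accuracy", "precision", "recall", "f1")},
                     "C": s["C"]})
    return pd.DataFrame(rows)


def reproduce_report(bundle: ExperimentBundle) -> str:
    """Markdown report of an experiment bundle."""
    if not bundle.cv_results:
        raise ValueError("bundle has no CV results")
    lines = ["# Active-mount detection experiment", ""]
    lines += ["## Mean metrics over CV iterations (percent)", ""]
    lines.append(_metric_table(bundle.cv_results).to_markdown(
        index=False, floatfmt=".1f"))
    lines.append("")

    lines += ["## F1 descriptive statistics", ""]
    for frame, cv in bundle.cv_results.items():
        mean, median, std = stats_compare.describe(cv.metrics["f1"].to_numpy())
        lines.append(f"- {frame}: mean {mean:.3f}, median {median:.3f}, "
                     f"std {std:.3f} ({cv.n_iterations} iterations)")
    lines.append("")

    if bundle.comparison is not None:
        c = bundle.comparison
        lines += ["## Frame comparison (F1 distributions)", ""]
        lines.append(f"- test: {c.test_name}, statistic {c.statistic:.4g}, "
                     f"p = {c.p_value:.3g}")
        if c.rank_biserial is not None:
            lines.append(f"- rank-biserial effect size: {c.rank_biserial:.3f}")
        lines.append(f"- mean difference (body - world): {c.mean_diff:.4f}, "
                     f"95% CI [{c.ci95[0]:.4f}, {c.ci95[1]:.4f}]")
        lines.append("")

    for frame, table in bundle.confusion.items():
        if len(table):
            lines += [f"## Non-mount false-positive rates ({frame} frame)", ""]
            lines.append(table.to_markdown(index=False, floatfmt=".2f"))
            lines.append("")

    if bundle.sbs_traces:
        lines += ["## Sequential backward selection", ""]
        for frame, trace in bundle.sbs_traces.items():
            lines.append(f"- {frame}: best subset {len(trace.best_subset)} "
                         f"features, F1 {trace.best_f1:.3f} "
                         f"(started at {trace.start_f1:.3f})")
        if bundle.sbs_comparison is not None:
            c = bundle.sbs_comparison
            lines.append(f"- after selection: {c.test_name} p = {c.p_value:.3g}"
                         + (f", rank-biserial {c.rank_biserial:.3f}"
                            if c.rank_biserial is not None else ""))
        lines.append("")
    return "\n".join(lines)


def export_bundle(bundle: ExperimentBundle, out_dir) -> Path:
    """Write CV tables, summaries, comparison JSON and the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seeds": bundle.seeds, "chosen_C": bundle.chosen_C}
    for frame, cv in bundle.cv_results.items():
        cv.metrics.to_csv(out / f"cv_metrics_{frame}.csv", index=False)
        summary[f"metrics_{frame}"] = cv.summary()
    if bundle.comparison is not None:
        summary["comparison"] = stats_compare.comparison_to_dict(bundle.comparison)
    if bundle.sbs_comparison is not None:
        summary["sbs_comparison"] = stats_compare.comparison_to_dict(
            bundle.sbs_comparison)
    for frame, trace in bundle.sbs_traces.items():
        trace.removals.to_csv(out / f"sbs_trace_{frame}.csv", index=False)
        (out / f"sbs_subset_{frame}.json").write_text(
            json.dumps({"features": trace.best_subset,
                        "f1": trace.best_f1}, indent=2))
    for frame, table in bundle.confusion.items():
        table.to_csv(out / f"confusion_{frame}.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "report.md").write_text(reproduce_report(bundle))
    return out
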