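"""Validation protocol and diagnostic-metric reporting.

The cohort is split 2:1 (stratified by group) into a cross-validation set and
an independent test set; 10-fold stratified cross-validation is run on the
former (normalizer, imputer and feature screening re-fit inside every
training partition), then the whole cross-validation set trains the final
model evaluated on the test set.  Metrics: accuracy, sensitivity,
specificity, PPV, NPV from pooled confusion counts; ROC and AUC from the
continuous relative-residual score.  Repeat intervals (2.5/97.5 percentiles
over re-seeded repetitions of the full cross-validation) accompany the CV
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from cerebrad.pipeline import FeatureMatrix, MedianImputer
from cerebrad.sparse import SparseRepresentationClassifier, SRCSettings

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "make_split",
    "binary_metrics",
    "roc_curve",
    "run_cv",
    "run_test",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class SplitPlan:
    """Stratified 2:1 cv/test partition plus 10 stratified folds over the cv set."""

    cv_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: dict  # subject id -> fold index (0..n_folds-1)
    n_folds: int
    seed: int

    def fold_members(self, fold: int) -> tuple[str, ...]:
        return tuple(s for s in self.cv_ids if self.folds[s] == fold)


def make_split(
    labels: pd.Series,
    ratio: tuple[int, int] = (2, 1),
    n_folds: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Stratified cv/test split at ``ratio`` with fold assignments.

    Per class, the test set takes ``floor(n_class * test_frac)`` subjects
    (floor on test, remainder to cv); cv subjects are dealt round-robin into
    folds so fold sizes differ by at most one within each class.
    """
    if ratio[1] <= 0 or ratio[0] <= 0:
        raise ValueError(f"both split portions must be positive, got ratio {ratio}")
    test_frac = ratio[1] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    cv_ids: list[str] = []
    test_ids: list[str] = []
    folds: dict[str, int] = {}
    for cls in sorted(labels.unique()):
        members = list(labels.index[labels == cls])
        rng.shuffle(members)
        n_test = int(np.floor(len(members) * test_frac))
        test_ids.extend(members[:n_test])
        cls_cv = members[n_test:]
        if len(cls_cv) < n_folds:
            raise ValueError(
                f"class {cls!r} has only {len(cls_cv)} cv subjects for {n_folds} folds"
            )
        cv_ids.extend(cls_cv)
        for i, s in enumerate(cls_cv):
            folds[s] = i % n_folds
    return SplitPlan(
        cv_ids=tuple(cv_ids), test_ids=tuple(test_ids),
        folds=folds, n_folds=n_folds, seed=seed,
    )


def binary_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV; NaN (with warning) on empty denominators."""
    out: dict[str, float] = {}
    total = tp + fn + tn + fp
    out["accuracy"] = (tp + tn) / total if total else np.nan
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator); reported as NA")
            out[name] = np.nan
        else:
            out[name] = num / den
    return out


def roc_curve(scores: Sequence[float], labels: Sequence[int]):
    """Threshold-sweep ROC points and trapezoidal AUC.

    ``labels`` are 0/1 with 1 the positive class; higher score means more
    positive.  The AUC equals the normalized Mann-Whitney U statistic.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return fpr, tpr, thresholds, auc


@dataclass
class EvaluationReport:
    """Confusion counts, diagnostic metrics, ROC, and repeat intervals."""

    task: tuple[str, str]  # (positive, negative) group labels
    confusion: dict[str, int]  # tp, fn, tn, fp
    metrics: dict[str, float]
    auc: float
    roc_points: pd.DataFrame
    repeat_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_repeat: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"task: {self.task[0]} (positive) vs {self.task[1]} (negative)",
            "confusion: "
            + ", ".join(f"{k.upper()}={v}" for k, v in self.confusion.items()),
        ]
        for name in METRIC_NAMES:
            v = self.metrics[name]
            if name in self.repeat_intervals:
                lo, hi = self.repeat_intervals[name]
                lines.append(f"{name:>12s}: {v:.3f} [{lo:.3f} {hi:.3f}]")
            else:
                lines.append(f"{name:>12s}: {v:.3f}" if np.isfinite(v) else f"{name:>12s}: NA")
        lines.append(f"{'auc':>12s}: {self.auc:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "task": list(self.task),
            "confusion": self.confusion,
            "metrics": {k: (None if not np.isfinite(v) else v) for k, v in self.metrics.items()},
            "auc": self.auc,
            "repeat_intervals": {k: list(v) for k, v in self.repeat_intervals.items()},
            "settings": self.settings,
        }

    def save(self, path: str | Path) -> None:
        import json

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        self.roc_points.to_csv(path.with_suffix(".roc.csv"), index=False)

    def plot_roc(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"], label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _evaluate_partition(
    fm: FeatureMatrix,
    ybin: pd.Series,
    train_ids: Sequence[str],
    eval_ids: Sequence[str],
    settings: SRCSettings,
    seed: int,
):
    """Fit imputer+normalizer+screening+dictionary on train, decide eval rows."""
    train_ids = list(train_ids)
    eval_ids = list(eval_ids)
    y_train = ybin.loc[train_ids]
    if y_train.nunique() < 2:
        raise ValueError("training partition contains a single class; cannot fit")
    imputer = MedianImputer().fit(fm.values.loc[train_ids], fm.flags.loc[train_ids])
    X_train = imputer.transform(fm.values.loc[train_ids], fm.flags.loc[train_ids]).to_numpy()
    X_eval = imputer.transform(fm.values.loc[eval_ids], fm.flags.loc[eval_ids]).to_numpy()
    model = SparseRepresentationClassifier(
        X_train, np.where(y_train.to_numpy() == 1, "pos", "neg"),
        classes=("neg", "pos"), settings=settings, seed=seed,
    )
    res = model.fit()
    dec = res.decide(X_eval)
    return dec["score"].to_numpy(), (dec["predicted"].to_numpy() == "pos").astype(int)


def _pooled_report(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray,
    task: tuple[str, str], settings: dict,
) -> EvaluationReport:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    mets = binary_metrics(tp, fn, tn, fp)
    if len(np.unique(y_true)) == 2:
        fpr, tpr, thr, auc = roc_curve(scores, y_true)
        roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    else:
        warnings.warn("single-class evaluation set; ROC/AUC reported as NA")
        auc = np.nan
        roc_df = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    return EvaluationReport(
        task=task, confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        metrics=mets, auc=auc, roc_points=roc_df, settings=settings,
    )


def _cv_once(
    fm: FeatureMatrix, ybin: pd.Series, plan: SplitPlan,
    settings: SRCSettings, fold_seed: int,
):
    """One full CV pass: returns pooled (y_true, y_pred, scores) over cv subjects."""
    # re-draw fold assignment for repeats > 0, keeping the cv/test partition fixed
    if fold_seed == plan.seed:
        folds = plan.folds
    else:
        rng = np.random.default_rng(fold_seed)
        folds = {}
        for cls in sorted(ybin.loc[list(plan.cv_ids)].unique()):
            members = [s for s in plan.cv_ids if ybin.loc[s] == cls]
            rng.shuffle(members)
            for i, s in enumerate(members):
                folds[s] = i % plan.n_folds
    y_true, y_pred, scores, ids = [], [], [], []
    for fold in range(plan.n_folds):
        held = [s for s in plan.cv_ids if folds[s] == fold]
        train = [s for s in plan.cv_ids if folds[s] != fold]
        if not held:
            continue
        sc, pred = _evaluate_partition(fm, ybin, train, held, settings, seed=fold_seed + fold)
        scores.extend(sc)
        y_pred.extend(pred)
        y_true.extend(ybin.loc[held])
        ids.extend(held)
    return np.asarray(y_true), np.asarray(y_pred), np.asarray(scores), ids


def _task_binary(fm: FeatureMatrix, positive, negative) -> tuple[FeatureMatrix, pd.Series]:
    sub, y = fm.task_subset(positive, negative)
    return sub, y


def _task_name(groups) -> str:
    return groups if isinstance(groups, str) else "+".join(groups)


def score_fusion_cv(
    fm: FeatureMatrix,
    plan: SplitPlan,
    positive: Sequence[str] | str,
    negative: Sequence[str] | str,
    settings: SRCSettings | None = None,
) -> EvaluationReport:
    """Score-level modality fusion: average the per-modality decision scores.

    Alternative to the default feature-concatenation fusion: one classifier
    is cross-validated per modality and the continuous relative-residual
    scores are averaged per subject; the fused prediction is the score sign.
    """
    settings = settings or SRCSettings()
    per_modality = []
    y_ref = None
    for m in fm.modalities:
        sub, ybin = _task_binary(fm.restrict([m]), positive, negative)
        cv_ids = [s for s in plan.cv_ids if s in sub.values.index]
        plan_m = SplitPlan(
            cv_ids=tuple(cv_ids), test_ids=plan.test_ids,
            folds={s: plan.folds[s] for s in cv_ids},
            n_folds=plan.n_folds, seed=plan.seed,
        )
        y_true, _, scores, ids = _cv_once(sub, ybin, plan_m, settings, plan.seed)
        per_modality.append(pd.Series(scores, index=ids))
        y_ref = pd.Series(y_true, index=ids)
    fused = pd.concat(per_modality, axis=1).mean(axis=1)
    y_true = y_ref.loc[fused.index].to_numpy()
    y_pred = (fused.to_numpy() > 0).astype(int)
    return _pooled_report(
        y_true, y_pred, fused.to_numpy(),
        task=(_task_name(positive), _task_name(negative)),
        settings={**settings.to_dict(), "protocol": "cv", "fusion": "score"},
    )


def run_cv(
    fm: FeatureMatrix,
    plan: SplitPlan,
    positive: Sequence[str] | str,
    negative: Sequence[str] | str,
    settings: SRCSettings | None = None,
    repeats: int = 1,
) -> EvaluationReport:
    """Stratified 10-fold cross-validation on the cv portion of the plan.

    Predictions are pooled over folds for the confusion matrix and ROC.  With
    ``repeats > 1`` the whole CV is re-run with re-seeded fold assignments and
    each metric's 2.5/97.5 percentile interval across repeats is reported.
    """
    settings = settings or SRCSettings()
    sub, ybin = _task_binary(fm, positive, negative)
    cv_ids = [s for s in plan.cv_ids if s in sub.values.index]
    plan_cv = SplitPlan(
        cv_ids=tuple(cv_ids), test_ids=plan.test_ids,
        folds={s: plan.folds[s] for s in cv_ids}, n_folds=plan.n_folds, seed=plan.seed,
    )
    per_repeat = []
    main_report: EvaluationReport | None = None
    for r in range(repeats):
        fold_seed = plan.seed + r
        y_true, y_pred, scores, _ = _cv_once(sub, ybin, plan_cv, settings, fold_seed)
        rep = _pooled_report(
            y_true, y_pred, scores,
            task=(_task_name(positive), _task_name(negative)),
            settings={**settings.to_dict(), "protocol": "cv", "repeats": repeats},
        )
        if r == 0:
            main_report = rep
        per_repeat.append({**rep.metrics, "auc": rep.auc})
    assert main_report is not None
    if repeats > 1:
        df = pd.DataFrame(per_repeat)
        main_report.per_repeat = df
        main_report.repeat_intervals = {
            name: (float(np.nanpercentile(df[name], 2.5)), float(np.nanpercentile(df[name], 97.5)))
            for name in df.columns
        }
    return main_report


def run_test(
    fm: FeatureMatrix,
    plan: SplitPlan,
    positive: Sequence[str] | str,
    negative: Sequence[str] | str,
    settings: SRCSettings | None = None,
    external: FeatureMatrix | None = None,
) -> EvaluationReport:
    """Train on the whole cv set, evaluate on the held-out test set.

    With ``external`` given, the test rows are drawn from that second cohort
    instead of the plan's held-out split (external-validation mode).
    """
    settings = settings or SRCSettings()
    sub, ybin = _task_binary(fm, positive, negative)
    train_ids = [s for s in plan.cv_ids if s in sub.values.index]
    if external is not None:
        ext_sub, ext_y = _task_binary(external, positive, negative)
        fused_values = pd.concat([sub.values.loc[train_ids], ext_sub.values])
        fused_flags = pd.concat([sub.flags.loc[train_ids], ext_sub.flags])
        fused_labels = pd.concat([sub.labels.loc[train_ids], ext_sub.labels])
        sub = FeatureMatrix(fused_values, fused_labels, fused_flags, sub.provenance)
        ybin = pd.concat([ybin.loc[train_ids], ext_y])
        eval_ids = list(ext_sub.values.index)
    else:
        eval_ids = [s for s in plan.test_ids if s in sub.values.index]
    if not eval_ids:
        raise ValueError("evaluation set is empty for this task")
    scores, y_pred = _evaluate_partition(sub, ybin, train_ids, eval_ids, settings, seed=plan.seed)
    y_true = ybin.loc[eval_ids].to_numpy()
    return _pooled_report(
        y_true, y_pred, scores,
        task=(_task_name(positive), _task_name(negative)),
        settings={**settings.to_dict(), "protocol": "external" if external is not None else "test"},
    )
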