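"""Cross-validation, regression reporting, threshold-sweep classification.

The evaluation mirrors a screening-study workflow: models are scored by
stratified k-fold cross-validation (folds preserve the normal/abnormal
bilirubin ratio); pooled out-of-fold predictions are summarised by an
ordinary-least-squares fit of the truth on the predictions (slope near 1 and
high R² mean a well-calibrated predictor); and jaundice classification is
tuned by sweeping the bilirubin threshold that defines "abnormal".

Sweep semantics: at each grid threshold t the *ground-truth* labels are
re-binarised as (truth > t) while the continuous predictions serve as scores,
so AUC(t) measures how well the predictor ranks subjects around each
candidate cutoff.  The confusion matrix at the chosen threshold then
binarises predictions and truth at the same t.  Grid points where one class
vanishes have no defined AUC and are excluded from the maximisation; ties are
broken toward the lowest threshold.

Classifier pairs are compared with the exact McNemar test (two-sided binomial
on the discordant pairs), the appropriate form at small discordant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import SubjectRecord

if TYPE_CHECKING:  # pragma: no cover
    from .models import ModelSpec
from .errors import (
    ConfigurationError,
    UndefinedAUCError,
    UndefinedMetricError,
    ZeroVarianceError,
)

DEFAULT_GRID = tuple(np.round(np.arange(1.0, 4.0 + 1e-9, 0.1), 1))


# --------------------------------------------------------------------------
# fold assignment and cross-validation
# --------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]  # subject_id -> fold index
    strat_threshold: float  # mg/dL

    def members(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]


def stratified_folds(
    cohort: Sequence[SubjectRecord],
    k: int = 5,
    strat_threshold: float = 3.0,
    seed: int = 0,
) -> FoldAssignment:
    """Seeded shuffle within each bilirubin stratum, then round-robin folds.

    Round-robin assignment within a stratum guarantees that per-fold counts
    of that stratum differ by at most one, the stratification invariant.
    """
    n = len(cohort)
    if k < 2:
        raise ConfigurationError("need k >= 2 folds")
    if n < k:
        raise ConfigurationError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for abnormal in (False, True):
        stratum = [r.subject_id for r in cohort if (r.total_bilirubin > strat_threshold) == abnormal]
        rng.shuffle(stratum)
        for i, sid in enumerate(stratum):
            fold_of[sid] = i % k
    return FoldAssignment(k=k, fold_of=fold_of, strat_threshold=strat_threshold)


def cross_validate(
    spec: "ModelSpec",
    cohort: Sequence[SubjectRecord],
    inputs: Mapping[str, object],
    folds: FoldAssignment,
) -> dict[str, float]:
    """Pooled out-of-fold predictions: each subject predicted exactly once
    by the model trained without its fold."""
    from . import models as _models  # local import keeps module layering acyclic

    missing = [r.subject_id for r in cohort if r.subject_id not in inputs]
    if missing:
        raise ConfigurationError(f"missing inputs for subjects {missing[:5]}")
    preds: dict[str, float] = {}
    by_id = {r.subject_id: r for r in cohort}
    for fold in range(folds.k):
        test_ids = [sid for sid in folds.fold_of if folds.fold_of[sid] == fold]
        train_ids = [sid for sid in folds.fold_of if folds.fold_of[sid] != fold]
        if not test_ids:
            continue
        model = _models.train(
            spec,
            [inputs[sid] for sid in train_ids],
            [by_id[sid].total_bilirubin for sid in train_ids],
        )
        for sid in test_ids:
            preds[sid] = _models.predict(model, inputs[sid])
    return preds


# --------------------------------------------------------------------------
# regression report
# --------------------------------------------------------------------------


@dataclass
class RegressionReport:
    slope_B: float
    slope_se: float
    r_squared: float
    pearson_r: float
    mean_difference: float  # mean(pred - truth), mg/dL
    diff_sd: float  # sample sd of (pred - truth), mg/dL
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope_B": self.slope_B,
            "slope_se": self.slope_se,
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "mean_difference": self.mean_difference,
            "diff_sd": self.diff_sd,
            "p_value": self.p_value,
            "n": self.n,
        }


def regression_report(pred: Sequence[float], truth: Sequence[float]) -> RegressionReport:
    """OLS of truth on prediction: truth = a + B*pred, with the slope t-test."""
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ConfigurationError("need aligned 1-D pred/truth with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("pred/truth must be finite")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("predictions have zero variance; slope undefined")
    fit = stats.linregress(x, y)
    diff = x - y
    return RegressionReport(
        slope_B=float(fit.slope),
        slope_se=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        pearson_r=float(fit.rvalue),
        mean_difference=float(diff.mean()),
        diff_sd=float(diff.std(ddof=1)),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


# --------------------------------------------------------------------------
# AUC and the threshold sweep
# --------------------------------------------------------------------------


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties ½."""
    s = np.asarray(scores, dtype=np.float64)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape or s.ndim != 1:
        raise ConfigurationError("scores and labels must be aligned 1-D")
    n_pos = int(lab.sum())
    n_neg = int(lab.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties as ½
    return float((ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ThresholdSweepResult:
    grid: tuple[float, ...]
    auc_at: dict[float, float | None]  # None where a class vanished
    best_threshold: float
    best_auc: float

    def as_dict(self) -> dict:
        return {
            "grid": list(self.grid),
            "auc_at": {f"{t:.1f}": a for t, a in self.auc_at.items()},
            "best_threshold": self.best_threshold,
            "best_auc": self.best_auc,
        }


def threshold_sweep(
    pred: Sequence[float],
    truth: Sequence[float],
    grid: Sequence[float] = DEFAULT_GRID,
) -> ThresholdSweepResult:
    """AUC of the continuous predictions against truth re-binarised at each t."""
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    grid = tuple(float(t) for t in grid)
    if len(grid) == 0:
        raise ConfigurationError("threshold grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError("threshold grid must be strictly increasing")
    if x.shape != y.shape:
        raise ConfigurationError("pred and truth must be aligned")
    auc_at: dict[float, float | None] = {}
    best_t, best_a = None, -np.inf
    for t in grid:
        labels = y > t
        if labels.all() or not labels.any():
            auc_at[t] = None
            continue
        a = auc(x, labels)
        auc_at[t] = a
        if a > best_a:  # strict: ties resolve to the lowest threshold
            best_t, best_a = t, a
    if best_t is None:
        raise UndefinedAUCError("every grid threshold left a single class")
    return ThresholdSweepResult(
        grid=grid, auc_at=auc_at, best_threshold=best_t, best_auc=float(best_a)
    )


# --------------------------------------------------------------------------
# confusion matrix metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


@dataclass
class ClassificationReport:
    threshold: float
    matrix: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "matrix": self.matrix.as_dict(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise ConfigurationError("precision and recall must be >= 0")
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined when precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def classification_report(
    pred: Sequence[float], truth: Sequence[float], threshold: float
) -> ClassificationReport:
    """Binarise both at the threshold and compute confusion-matrix metrics.

    A zero denominator (no predicted positives for precision, no true
    positives for recall) raises :class:`UndefinedMetricError` rather than
    returning NaN.
    """
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if x.shape != y.shape or x.size < 1:
        raise ConfigurationError("need aligned non-empty pred/truth")
    pl = x > threshold
    tl = y > threshold
    m = ConfusionMatrix(
        tp=int(np.sum(pl & tl)),
        tn=int(np.sum(~pl & ~tl)),
        fp=int(np.sum(pl & ~tl)),
        fn=int(np.sum(~pl & tl)),
    )
    if m.tp + m.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    if m.tp + m.fn == 0:
        raise UndefinedMetricError("recall undefined: no true positives")
    precision = m.tp / (m.tp + m.fp)
    recall = m.tp / (m.tp + m.fn)
    return ClassificationReport(
        threshold=float(threshold),
        matrix=m,
        accuracy=(m.tp + m.tn) / m.total,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
    )


# --------------------------------------------------------------------------
# McNemar exact test
# --------------------------------------------------------------------------


@dataclass
class McNemarResult:
    discordant_b: int  # A correct, B wrong
    discordant_c: int  # B correct, A wrong
    p_value: float

    def as_dict(self) -> dict:
        return {
            "discordant_b": self.discordant_b,
            "discordant_c": self.discordant_c,
            "p_value": self.p_value,
        }


def mcnemar_exact(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> McNemarResult:
    """Exact two-sided binomial McNemar test on paired correctness vectors."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("correctness vectors must be aligned 1-D")
    db = int(np.sum(a & ~b))
    dc = int(np.sum(~a & b))
    n = db + dc
    if n == 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(db, dc), n, 0.5)))
    return McNemarResult(discordant_b=db, discordant_c=dc, p_value=p)
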