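"""Confusion-matrix accounting, edge-corrected d-prime, and empirical nulls.

d' = z(TPR) - z(FPR), with z the standard normal quantile function. TPR and
FPR are computed with edge substitutions that keep both rates strictly inside
(0, 1) so d' is finite for every confusion matrix with at least one member
per truth class:

    TPR = 1/(TP+FN)      if TP = 0
        = (TP-1)/(TP+FN) if FN = 0
        = TP/(TP+FN)     otherwise

and symmetrically for FPR with FP/TN. (The FPR perfect-rejection branch is
conditioned on TN = 0; see the note on ``tpr_fpr``.) High workload is the
positive class throughout.

Empirical null distributions re-run the identical fold structure and feature
matrices with class labels randomly permuted (which preserves the balanced
class counts) in both the learning and test sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .learning import (
    HIGH,
    ClassifierConfig,
    FoldSpec,
    TrainedClassifier,
    make_folds,
    predict,
    train_classifier,
    zscore_apply,
    zscore_fit,
)


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class PerformanceRecord:
    accuracy: float
    d_prime: float
    fold: int
    kind: str
    direction: str = "S1->S2"
    feature_subset: str = "all"
    null_flag: bool = False
    nested_accuracy: float = float("nan")
    nested_d_prime: float = float("nan")


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Counts under the high-workload-positive convention."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == HIGH) & (y_pred == HIGH)))
    fn = int(np.sum((y_true == HIGH) & (y_pred != HIGH)))
    fp = int(np.sum((y_true != HIGH) & (y_pred == HIGH)))
    tn = int(np.sum((y_true != HIGH) & (y_pred != HIGH)))
    return ConfusionMatrix(tp, fn, fp, tn)


def _edge_rate(hits: int, misses: int) -> float:
    """Rate with edge substitution keeping the value strictly in (0, 1)."""
    total = hits + misses
    if hits == 0:
        return 1.0 / total
    if misses == 0:
        return (hits - 1.0) / total
    return hits / total


def tpr_fpr(cm: ConfusionMatrix) -> tuple[float, float]:
    """(TPR, FPR) with the edge substitutions, each strictly inside (0, 1).

    Note: the published piecewise definition of FPR labels its
    perfect-detection branch with the condition FN = 0, but that condition
    belongs to the TPR expression; the substitution is only reachable (and
    only needed) when TN = 0, which is what this implementation uses.
    """
    if cm.tp + cm.fn < 1 or cm.fp + cm.tn < 1:
        raise ValueError("each truth class must contain at least one epoch")
    return _edge_rate(cm.tp, cm.fn), _edge_rate(cm.fp, cm.tn)


def d_prime(cm: ConfusionMatrix) -> float:
    """Edge-corrected sensitivity z(TPR) - z(FPR); finite for all legal input."""
    tpr, fpr = tpr_fpr(cm)
    return float(stats.norm.ppf(tpr) - stats.norm.ppf(fpr))


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.n


def balanced_permutation(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random label assignment preserving the (balanced) class counts."""
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) != 2 or counts[0] != counts[1]:
        raise ValueError("labels must be balanced for the null permutation")
    return rng.permutation(y)


def evaluate_fold(
    x_learn_raw: np.ndarray,
    y_learn: np.ndarray,
    x_test_raw: np.ndarray,
    y_test: np.ndarray,
    kind: str,
    fold: int,
    seed: int,
    config: ClassifierConfig | None = None,
    nested: tuple[np.ndarray, np.ndarray] | None = None,
    fitted_on: str = "S1",
    return_classifier: bool = False,
    **record_kwargs,
) -> PerformanceRecord | tuple[PerformanceRecord, TrainedClassifier]:
    """Train one classifier on the learning subset and score the test set.

    Normalization is fitted on the learning subset only and applied to every
    other matrix, so neither nested-test nor between-session data influences
    the statistics (no leakage).
    """
    norm = zscore_fit(x_learn_raw, fitted_on=fitted_on)
    clf = train_classifier(
        kind, zscore_apply(norm, x_learn_raw), y_learn, config, seed, normalization=norm
    )
    cm = confusion(y_test, predict(clf, zscore_apply(norm, x_test_raw)))
    rec = PerformanceRecord(
        accuracy=accuracy(cm), d_prime=d_prime(cm), fold=fold, kind=kind, **record_kwargs
    )
    if nested is not None:
        x_nest, y_nest = nested
        cm_n = confusion(y_nest, predict(clf, zscore_apply(norm, x_nest)))
        rec.nested_accuracy = accuracy(cm_n)
        rec.nested_d_prime = d_prime(cm_n)
    if return_classifier:
        return rec, clf
    return rec


def run_kfold(
    x_learn_session: np.ndarray,
    y_learn_session: np.ndarray,
    x_test_session: np.ndarray,
    y_test_session: np.ndarray,
    spec: FoldSpec,
    kind: str,
    seed: int,
    config: ClassifierConfig | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    **record_kwargs,
) -> list[PerformanceRecord]:
    """The k-fold transfer procedure: per fold, train on a balanced 90%
    subsample of the learning session, score nested test (the complement) and
    the full between-session test set."""
    if folds is None:
        folds = make_folds(y_learn_session, spec)
    seeds = _child_seeds(seed, len(folds))
    records = []
    for i, (learn, nest) in enumerate(folds):
        records.append(
            evaluate_fold(
                x_learn_session[learn],
                y_learn_session[learn],
                x_test_session,
                y_test_session,
                kind,
                fold=i,
                seed=seeds[i],
                config=config,
                nested=(x_learn_session[nest], y_learn_session[nest]),
                **record_kwargs,
            )
        )
    return records


def empirical_null(
    x_learn_session: np.ndarray,
    y_learn_session: np.ndarray,
    x_test_session: np.ndarray,
    y_test_session: np.ndarray,
    spec: FoldSpec,
    kind: str,
    seed: int,
    config: ClassifierConfig | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    **record_kwargs,
) -> list[PerformanceRecord]:
    """Empirical null: identical fold indices and feature matrices as the
    matched accuracy k-fold, with labels randomly permuted (balance preserved)
    in both the learning and test sets."""
    if folds is None:
        folds = make_folds(y_learn_session, spec)
    rng = np.random.default_rng(seed)
    y_learn_null = balanced_permutation(y_learn_session, rng)
    y_test_null = balanced_permutation(y_test_session, rng)
    seeds = _child_seeds(seed, len(folds))
    records = []
    for i, (learn, _nest) in enumerate(folds):
        records.append(
            evaluate_fold(
                x_learn_session[learn],
                y_learn_null[learn],
                x_test_session,
                y_test_null,
                kind,
                fold=i,
                seed=seeds[i],
                config=config,
                null_flag=True,
                **record_kwargs,
            )
        )
    return records


def median_over_folds(records: list[PerformanceRecord]) -> dict[str, float]:
    """Median accuracy and d' across the folds of one group."""
    if not records:
        raise ValueError("no records to summarize")
    return {
        "accuracy": float(np.median([r.accuracy for r in records])),
        "d_prime": float(np.median([r.d_prime for r in records])),
    }


def compare_to_null(
    true_medians: np.ndarray,
    null_medians: np.ndarray,
    alpha: float = 0.01,
    m_comparisons: int = 1,
) -> dict[str, float | bool]:
    """Two-tailed paired t-test of per-subject medians against their matched
    nulls, with a Bonferroni-adjusted threshold alpha/m."""
    a = np.asarray(true_medians, dtype=float)
    b = np.asarray(null_medians, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return {"t": 0.0, "p": 1.0, "significant": False, "alpha_adjusted": alpha / m_comparisons}
        # zero variance, nonzero shift: infinitely strong evidence
        return {
            "t": float(np.inf) * np.sign(diff.mean()),
            "p": 0.0,
            "significant": True,
            "alpha_adjusted": alpha / m_comparisons,
        }
    t, p = stats.ttest_rel(a, b)
    adj = alpha / m_comparisons
    return {"t": float(t), "p": float(p), "significant": bool(p < adj), "alpha_adjusted": adj}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]
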