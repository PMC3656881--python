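"""Performance measures and the nested model-selection protocol.

Per-domain predictive performance is summarized by sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), and the areas
under the ROC and precision-recall curves.  Undefined ratios (empty
denominator) are reported as ``None``, never coerced to 0.

Model selection follows a nested scheme: an outer stratified 5-fold
cross-validation repeated 5 times (or, alternatively, ten 75/25 random
splits); on each outer training set the (degree, C) pair maximizing the
inner 10-fold cross-validated AUC ROC is recorded, the modal pair across
outer folds becomes the final configuration, and the outer held-out folds
measure its performance.  Ties in the vote break toward the simpler
model: smaller degree, then smaller C.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .svm import COST_GRID_DEFAULT, DEGREE_GRID_DEFAULT, SVMConfig, train


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None


def confusion(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0) -> ConfusionCounts:
    """2x2 confusion counts predicting binding where ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _check_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the normalized Mann-Whitney U
    statistic (ties counted half)."""
    labels = np.asarray(labels)
    _check_both_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_pr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise interpolation
    (average precision over the threshold sweep)."""
    labels = np.asarray(labels)
    _check_both_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def threshold_at_specificity(
    scores: Sequence[float], labels: Sequence[int], target_specificity: float
) -> Tuple[float, Optional[float]]:
    """Smallest decision threshold achieving at least the target specificity.

    Used for matched-specificity comparisons against a fixed-threshold
    baseline: pick the threshold where our specificity meets the
    comparator's, then report sensitivity there.  Returns
    ``(threshold, sensitivity_at_threshold)``.
    """
    if not 0.0 <= target_specificity <= 1.0:
        raise ValueError(f"target specificity must lie in [0, 1], got {target_specificity}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.any(labels == -1):
        raise ValueError("threshold calibration requires negative instances")
    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    for t in candidates:  # ascending: first hit is the smallest threshold
        cm = confusion(scores, labels, t)
        if cm.specificity is not None and cm.specificity >= target_specificity:
            return float(t), cm.sensitivity
    raise ValueError("unattainable target specificity")  # pragma: no cover


@dataclass(frozen=True)
class SelectionProtocol:
    """Outer/inner cross-validation layout for hyper-parameter selection."""

    outer: str = "stratified_5fold_x5"  # or "random_split_75_25_x10"
    n_outer_folds: int = 5
    n_repeats: int = 5
    n_inner_folds: int = 10
    seed: int = 0


@dataclass
class EvalReport:
    """Fold-wise performance, aggregated as mean and standard deviation."""

    per_fold: List[Dict[str, Optional[float]]] = field(default_factory=list)
    confusions: List[ConfusionCounts] = field(default_factory=list)

    def _collect(self, key: str) -> List[float]:
        return [f[key] for f in self.per_fold if f.get(key) is not None]

    def mean(self, key: str) -> Optional[float]:
        vals = self._collect(key)
        return float(np.mean(vals)) if vals else None

    def sd(self, key: str) -> Optional[float]:
        vals = self._collect(key)
        return float(np.std(vals)) if vals else None

    def summary(self) -> Dict[str, Optional[float]]:
        keys = ("sensitivity", "specificity", "precision", "auc_roc", "auc_pr")
        out: Dict[str, Optional[float]] = {}
        for k in keys:
            out[k] = self.mean(k)
            out[k + "_sd"] = self.sd(k)
        return out


def _fold_metrics(scores: np.ndarray, labels: np.ndarray) -> Dict[str, Optional[float]]:
    cm = confusion(scores, labels)
    both = len(np.unique(labels)) == 2
    return {
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "precision": cm.precision,
        "auc_roc": auc_roc(scores, labels) if both else None,
        "auc_pr": auc_pr(scores, labels) if both else None,
    }


def _safe_folds(requested: int, y: np.ndarray) -> int:
    """Reduce the fold count when a class has fewer members than folds."""
    smallest = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    n = min(requested, smallest)
    if n < requested:
        import warnings

        warnings.warn(f"reducing folds from {requested} to {n} (minority class size)", stacklevel=3)
    return max(n, 2)


def inner_cv_auc(
    X: np.ndarray, y: np.ndarray, config: SVMConfig, n_folds: int, seed: int
) -> float:
    """Inner cross-validated AUC ROC of one hyper-parameter configuration."""
    skf = StratifiedKFold(n_splits=_safe_folds(n_folds, y), shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        model = train(X[tr][y[tr] == 1], X[tr][y[tr] == -1], config, seed=seed)
        scores[te] = model.decision_values(X[te])
    return auc_roc(scores, y)


def _grid(degrees: Sequence[int], costs: Sequence[float], coef0: float) -> List[SVMConfig]:
    return [SVMConfig(d, C, coef0) for d in degrees for C in costs]


def select_model(
    X: np.ndarray,
    y: np.ndarray,
    degrees: Sequence[int] = DEGREE_GRID_DEFAULT,
    costs: Sequence[float] = COST_GRID_DEFAULT,
    protocol: SelectionProtocol = SelectionProtocol(),
    coef0: float = 1.0,
) -> Tuple[SVMConfig, EvalReport, List[SVMConfig]]:
    """Nested model selection: modal inner-CV winner, outer performance.

    Returns ``(modal_config, outer_report, per_fold_winners)``.  The modal
    (degree, C) pair is the most frequent inner-CV winner across all outer
    training sets; ties break toward smaller degree, then smaller C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = _grid(degrees, costs, coef0)

    outer_splits: List[Tuple[np.ndarray, np.ndarray]] = []
    if protocol.outer == "stratified_5fold_x5":
        for rep in range(protocol.n_repeats):
            skf = StratifiedKFold(
                n_splits=_safe_folds(protocol.n_outer_folds, y),
                shuffle=True,
                random_state=protocol.seed + rep,
            )
            outer_splits.extend(skf.split(X, y))
    elif protocol.outer == "random_split_75_25_x10":
        sss = StratifiedShuffleSplit(
            n_splits=protocol.n_repeats, test_size=0.25, random_state=protocol.seed
        )
        outer_splits.extend(sss.split(X, y))
    else:
        raise ValueError(f"unknown outer protocol {protocol.outer!r}")

    winners: List[SVMConfig] = []
    for tr, _ in outer_splits:
        best: Optional[Tuple[float, SVMConfig]] = None
        for cfg in grid:
            a = inner_cv_auc(X[tr], y[tr], cfg, protocol.n_inner_folds, protocol.seed)
            # strict > keeps the earliest (simplest, by grid order) on ties
            if best is None or a > best[0]:
                best = (a, cfg)
        winners.append(best[1])

    counts = Counter(winners)
    top = max(counts.values())
    modal = min(
        (c for c, n in counts.items() if n == top), key=lambda c: (c.degree, c.C)
    )

    report = EvalReport()
    for tr, te in outer_splits:
        model = train(X[tr][y[tr] == 1], X[tr][y[tr] == -1], modal, seed=protocol.seed)
        s = model.decision_values(X[te])
        report.per_fold.append(_fold_metrics(s, y[te]))
        report.confusions.append(confusion(s, y[te]))
    return modal, report, winners


def cross_validated_auc(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Plain stratified k-fold AUC ROC of a fixed configuration."""
    return inner_cv_auc(np.asarray(X, float), np.asarray(y), config, n_folds, seed)
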