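"""Classification metrics, ROC/PR curves and the cross-validation harness.

Point metrics follow the standard confusion-table formulas:

    SN (recall/TPR) = TP / (TP + FN)          FPR = FP / (FP + TN)
    SP              = TN / (TN + FP)          ACC = (TP + TN) / total
    Precision       = TP / (TP + FP)          F1  = 2 P R / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

with the convention that a zero denominator yields 0 for that measure and
the measure's name is flagged on the result. Curves are computed at every
distinct score threshold; areas by the trapezoid rule, which for the ROC
curve coincides with the tie-corrected concordant-pair (Mann-Whitney)
statistic.

Classifiers are pluggable through :class:`ClassifierSpec`; the three
stock families (random forest, support-vector machine with probability
outputs, feed-forward network) use scikit-learn with library defaults and
a fixed seed. Cross-validation is stratified so that every fold carries
both classes, and the fold assignment depends only on (labels, k, seed) —
never on the classifier — so families are compared on identical splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import CHANNELS, FeatureVector, feature_table

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "Curve",
    "ClassifierSpec",
    "CrossValResult",
    "compute_metrics",
    "confusion_from_predictions",
    "roc_curve_points",
    "pr_curve_points",
    "make_classifier",
    "crossvalidate",
    "balance_experiment",
]

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    fpr: float
    sp: float
    acc: float
    mcc: float
    precision: float
    f1: float
    flagged: tuple[str, ...] = ()  # measures whose denominator was zero

    def as_dict(self) -> dict[str, float]:
        return {
            "SN": self.sn,
            "FPR": self.fpr,
            "SP": self.sp,
            "ACC": self.acc,
            "MCC": self.mcc,
            "Precision": self.precision,
            "F1": self.f1,
        }


def _ratio(num: float, den: float, name: str, flagged: list[str]) -> float:
    if den == 0:
        flagged.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """All seven point measures from one confusion table."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flagged: list[str] = []
    sn = _ratio(tp, tp + fn, "SN", flagged)
    fpr = _ratio(fp, fp + tn, "FPR", flagged)
    sp = _ratio(tn, tn + fp, "SP", flagged)
    acc = (tp + tn) / counts.total
    mcc_den = math.sqrt((tn + fn) * (tn + fp) * (tp + fn) * (tp + fp))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC", flagged)
    precision = _ratio(tp, tp + fp, "Precision", flagged)
    f1 = _ratio(2 * precision * sn, precision + sn, "F1", flagged)
    return MetricSet(sn, fpr, sp, acc, mcc, precision, f1, tuple(flagged))


def confusion_from_predictions(
    labels: Sequence[str], predicted_positive: Sequence[bool]
) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for lab, pred in zip(labels, predicted_positive, strict=True):
        if lab == POSITIVE:
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True, eq=False)
class Curve:
    """An ROC or PR curve: ordered points plus the trapezoid area."""

    x: np.ndarray
    y: np.ndarray
    area: float


def _threshold_counts(scores: Sequence[float], labels: Sequence[str]):
    """Cumulative TP/FP at each distinct score threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in labels])
    if len(scores) != len(y):
        raise ValueError("scores and labels differ in length")
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    distinct = np.where(np.diff(scores))[0]
    idx = np.r_[distinct, len(scores) - 1]  # last index of each score group
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    return tps, fps, int(y.sum()), int(len(y) - y.sum())


def roc_curve_points(scores: Sequence[float], labels: Sequence[str]) -> Curve:
    """ROC curve over all distinct thresholds, anchored at (0,0) and (1,1)."""
    tps, fps, n_pos, n_neg = _threshold_counts(scores, labels)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC curve requires both classes present")
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return Curve(fpr, tpr, area)


def pr_curve_points(scores: Sequence[float], labels: Sequence[str]) -> Curve:
    """PR curve over all distinct thresholds; area by trapezoid over recall.

    The zero-recall anchor reuses the precision of the highest-score
    threshold (the curve's leftmost measured point), the usual convention
    for a finite sample.
    """
    tps, fps, n_pos, _ = _threshold_counts(scores, labels)
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    recall = tps / n_pos
    precision = tps / (tps + fps)
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    area = float(np.trapezoid(precision, recall))
    return Curve(recall, precision, area)


@dataclass(frozen=True)
class ClassifierSpec:
    """Family label + hyperparameter overrides + seed for one model."""

    family: str = "tree-ensemble"
    params: dict = field(default_factory=dict)
    seed: int = 0

    ALIASES = {
        "rf": "tree-ensemble",
        "svm": "max-margin",
        "ann": "feed-forward",
    }

    def canonical_family(self) -> str:
        family = self.ALIASES.get(self.family, self.family)
        if family not in ("tree-ensemble", "max-margin", "feed-forward"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        return family


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec (library defaults)."""
    family = spec.canonical_family()
    if family == "tree-ensemble":
        return RandomForestClassifier(random_state=spec.seed, **spec.params)
    if family == "max-margin":
        return SVC(probability=True, random_state=spec.seed, **spec.params)
    return MLPClassifier(random_state=spec.seed, **spec.params)


@dataclass(frozen=True, eq=False)
class CrossValResult:
    metrics: MetricSet
    roc: Curve
    pr: Curve
    scores: np.ndarray  # pooled out-of-fold scores, in input order
    labels: tuple[str, ...]
    fold_assignment: np.ndarray


def _as_frame(dataset: Iterable[FeatureVector] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset
    return feature_table(dataset)


def crossvalidate(
    dataset: Iterable[FeatureVector] | pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValResult:
    """Stratified k-fold cross-validation with pooled out-of-fold scores.

    Point metrics cut the pooled scores at ``threshold``. The fold
    assignment is a pure function of (labels, k, seed), so different
    classifier specs evaluated with the same seed see identical splits.
    """
    frame = _as_frame(dataset)
    feature_cols = [f"q_{c}" for c in CHANNELS]
    X = frame[feature_cols].to_numpy(dtype=float)
    labels = tuple(frame["label"])
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in labels])
    if k < 2:
        raise ValueError("k must be >= 2")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() == 0:
        raise ValueError("both classes must be present")
    if class_counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds: minority class has only "
            f"{class_counts.min()} sample(s); reduce k or resample"
        )

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    fold_assignment = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        model = make_classifier(spec)
        model.fit(X[train], y[train])
        proba = model.predict_proba(X[test])
        positive_col = int(np.where(model.classes_ == 1)[0][0])
        scores[test] = proba[:, positive_col]
        fold_assignment[test] = fold

    counts = confusion_from_predictions(labels, scores >= threshold)
    metrics = compute_metrics(counts)
    roc = roc_curve_points(scores, labels)
    pr = pr_curve_points(scores, labels)
    return CrossValResult(metrics, roc, pr, scores, labels, fold_assignment)


def balance_experiment(
    positives: Iterable[FeatureVector] | pd.DataFrame,
    negatives: Iterable[FeatureVector] | pd.DataFrame,
    mode: str = "all",
    spec: ClassifierSpec = ClassifierSpec(),
    n_repeats: int = 5,
    k: int = 10,
    seed: int = 0,
) -> list[CrossValResult]:
    """Cross-validate under three negative-to-positive sampling regimes.

    ``mode='all'`` uses every negative once; ``'balanced-1x'`` (alias
    ``'1x'``) draws as many negatives as positives; ``'imbalanced-2x'``
    (alias ``'2x'``) draws twice as many, each repeated ``n_repeats``
    times with independent draws without replacement.
    """
    pos = _as_frame(positives).reset_index(drop=True)
    neg = _as_frame(negatives).reset_index(drop=True)
    mode = {"1x": "balanced-1x", "2x": "imbalanced-2x"}.get(mode, mode)
    if mode == "all":
        data = pd.concat([pos, neg], ignore_index=True)
        return [crossvalidate(data, spec, k=k, seed=seed)]
    if mode == "balanced-1x":
        n_draw = len(pos)
    elif mode == "imbalanced-2x":
        n_draw = 2 * len(pos)
    else:
        raise ValueError(f"unknown balance mode {mode!r}")
    if len(neg) < n_draw:
        raise ValueError(
            f"balance mode {mode!r} needs {n_draw} negatives, only {len(neg)} available"
        )
    rng = np.random.default_rng(seed)
    results = []
    for repeat in range(n_repeats):
        chosen = rng.choice(len(neg), size=n_draw, replace=False)
        data = pd.concat([pos, neg.iloc[np.sort(chosen)]], ignore_index=True)
        results.append(crossvalidate(data, spec, k=k, seed=seed + repeat))
    return results
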