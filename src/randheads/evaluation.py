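"""Confusion-matrix metrics, k-fold cross-validation and fold aggregation.

Conventions: the unhealthy class is the positive (label 1); all metrics
are percentages kept at full precision internally and rounded half-up to
two decimals only for display; fold aggregation uses the arithmetic mean
and the POPULATION standard deviation (divisor k, not k-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureExtractor, FineTuneConfig, LabeledImageSet, extract_features, fine_tune
from .heads import TargetMatrix, make_hidden_layer, predict, train_elm, train_rvfl, train_snn

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldAssignment",
    "AggregateReport",
    "confusion",
    "metrics",
    "harmonic_f1",
    "kfold_split",
    "aggregate",
    "roc_auc",
    "cross_validate_features",
    "run_cv_pipeline",
    "round2",
    "METRIC_NAMES",
    "HEAD_TRAINERS",
]

METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1")

HEAD_TRAINERS = {"snn": train_snn, "elm": train_elm, "rvfl": train_rvfl}


def round2(x: float) -> float:
    """Round to 2 decimals, half-up (display convention)."""
    if not np.isfinite(x):
        return float(x)
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion counts must sum to at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Five classification metrics as percentages in [0, 100].

    A metric whose denominator is zero is NaN and listed in ``undefined``.
    """

    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    undefined: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            v = float(getattr(self, name))
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "undefined", frozenset(self.undefined))

    def as_dict(self, rounded: bool = False) -> dict:
        f = round2 if rounded else float
        return {name: f(getattr(self, name)) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldAssignment:
    """k disjoint index lists partitioning 0..N-1 with sizes differing by <= 1."""

    folds: tuple

    def __post_init__(self) -> None:
        folds = tuple(np.asarray(f, dtype=int) for f in self.folds)
        sizes = [f.size for f in folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")
        all_idx = np.concatenate(folds)
        n = all_idx.size
        if not np.array_equal(np.sort(all_idx), np.arange(n)):
            raise ValueError("folds must partition 0..N-1")
        object.__setattr__(self, "folds", folds)

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for fold i."""
        test = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return train, test


@dataclass(frozen=True)
class AggregateReport:
    """Per-metric mean and population standard deviation across folds."""

    means: dict
    stds: dict
    k: int

    def as_dict(self, rounded: bool = False) -> dict:
        f = round2 if rounded else float
        return {name: {"mean": f(self.means[name]), "std": f(self.stds[name])}
                for name in METRIC_NAMES}


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/FN/FP/TN with class 1 (unhealthy) as the positive."""
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if t.size < 1:
        raise ValueError("empty label vectors")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: set) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        undefined.add(name)
        return float("nan")
    return 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    und: set = set()
    return MetricsReport(
        acc=_ratio(c.tp + c.tn, c.total, "acc", und),
        sen=_ratio(c.tp, c.tp + c.fn, "sen", und),
        spe=_ratio(c.tn, c.tn + c.fp, "spe", und),
        pre=_ratio(c.tp, c.tp + c.fp, "pre", und),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1", und),
        undefined=frozenset(und),
    )


def harmonic_f1(pre: float, sen: float) -> float:
    """F1 as the harmonic mean of precision and sensitivity (same units in/out)."""
    if pre + sen == 0:
        raise ValueError("precision + sensitivity is zero")
    return 2.0 * pre * sen / (pre + sen)


def kfold_split(labels: Sequence[int], k: int, seed: int,
                stratified: bool = True) -> FoldAssignment:
    """Seeded shuffle-and-partition into k near-equal folds.

    Stratified (default) keeps each fold's class ratio within one sample
    of the overall ratio.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > y.size:
        raise ValueError(f"k={k} exceeds the number of samples N={y.size}")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(test for _, test in splitter.split(np.zeros((y.size, 1)), y))
    return FoldAssignment(folds=folds)


def aggregate(fold_reports: Sequence[MetricsReport]) -> AggregateReport:
    """Mean and population standard deviation of each metric across folds.

    Folds where a metric is undefined are excluded from that metric's
    aggregate (with a warning); if no fold defines it, the aggregate is NaN.
    """
    if len(fold_reports) < 1:
        raise ValueError("need at least one fold report")
    means, stds = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in fold_reports], dtype=float)
        ok = np.isfinite(vals)
        if not ok.all():
            warnings.warn(f"{name} undefined in {int((~ok).sum())} fold(s); "
                          "aggregating over the remaining folds", RuntimeWarning)
        if ok.any():
            means[name] = float(vals[ok].mean())
            stds[name] = float(vals[ok].std(ddof=0))
        else:
            means[name] = float("nan")
            stds[name] = float("nan")
    return AggregateReport(means=means, stds=stds, k=len(fold_reports))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _zscore(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def cross_validate_features(
    X: np.ndarray,
    labels: Sequence[int],
    head_kind: str,
    k: int = 5,
    seed: int = 0,
    V: int = 400,
    ridge: float = 0.0,
    zscore: bool = False,
    stratified: bool = True,
) -> tuple[list[MetricsReport], AggregateReport]:
    """k-fold cross-validation of one closed-form head on a fixed feature matrix."""
    if head_kind not in HEAD_TRAINERS:
        raise ValueError(f"unknown head kind {head_kind!r}; choose from {sorted(HEAD_TRAINERS)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    trainer = HEAD_TRAINERS[head_kind]
    assignment = kfold_split(y, k, seed, stratified=stratified)
    reports = []
    for i in range(assignment.k):
        tr, te = assignment.split(i)
        Xtr, Xte = X[tr], X[te]
        if zscore:
            Xtr, Xte = _zscore(Xtr, Xte)
        layer = make_hidden_layer(X.shape[1], V, seed=seed + i)
        model = trainer(Xtr, TargetMatrix.from_labels(y[tr], m=2), layer, ridge=ridge)
        _, pred = predict(model, Xte)
        reports.append(metrics(confusion(y[te], pred)))
    return reports, aggregate(reports)


def run_cv_pipeline(
    data: LabeledImageSet,
    cfg: FineTuneConfig,
    head_kind: str,
    k: int = 5,
    stratified: bool = True,
    return_features: bool = False,
):
    """Full image pipeline under k-fold cross-validation.

    Per fold: fine-tune the extractor on the training images, extract
    FC128 features, fit the requested closed-form head on the training
    features, and score the held-out fold.  Returns the per-fold
    :class:`MetricsReport` list and the :class:`AggregateReport`
    (plus the per-fold feature matrices when ``return_features``).
    """
    if head_kind not in HEAD_TRAINERS:
        raise ValueError(f"unknown head kind {head_kind!r}; choose from {sorted(HEAD_TRAINERS)}")
    trainer = HEAD_TRAINERS[head_kind]
    y = data.labels
    assignment = kfold_split(y, k, cfg.seed, stratified=stratified)
    reports, fold_features = [], []
    for i in range(assignment.k):
        tr, te = assignment.split(i)
        train_set, test_set = data.subset(tr), data.subset(te)
        extractor = fine_tune(None, train_set, cfg)
        Ftr = extract_features(extractor, train_set)
        Fte = extract_features(extractor, test_set)
        layer = make_hidden_layer(Ftr.shape[1], cfg.hidden_nodes_V, seed=cfg.seed + i)
        model = trainer(Ftr, TargetMatrix.from_labels(train_set.labels, m=2), layer)
        _, pred = predict(model, Fte)
        reports.append(metrics(confusion(test_set.labels, pred)))
        if return_features:
            fold_features.append((Ftr, Fte))
    agg = aggregate(reports)
    if return_features:
        return reports, agg, fold_features
    return reports, agg
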