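"""In silico rare-cell mixture evaluation.

Classifier performance on a balanced validation cohort is reweighted to the
class proportions of a realistic sample: for a target proportion ``pi`` the
precision at threshold ``t`` is

    precision(t) = pi * TPR(t) / (pi * TPR(t) + (1 - pi) * FPR(t))

with recall(t) = TPR(t).  This is exact for i.i.d. mixtures and avoids having
to physically subsample 1:100,000 mixtures (which would need >= 10^7 cells);
an explicit-mixture construction is provided for cross-validation.

Quality classes (debris, out-of-focus) are removed from validation cohorts
before any performance statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .synth import DEFAULT_QUALITY_CLASSES, CellRecord

__all__ = [
    "ROCCurve",
    "PRCurve",
    "ConfusionMatrix",
    "OperatingPoint",
    "filter_evaluable",
    "selection_scores",
    "roc_curve",
    "mixture_pr_curve",
    "empirical_mixture_pr_curve",
    "confusion",
    "operating_point",
]


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep: a cell is called positive when its score >= threshold.

    Thresholds are descending; tied scores move between thresholds as a
    block.  Endpoints (0,0) (threshold +inf) and (1,1) (lowest score) are
    always present.  ``auc`` is the trapezoidal integral of TPR over FPR.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        for name in ("thresholds", "tpr", "fpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall curve at mixture proportion ``mixture_pi``."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    mixture_pi: float

    def __post_init__(self) -> None:
        for name in ("thresholds", "precision", "recall"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))


@dataclass(frozen=True)
class ConfusionMatrix:
    class_names: tuple[str, ...]
    counts: np.ndarray  # rows = ground truth, columns = argmax prediction

    @property
    def fractions(self) -> np.ndarray:
        """Row-normalised fractions; rows with no cells are all-NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)


@dataclass(frozen=True)
class OperatingPoint:
    """A chosen threshold with its precision/recall/FPR.

    ``attainable`` is False when no threshold reaches the requested
    precision; the numeric fields are then NaN.
    """

    threshold: float
    precision: float
    recall: float
    fpr: float
    attainable: bool = True

    @classmethod
    def unattainable(cls) -> "OperatingPoint":
        return cls(np.nan, np.nan, np.nan, np.nan, attainable=False)


def filter_evaluable(
    records: Sequence[CellRecord],
    quality_classes: Iterable[str] = DEFAULT_QUALITY_CLASSES,
) -> list[CellRecord]:
    """Drop cells whose ground-truth label is an image-quality class.

    Order is preserved and the input is untouched.  ``quality_classes`` must
    be a subset of the records' known class names (checked when records are
    present).
    """
    quality = set(quality_classes)
    records = list(records)
    if records:
        known = set(records[0].class_names)
        unknown = quality - known
        if unknown:
            raise KeyError(f"quality classes not among known classes: {sorted(unknown)}")
    return [r for r in records if r.true_label not in quality]


def selection_scores(
    records: Sequence[CellRecord],
    mode: str,
    target_class: str,
    background_classes: Iterable[str],
) -> np.ndarray:
    """Per-cell sorting score; higher always means "more likely sorted".

    positive mode: the target class softmax score.
    negative mode: 1 minus the largest background-class score.
    """
    background = set(background_classes)
    if target_class in background:
        raise ValueError(
            f"target class {target_class!r} overlaps the background set"
        )
    if mode not in ("positive", "negative"):
        raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")
    if not records:
        return np.empty(0)
    names = records[0].class_names
    for c in {target_class} | background:
        if c not in names:
            raise KeyError(f"unknown class {c!r}")
    scores = np.stack([r.scores for r in records])
    if mode == "positive":
        return scores[:, names.index(target_class)]
    bg_idx = [names.index(c) for c in sorted(background)]
    return 1.0 - scores[:, bg_idx].max(axis=1)


def roc_curve(
    target_scores: np.ndarray, background_scores: np.ndarray
) -> ROCCurve:
    """ROC over every distinct score threshold, ties grouped.

    AUC by the trapezoid rule, which on this tie-grouped curve equals the
    Mann-Whitney pair-ordering statistic (ties counted 1/2).
    """
    t = np.asarray(target_scores, float)
    b = np.asarray(background_scores, float)
    if t.size == 0 or b.size == 0:
        raise ValueError("both target and background scores must be non-empty")
    thresholds = np.unique(np.concatenate([t, b]))[::-1]
    # cells with score >= threshold are called positive
    tp = t.size - np.searchsorted(np.sort(t), thresholds, side="left")
    fp = b.size - np.searchsorted(np.sort(b), thresholds, side="left")
    tpr = np.concatenate([[0.0], tp / t.size])
    fpr = np.concatenate([[0.0], fp / b.size])
    thresholds = np.concatenate([[np.inf], thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def mixture_pr_curve(roc: ROCCurve, pi: float) -> PRCurve:
    """Reweight an ROC curve to a mixture with target proportion ``pi``.

    Where TPR = FPR = 0 (nothing called positive) precision is defined as 1.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must lie strictly between 0 and 1")
    num = pi * roc.tpr
    den = num + (1.0 - pi) * roc.fpr
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return PRCurve(
        thresholds=roc.thresholds,
        precision=precision,
        recall=roc.tpr.copy(),
        mixture_pi=pi,
    )


def empirical_mixture_pr_curve(
    target_scores: np.ndarray,
    background_scores: np.ndarray,
    pi: float,
    n: int,
    seed: int,
) -> PRCurve:
    """PR curve of an explicitly constructed mixture (cross-validation oracle).

    Resamples ``round(n*pi)`` target and ``n - round(n*pi)`` background cells
    with replacement and computes precision/recall by direct counting.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_t = int(round(n * pi))
    if n_t == 0 or n_t == n:
        raise ValueError("n * pi must resolve to at least one cell of each kind")
    t = rng.choice(np.asarray(target_scores, float), size=n_t, replace=True)
    b = rng.choice(np.asarray(background_scores, float), size=n - n_t, replace=True)
    roc = roc_curve(t, b)
    tp = roc.tpr * n_t
    fp = roc.fpr * (n - n_t)
    called = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(called > 0, tp / np.where(called > 0, called, 1.0), 1.0)
    return PRCurve(
        thresholds=roc.thresholds,
        precision=precision,
        recall=roc.tpr,
        mixture_pi=pi,
    )


def confusion(
    records: Sequence[CellRecord],
    quality_classes: Iterable[str] = DEFAULT_QUALITY_CLASSES,
) -> ConfusionMatrix:
    """Argmax-prediction confusion matrix after quality filtering.

    Rows are ground truth, columns the argmax prediction; argmax ties break
    deterministically by class-name sort order.
    """
    kept = filter_evaluable(records, quality_classes)
    if not kept:
        raise ValueError("no evaluable records remain after quality filtering")
    names = kept[0].class_names
    idx = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for r in kept:
        counts[idx[r.true_label], idx[r.predicted_label]] += 1
    return ConfusionMatrix(class_names=names, counts=counts)


def operating_point(pr: PRCurve, min_precision: float) -> OperatingPoint:
    """Maximal-recall threshold whose precision meets ``min_precision``."""
    if not (0.0 < min_precision <= 1.0):
        raise ValueError("min_precision must lie in (0, 1]")
    prec = np.asarray(pr.precision, float)
    rec = np.asarray(pr.recall, float)
    if prec.shape != rec.shape or prec.size == 0:
        raise ValueError("malformed PR curve")
    ok = prec >= min_precision
    if not ok.any():
        return OperatingPoint.unattainable()
    i = int(np.flatnonzero(ok)[np.argmax(rec[ok])])
    denom = pr.mixture_pi * rec[i]
    # back out FPR from the reweighting identity
    if prec[i] > 0 and rec[i] > 0:
        fpr = denom * (1.0 / prec[i] - 1.0) / (1.0 - pr.mixture_pi)
    else:
        fpr = 0.0
    return OperatingPoint(
        threshold=float(pr.thresholds[i]),
        precision=float(prec[i]),
        recall=float(rec[i]),
        fpr=float(fpr),
    )
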