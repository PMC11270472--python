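"""Evaluation statistics: Dice, confusion-matrix metrics, Pearson correlation,
Bland–Altman limits of agreement, and k-fold cross-validation summaries.

These are the statistics used to judge both stages of the pipeline: overlap
(DSC) for the segmenter, precision/recall/F1 for the slice classifier, and
agreement statistics (Pearson r with R², Bland–Altman mean difference with
95% limits ``mean ± 1.96·SD``) between label-derived and predicted EATv/EATd
across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .image_io import BinaryMask


class EvaluateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dice similarity coefficient
# ---------------------------------------------------------------------------

def dice(a, b, both_empty: float | None = 1.0) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Accepts :class:`BinaryMask` or raw 0/1 arrays of the same shape.  When
    both masks are empty the score is ``both_empty`` (default 1.0: perfect
    agreement on absence); pass ``both_empty=None`` to get nan instead.
    """
    ga = a.grid if isinstance(a, BinaryMask) else np.asarray(a)
    gb = b.grid if isinstance(b, BinaryMask) else np.asarray(b)
    if ga.shape != gb.shape:
        raise EvaluateError(f"mask shapes differ: {ga.shape} vs {gb.shape}")
    ga = ga.astype(bool)
    gb = gb.astype(bool)
    denom = int(ga.sum()) + int(gb.sum())
    if denom == 0:
        return float("nan") if both_empty is None else float(both_empty)
    return 2.0 * int((ga & gb).sum()) / denom


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """2x2 counts indexed (actual, predicted) over classes {0, 1}."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0) or c.sum() == 0:
            raise EvaluateError("confusion matrix must be 2x2, nonnegative, nonempty")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_counts(cls, tn: int, fp: int, fn: int, tp: int) -> "ConfusionMatrix":
        """Counts with class 1 as positive: rows actual 0/1, cols predicted 0/1."""
        return cls(np.array([[tn, fp], [fn, tp]]))

    @classmethod
    def from_predictions(cls, actual: Sequence[int], predicted: Sequence[int]) -> "ConfusionMatrix":
        a = np.asarray(actual, dtype=int)
        p = np.asarray(predicted, dtype=int)
        if a.shape != p.shape:
            raise EvaluateError("actual/predicted length mismatch")
        c = np.zeros((2, 2), dtype=np.int64)
        for i in (0, 1):
            for j in (0, 1):
                c[i, j] = int(np.sum((a == i) & (p == j)))
        return cls(c)


@dataclass
class ClassificationMetrics:
    precision: float  # nan when denominator is zero
    recall: float
    f1: float
    accuracy: float
    positive_class: int


def confusion_metrics(cm: ConfusionMatrix, positive_class: int = 1) -> ClassificationMetrics:
    """One-vs-rest precision/recall/F1/accuracy for the stated positive class.

    Swapping the positive class exchanges precision and recall roles relative
    to the same matrix; undefined ratios (zero denominators) come back as nan.
    """
    if positive_class not in (0, 1):
        raise EvaluateError("positive_class must be 0 or 1")
    c = cm.counts
    pos = positive_class
    neg = 1 - pos
    tp = c[pos, pos]
    fp = c[neg, pos]
    fn = c[pos, neg]
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    accuracy = (c[0, 0] + c[1, 1]) / c.sum()
    return ClassificationMetrics(
        precision=float(precision), recall=float(recall), f1=float(f1),
        accuracy=float(accuracy), positive_class=pos,
    )


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class PearsonResult:
    r: float
    r_squared: float
    p_value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with R² and a t-transform p-value.

    Constant input has no defined correlation: nan is returned (flagged via
    ``defined``), never an arbitrary value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EvaluateError("x and y length mismatch")
    if x.size < 3:
        raise EvaluateError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(float("nan"), float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return PearsonResult(r=float(r), r_squared=float(r) ** 2, p_value=float(p))


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(labels: Sequence[float], preds: Sequence[float]) -> BlandAltman:
    """Bland–Altman agreement of predictions against labels.

    Differences are ``pred − label``; the 95% limits of agreement are
    ``mean ± 1.96 · SD`` with the sample (n−1) standard deviation.
    """
    labels = np.asarray(labels, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if labels.shape != preds.shape:
        raise EvaluateError("labels/preds length mismatch")
    if labels.size < 2:
        raise EvaluateError("need at least 2 pairs")
    d = preds - labels
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean, loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        sd_diff=sd, n=int(d.size),
    )


@dataclass
class AgreementReport:
    pearson_r: float
    r_squared: float
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


def agreement_report(labels: Sequence[float], preds: Sequence[float]) -> AgreementReport:
    """Cohort-level agreement: Pearson r/R² plus Bland–Altman limits."""
    pr = pearson_r(labels, preds)
    ba = bland_altman(labels, preds)
    return AgreementReport(
        pearson_r=pr.r, r_squared=pr.r_squared, mean_diff=ba.mean_diff,
        loa_low=ba.loa_low, loa_high=ba.loa_high, n=ba.n,
    )


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldSummary:
    fold: int
    mean: float
    sd: float
    max: float
    median: float
    n_val: int


def kfold_dsc_summary(
    dataset: Sequence,
    trainer: Callable,
    k: int = 5,
    seed: int = 0,
    groups: Sequence[int] | None = None,
) -> list[FoldSummary]:
    """k-fold cross-validated Dice summaries (mean/sd/max/median per fold).

    ``dataset`` is a sequence of ``(image, mask)`` pairs.  ``trainer`` is
    called as ``trainer(train_pairs)`` and must return a callable
    ``predict(image) -> mask``.  Folds partition the data (each item
    validates exactly once); ``groups`` switches to a grouped partition so
    items sharing a group id stay in the same fold.
    """
    n = len(dataset)
    if k > n:
        raise EvaluateError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        gfolds = np.array_split(uniq, k)
        folds = [np.nonzero(np.isin(groups, gf))[0] for gf in gfolds]
    else:
        folds = np.array_split(rng.permutation(n), k)

    summaries = []
    for f, val_idx in enumerate(folds):
        val_idx = np.sort(val_idx)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        predict = trainer([dataset[i] for i in train_idx])
        scores = np.array(
            [dice(predict(dataset[i][0]), dataset[i][1]) for i in val_idx], dtype=float
        )
        summaries.append(
            FoldSummary(
                fold=f, mean=float(scores.mean()),
                sd=float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
                max=float(scores.max()), median=float(np.median(scores)),
                n_val=int(scores.size),
            )
        )
    return summaries
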