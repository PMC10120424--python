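"""Precision-recall / ROC curves, F-beta threshold calibration, and
score/feature correlation utilities for heavily imbalanced classification.

Conventions (recorded in every CurveResult):

* a variant is called positive when ``score >= cutoff`` (inclusive);
* curves are evaluated at every unique score plus the sentinels 0 and 1;
* AUPRC uses the step-function (non-interpolated) convention — the standard
  for imbalanced-data reporting, where linear PR interpolation is known to
  flatter classifiers; AUROC uses the trapezoid rule, which on unique
  thresholds equals the Mann-Whitney pairwise-comparison statistic;
* precision at zero predicted positives is reported as 0 and flagged,
  not NaN;
* reported percentages are rounded half-up.

Under extreme imbalance AUPRC is the headline metric: a score can reach
AUROC > 0.9 while flagging tens of thousands of false positives per true
positive, which the PR curve exposes and the ROC curve hides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "Confusion",
    "CurveResult",
    "ThresholdBands",
    "confusion_at",
    "curve",
    "pr_curve",
    "roc_curve",
    "f_beta_curve",
    "optimal_threshold",
    "classify",
    "correlate",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (so 92.5% prints as 93%)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Confusion:
    """Confusion counts and derived rates at one cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    precision: float
    fp_rate: float
    precision_defined: bool


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0:
        raise ValueError("no positive labels: recall is undefined")
    return scores, labels


def confusion_at(scores, labels, cutoff: float) -> Confusion:
    """Confusion table with the inclusive rule ``score >= cutoff`` -> positive."""
    scores, labels = _check_labels(scores, labels)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    recall = tp / (tp + fn)
    fp_rate = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    return Confusion(tp, fp, tn, fn, recall, precision, fp_rate, defined)


@dataclass(frozen=True)
class CurveResult:
    """Per-threshold operating points plus scalar areas.

    ``thresholds`` is ascending; recall and FP rate are non-increasing in
    the threshold. ``auprc`` uses the step convention, ``auroc`` the
    trapezoid rule.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fp_rate: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    auprc: float
    auroc: float
    auprc_convention: str = "step"

    def f_beta(self, beta: float) -> np.ndarray:
        return _f_beta(self.precision, self.recall, beta)


def _f_beta(precision: np.ndarray, recall: np.ndarray, beta: float) -> np.ndarray:
    b2 = beta * beta
    num = (1 + b2) * precision * recall
    den = b2 * precision + recall
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def curve(scores, labels) -> CurveResult:
    """Evaluate precision, recall, FP rate, F1 and F2 at every unique score
    plus the sentinels 0 and 1, and integrate AUPRC / AUROC.

    Constant scores yield a degenerate single-knee curve with a warning.
    """
    scores, labels = _check_labels(scores, labels)
    if np.unique(scores).size == 1:
        warnings.warn("constant scores: degenerate curve", stacklevel=2)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    n_pos, n_neg = pos.size, neg.size
    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))

    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    recall = tp / n_pos
    fp_rate = fp / n_neg if n_neg > 0 else np.zeros_like(recall)
    pred_pos = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1), 0.0)

    # step-convention AUPRC: sum precision * increment of recall, walking
    # the thresholds from high to low (recall increasing)
    r_desc = recall[::-1]
    p_desc = precision[::-1]
    auprc = float(np.sum(np.diff(np.concatenate([[0.0], r_desc])) * p_desc))
    # trapezoid AUROC over (FPR, TPR), from high threshold to low, anchored
    # at (0,0) so a tie block at the top score contributes its chord
    auroc = float(
        np.trapezoid(
            np.concatenate([[0.0], recall[::-1]]),
            np.concatenate([[0.0], fp_rate[::-1]]),
        )
    )

    return CurveResult(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        fp_rate=fp_rate,
        f1=_f_beta(precision, recall, 1.0),
        f2=_f_beta(precision, recall, 2.0),
        auprc=auprc,
        auroc=auroc,
    )


# The PR and ROC views are two projections of the same threshold sweep.
pr_curve = curve
roc_curve = curve


def f_beta_curve(scores, labels, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-threshold F-beta values; returns (thresholds, f_beta)."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    c = curve(scores, labels)
    return c.thresholds, c.f_beta(beta)


def optimal_threshold(c: CurveResult, beta: float) -> float:
    """Threshold maximising F-beta over the evaluated thresholds.

    Ties are broken toward the largest threshold (the stricter call).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    fb = c.f_beta(beta)
    best = fb.max()
    return float(c.thresholds[np.flatnonzero(fb == best)[-1]])


@dataclass(frozen=True)
class ThresholdBands:
    """Classification bands from the F1- and F2-optimal thresholds.

    A score at or above the F1 threshold is weak computational evidence for
    "pathogenic"; between the F2 and F1 thresholds, "likely pathogenic".
    The published hg38 values are (f1=0.963, f2=0.914).
    """

    f1_threshold: float
    f2_threshold: float

    def __post_init__(self) -> None:
        for t in (self.f1_threshold, self.f2_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.f2_threshold > self.f1_threshold:
            raise ValueError(
                f"f2_threshold ({self.f2_threshold}) must not exceed "
                f"f1_threshold ({self.f1_threshold})"
            )


def classify(score, bands: ThresholdBands):
    """Map score(s) to {'pathogenic', 'likely_pathogenic', 'below_evidence'}.

    Monotone in the score: a higher score never yields a weaker category.
    """
    arr = np.asarray(score, dtype=float)
    out = np.where(
        arr >= bands.f1_threshold,
        "pathogenic",
        np.where(arr >= bands.f2_threshold, "likely_pathogenic", "below_evidence"),
    )
    if np.isscalar(score) or arr.ndim == 0:
        return str(out)
    return out


def correlate(x, y, method: str = "spearman") -> float:
    """Spearman or Pearson correlation coefficient.

    Spearman is Pearson on midranks. Inputs must be finite, length >= 3,
    and non-constant (zero variance is undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
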