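"""Pixel-level segmentation and detection metrics.

DSC = 2TP / (FP + 2TP + FN), PPV = TP / (TP + FP),
Sensitivity = TP / (TP + FN); all counts are computed over an evaluation
domain (the brain mask). The pixel-score AUC is the Mann-Whitney rank
statistic with midrank tie handling, identical to the area under the
trapezoidal ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "confusion", "dsc", "ppv", "sensitivity", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _domain(shape, domain_mask) -> np.ndarray:
    if domain_mask is None:
        return np.ones(shape, dtype=bool)
    return np.asarray(domain_mask, dtype=bool)


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray,
              domain_mask: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts restricted to the evaluation domain."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    dom = _domain(pred.shape, domain_mask)
    p, t = pred[dom], truth[dom]
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty (perfect
    agreement convention, needed for all-normal images)."""
    denom = c.FP + 2 * c.TP + c.FN
    if denom == 0:
        return 1.0
    return 2.0 * c.TP / denom


def ppv(c: ConfusionCounts) -> float:
    """Positive predictive value; NaN (with a warning) when nothing was predicted."""
    if c.TP + c.FP == 0:
        warnings.warn("PPV undefined for an empty prediction", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return c.TP / (c.TP + c.FP)


def sensitivity(c: ConfusionCounts) -> float:
    """Sensitivity (recall); NaN (with a warning) when the truth is empty."""
    if c.TP + c.FN == 0:
        warnings.warn("sensitivity undefined for an empty truth mask",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return c.TP / (c.TP + c.FN)


def auc(scores: np.ndarray, truth_mask: np.ndarray,
        domain_mask: np.ndarray | None = None) -> float:
    """ROC AUC of per-pixel anomaly scores against the truth mask.

    Mann-Whitney formulation with midranks:
    AUC = (sum of positive-score ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth_mask, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth shapes differ")
    dom = _domain(scores.shape, domain_mask)
    s, t = scores[dom].ravel(), truth[dom].ravel()
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both positive and negative pixels")
    ranks = rankdata(s, method="average")
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
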