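"""Evaluation of a matching against a known ground truth.

With a predicted partial matching M and ground truth M*, every cell of the
p1 x p2 grid is a binary decision; precision = TP/(TP+FP) and recall =
TP/(TP+FN) summarize it, with the F1 score their harmonic mean.  Wilson
score intervals quantify the binomial uncertainty of these proportions at
small validation-set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .matching import MatchingMatrix

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "precision_recall_f1",
    "wilson_interval",
    "score_matching",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(m: MatchingMatrix, m_star: MatchingMatrix) -> ConfusionCounts:
    """Cell-wise confusion counts of a predicted matching against ground truth."""
    pred = m.m
    true = m_star.m
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 with total conventions for empty denominators.

    When no matches are predicted, precision is 1 if there were also no true
    matches to find, else 0; recall is 1 when there are no true matches; F1
    is 0 when precision + recall = 0.
    """
    if c.tp + c.fp == 0:
        precision = 1.0 if c.fn == 0 else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    recall = 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def wilson_interval(
    successes: int, n: int, level: float = 0.95, boundary_exact: bool = False
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    ``boundary_exact=True`` substitutes the one-sided exact (Clopper-Pearson)
    bound at the boundary counts (0, 1, n-1, n), a common modification for
    extreme proportions; the default is the standard score interval.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    if boundary_exact:
        beta_lo, beta_hi = proportion_confint(successes, n, alpha=alpha, method="beta")
        if successes >= n - 1:
            hi = beta_hi
        if successes <= 1:
            lo = beta_lo
    return float(lo), float(hi)


def score_matching(m: MatchingMatrix, m_star: MatchingMatrix) -> dict:
    """Convenience scoring: counts plus precision/recall/F1 in one dict."""
    c = confusion_counts(m, m_star)
    precision, recall, f1 = precision_recall_f1(c)
    return {
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
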