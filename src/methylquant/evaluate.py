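"""Evaluation statistics for methylation estimates.

Correlation against truth or microarray beta values, a dependent-correlation
t-test for comparing two estimators scored against the same reference,
ROC/AUC against dichotomized beta values, technical-replicate consistency,
and Infinium beta-value renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationResult",
    "dependent_corr_test",
    "roc_auc",
    "consistency",
    "infinium_normalize",
    "evaluate_estimates",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Agreement of one estimator with a reference vector."""

    method: str
    pearson: float
    spearman: float
    n: int
    auc: float | None = None

    def __post_init__(self) -> None:
        if abs(self.pearson) > 1 + 1e-12 or abs(self.spearman) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def dependent_corr_test(r1: float, r2: float, r12: float, n: int
                        ) -> tuple[float, float]:
    """Williams/Steiger t-test for two dependent correlations.

    Tests whether two estimators correlate equally with a shared reference
    variable: r1 = corr(est1, ref), r2 = corr(est2, ref), r12 =
    corr(est1, est2), all from the same n observations.  Returns the
    t-statistic (df = n - 3) and the two-sided p-value.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if abs(r) > 1:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    if n < 4:
        raise ValueError("need n >= 4 observations")
    det = 1.0 - r1 ** 2 - r2 ** 2 - r12 ** 2 + 2.0 * r1 * r2 * r12
    if det <= 0:
        raise ValueError(
            "the three correlations do not form a positive-definite matrix")
    if r1 == r2:
        return 0.0, 1.0
    rbar = 0.5 * (r1 + r2)
    denom = (2.0 * det * (n - 1) / (n - 3)
             + rbar ** 2 * (1.0 - r12) ** 3)
    t = (r1 - r2) * np.sqrt((n - 1) * (1.0 + r12) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def roc_auc(predictor: Sequence[float], gold_beta: Sequence[float],
            threshold: float = 0.6,
            orientation: str = "higher_is_methylated") -> float:
    """Area under the ROC curve against dichotomized beta values.

    Beta values above ``threshold`` define the methylated class.  The AUC
    is the Mann-Whitney statistic (tied predictor pairs count one half).
    ``orientation='lower_is_methylated'`` flips the predictor sign — raw
    HpaII tag counts predict *un*methylation, unlike the mu estimators.
    """
    pred = np.asarray(predictor, dtype=float)
    beta = np.asarray(gold_beta, dtype=float)
    if pred.shape != beta.shape or pred.ndim != 1:
        raise ValueError("predictor and gold_beta must be equal-length 1-D")
    if orientation not in ("higher_is_methylated", "lower_is_methylated"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "lower_is_methylated":
        pred = -pred
    pos = beta > threshold
    neg = beta < threshold
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present after dichotomization")
    ranks = stats.rankdata(np.concatenate([pred[pos], pred[neg]]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def consistency(est_a: Sequence[float], est_b: Sequence[float]) -> float:
    """Pearson correlation between paired technical-replicate estimates.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    a = np.asarray(est_a, dtype=float)
    b = np.asarray(est_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 estimates")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("consistency undefined: zero variance in a replicate",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def infinium_normalize(meth: float, unmeth: float,
                       neg_ctrl_median: float,
                       neg_ctrl_median_unmeth: float | None = None
                       ) -> float:
    """Background-corrected Infinium beta value b/(a+b).

    The negative-control median is subtracted from each channel and the
    result floored at zero; a channel-specific median for the unmethylated
    channel may be supplied.  Returns NaN (a missing value, not an error)
    when both channels are floored to zero.
    """
    ctrl_u = neg_ctrl_median if neg_ctrl_median_unmeth is None \
        else neg_ctrl_median_unmeth
    b = max(meth - neg_ctrl_median, 0.0)
    a = max(unmeth - ctrl_u, 0.0)
    if a + b == 0:
        return float("nan")
    return b / (a + b)


def evaluate_estimates(estimates: Sequence[float], reference: Sequence[float],
                       method: str = "", gold_beta: Sequence[float] | None = None,
                       threshold: float = 0.6,
                       orientation: str = "higher_is_methylated"
                       ) -> EvaluationResult:
    """Correlations (and optionally AUC) of estimates against a reference."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and reference must be equal-length 1-D")
    pearson = float(np.corrcoef(est, ref)[0, 1])
    spearman = float(stats.spearmanr(est, ref).statistic)
    auc = None
    if gold_beta is not None:
        auc = roc_auc(est, gold_beta, threshold, orientation)
    return EvaluationResult(method=method, pearson=pearson, spearman=spearman,
                            n=est.size, auc=auc)
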