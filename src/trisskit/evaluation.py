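"""Discrimination analysis: ROC curve, AUC with 95% CI, optimal cutoff.

Scores are survival probabilities and the positive class is "survived"
(the models predict survival); pass ``predict_death=True`` to flip the
orientation, which is pure relabelling.

The AUC is the Mann-Whitney probability that a random survivor outranks
a random non-survivor, ties counted 1/2 — identical to the trapezoidal
area under the empirical ROC staircase.  Confidence intervals come from
the DeLong closed-form variance (default) or a stratified percentile
bootstrap; the cutoff from the Youden index (max sens + spec - 1), ties
broken toward the higher threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import EvaluationError


@dataclass
class RocResult:
    """ROC staircase with AUC, confidence interval and chosen cutoff."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None
    cutoff: Optional[float] = None
    cutoff_sens: Optional[float] = None
    cutoff_spec: Optional[float] = None


def _validate(scores, outcome, predict_death: bool):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise EvaluationError("scores and outcome must be equal-length 1-d arrays")
    if set(np.unique(y)) - {0, 1}:
        raise EvaluationError("outcome must be coded 0/1")
    if predict_death:
        s, y = -s, 1 - y
    if y.sum() == 0 or y.sum() == len(y):
        raise EvaluationError(
            "AUC undefined: both outcome classes must be present"
        )
    return s, y


def auc(scores, outcome, *, predict_death: bool = False) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    s, y = _validate(scores, outcome, predict_death)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, outcome, *, predict_death: bool = False) -> RocResult:
    """Empirical ROC staircase at every unique score plus sentinels."""
    s, y = _validate(scores, outcome, predict_death)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc(s, y),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def _delong_variance(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midranks."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci(
    scores,
    outcome,
    method: str = "delong",
    *,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    predict_death: bool = False,
) -> tuple[float, float]:
    """Two-sided confidence interval for the AUC.

    ``delong`` uses the closed-form variance of the Mann-Whitney
    statistic; ``bootstrap`` a percentile interval over class-stratified
    resamples (``reps`` >= 200, seeded).  A degenerate variance (e.g.
    AUC exactly 1 at tiny n) collapses the interval with a warning.
    """
    s, y = _validate(scores, outcome, predict_death)
    if method == "delong":
        a, var = _delong_variance(s, y)
        if var <= 0:
            warnings.warn(
                "degenerate AUC variance; interval collapsed to the point",
                stacklevel=2,
            )
            return a, a
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return max(0.0, a - half), min(1.0, a + half)
    if method == "bootstrap":
        if reps < 200:
            raise EvaluationError("bootstrap requires reps >= 200")
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        stats = np.empty(reps)
        for i in range(reps):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            stats[i] = auc(s[idx], y[idx])
        lo, hi = np.quantile(stats, [0.5 - level / 2, 0.5 + level / 2])
        if lo == hi:
            warnings.warn("degenerate bootstrap distribution", stacklevel=2)
        return float(lo), float(hi)
    raise EvaluationError(f"unknown CI method {method!r}")


def optimal_cutoff(
    roc: RocResult, method: str = "youden"
) -> tuple[float, float, float]:
    """Score threshold maximising the Youden index (sens + spec - 1).

    Ties break toward the higher threshold (higher specificity).  The
    sentinel threshold above the maximum score is reported as the
    maximum finite threshold.
    """
    if method != "youden":
        raise EvaluationError(f"unknown cutoff method {method!r}")
    j = roc.sensitivity + roc.specificity - 1.0
    k = int(np.argmax(j))  # thresholds descend: first max = highest threshold
    cut = float(roc.thresholds[k])
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    if not np.isfinite(cut) or (finite.size and cut > finite.max()):
        cut = float(finite.max()) if finite.size else cut
    return cut, float(roc.sensitivity[k]), float(roc.specificity[k])


def discrimination_report(
    scores,
    outcome,
    *,
    ci_method: str = "delong",
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    predict_death: bool = False,
) -> RocResult:
    """Full ROC analysis: curve, AUC, CI and Youden cutoff in one call."""
    roc = roc_curve(scores, outcome, predict_death=predict_death)
    lo, hi = auc_ci(
        scores,
        outcome,
        ci_method,
        level=level,
        reps=reps,
        seed=seed,
        predict_death=predict_death,
    )
    cut, sens, spec = optimal_cutoff(roc)
    roc.ci_low, roc.ci_high, roc.ci_method = lo, hi, ci_method
    roc.cutoff, roc.cutoff_sens, roc.cutoff_spec = cut, sens, spec
    return roc


__all__ = [
    "RocResult",
    "auc",
    "roc_curve",
    "auc_ci",
    "optimal_cutoff",
    "discrimination_report",
]
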