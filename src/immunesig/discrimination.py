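"""ROC curves, AUC, and the DeLong paired comparison of two AUCs.

The AUC uses the midrank (ties count 1/2) convention, making it identical to
the Mann–Whitney U statistic scaled by n1*n0.  The DeLong test estimates the
variance of the paired AUC difference from per-sample placement values and
refers z = ΔAUC / se to the standard normal.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "roc_auc", "delong_test"]


@dataclasses.dataclass
class ROCResult:
    """Empirical ROC points and AUC for one score."""

    points: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    name: str
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of [0, 1]: {self.auc}")

    def write_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def _check_binary(outcome: np.ndarray) -> np.ndarray:
    outcome = np.asarray(outcome).astype(bool)
    if outcome.all() or not outcome.any():
        raise ValueError("both outcome classes must be present")
    return outcome


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_midrank(scores: np.ndarray, outcome: np.ndarray) -> float:
    ranks = _midrank(scores)
    n1 = int(outcome.sum())
    n0 = outcome.size - n1
    u = ranks[outcome].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, outcome, name: str = "score") -> ROCResult:
    """Empirical ROC over score thresholds with midrank AUC."""
    scores = np.asarray(scores, dtype=float)
    outcome = _check_binary(outcome)
    if scores.size != outcome.size:
        raise ValueError("scores and outcome must be paired")
    fpr, tpr, thresholds = roc_curve(outcome.astype(int), scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    auc = _auc_midrank(scores, outcome)
    return ROCResult(
        points=points,
        auc=auc,
        name=name,
        n_positive=int(outcome.sum()),
        n_negative=int((~outcome).sum()),
    )


def _placements(scores: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[outcome]
    neg = scores[~outcome]
    m, n = pos.size, neg.size
    ranks_all = _midrank(np.concatenate([pos, neg]))
    ranks_pos = _midrank(pos)
    ranks_neg = _midrank(neg)
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01, float(auc)


def delong_test(scores_a, scores_b, outcome) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two AUCs on the same samples.

    Returns (auc_a, auc_b, z, two-sided p).  When the variance of the
    difference is zero and the AUCs are equal, p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    outcome = _check_binary(outcome)
    if not (scores_a.size == scores_b.size == outcome.size):
        raise ValueError("scores_a, scores_b and outcome must be paired")

    v10 = np.empty((2, int(outcome.sum())))
    v01 = np.empty((2, int((~outcome).sum())))
    aucs = np.empty(2)
    for k, scores in enumerate((scores_a, scores_b)):
        v10[k], v01[k], aucs[k] = _placements(scores, outcome)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10)  # 2x2 across positives
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var_diff <= 0:
        if math.isclose(delta, 0.0, abs_tol=1e-12):
            return float(aucs[0]), float(aucs[1]), 0.0, 1.0
        raise ValueError("zero variance estimate with unequal AUCs")
    z = delta / math.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)
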