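"""Score vs. categorical outcome: contingency tests, ROC/AUC, DeLong.

The immunotherapy-response analyses compare high/low score groups against
RECIST categories (chi-square or Fisher's exact, two-sided by summing the
probabilities of tables no more likely than the observed one) and evaluate
the continuous score as a responder classifier.  AUC is the trapezoid area
under the empirical ROC, which equals the Mann-Whitney pair-counting
probability with half-weight ties; ``positive_direction="lower"`` scores a
marker whose low values predict response (the direction reported for the
m6Ascore under checkpoint blockade).  Paired AUCs are compared with DeLong's
structural-components test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

#: RECIST collapse used for the responder binarization.
RESPONDER_CATEGORIES = ("CR", "PR")


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    curve: pd.DataFrame  # columns fpr, tpr, threshold
    n_pos: int
    n_neg: int


def contingency_test(table, method: str = "auto"):
    """Chi-square or Fisher test of a contingency table.

    ``method``: ``chi2`` (df = (r-1)(c-1), no continuity correction),
    ``fisher2x2`` (2x2 only), or ``auto`` (Fisher for a 2x2 with any expected
    count < 5, chi-square otherwise).  A zero row/column margin is an error.
    Returns ``(statistic, p)``; for Fisher the statistic is the odds ratio.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    if method == "auto":
        if counts.shape == (2, 2):
            expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
            method = "fisher2x2" if (expected < 5).any() else "chi2"
        else:
            method = "chi2"
    if method == "fisher2x2":
        if counts.shape != (2, 2):
            raise ValueError("fisher2x2 requires a 2x2 table")
        odds, p = stats.fisher_exact(counts.astype(int), alternative="two-sided")
        return float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


def binarize_response(response: pd.Series,
                      responder_categories=RESPONDER_CATEGORIES) -> pd.Series:
    """RECIST categories -> 1 (responder) / 0; missing stays missing."""
    resp = response.dropna()
    return resp.isin(responder_categories).astype(int).reindex(response.index)


def roc_auc(scores, labels, positive_direction: str = "higher") -> RocResult:
    """Empirical ROC and AUC, with a DeLong-variance confidence interval.

    ``positive_direction="lower"`` treats small scores as predicting the
    positive class (the score is negated internally).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    if positive_direction == "lower":
        scores = -scores
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    var = _delong_variance_single(scores, labels)
    ci = _auc_ci(auc, var)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(auc=auc, ci95=ci, curve=curve, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# DeLong machinery

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """V10 (per positive) and V01 (per negative) placement components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def _delong_variance_single(scores, labels) -> float:
    v10, v01 = _structural_components(np.asarray(scores, float), np.asarray(labels, int))
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def _auc_ci(auc: float, var: float, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(max(var, 0.0))
    if se == 0:
        return (auc, auc)
    # logit scale near the boundary keeps the interval inside [0, 1]
    if auc < 0.05 or auc > 0.95:
        if auc in (0.0, 1.0):
            return (max(0.0, auc - z * se), min(1.0, auc + z * se))
        logit = np.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo, hi = logit - z * se_logit, logit + z * se_logit
        return (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def delong_compare(scores_a, scores_b, labels):
    """DeLong test for two paired AUCs on the same samples.

    Returns ``(auc_a, auc_b, z, p)``.  A non-positive variance of the AUC
    difference (e.g., identical scores) is the degenerate path: z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores and labels must align")
    v10a, v01a = _structural_components(scores_a, labels)
    v10b, v01b = _structural_components(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var_diff <= 1e-15:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def response_rate_table(groups: pd.Series, response: pd.Series) -> pd.DataFrame:
    """Counts of responders / non-responders per score group (rows high, low)."""
    binary = binarize_response(response)
    df = pd.DataFrame({"group": groups, "responder": binary}).dropna()
    table = pd.crosstab(df["group"], df["responder"])
    table.columns = ["non_responder" if c == 0 else "responder" for c in table.columns]
    return table
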