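"""Differential-expression screen per regulation pattern and CEG intersection.

Each cluster is contrasted one-vs-rest with a moderated t-test on log2
expression: per-gene pooled variances are shrunk toward a common prior by
empirical Bayes, with the prior degrees of freedom d0 and prior variance s0^2
moment-matched on the log-variance scale (the limma construction):

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d),   df_post = d0 + d

A gene passes for a cluster when p < p_threshold and |fold change| >
fc_threshold on the linear scale (fc 2 <=> |log2FC| > 1).  The co-expressed
gene (CEG) set is the intersection of the per-cluster passing sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CEGSet:
    members: frozenset[str]
    per_cluster_counts: dict[int, int]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in limma's fitFDist)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Works on z = log(s2): E[z] and Var[z] under the hierarchical model give
    two equations solved with digamma/trigamma, following the standard
    empirical-Bayes treatment.  Returns ``(d0, s0_squared)``; ``d0`` may be
    ``inf`` when the observed variances are less dispersed than chi-square
    sampling alone implies.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("not enough positive variances to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(e.mean())
    # unbiased-ish excess variance of e over the chi-square sampling variance
    n = len(e)
    var_e = float(e.var(ddof=1)) - special.polygamma(1, df / 2.0)
    if var_e <= 0:
        return float("inf"), float(np.exp(mean_e))
    d0 = 2.0 * _trigamma_inverse(var_e)
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(group_a: np.ndarray, group_b: np.ndarray,
                    prior_df: float | None = None):
    """Vectorized moderated two-sample t across genes (rows).

    Returns DataFrame columns: log2_fc, t, p, df_total.  ``prior_df``
    overrides the fitted d0 (0 reproduces the ordinary t exactly).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 3 or nb < 3:
        raise ValueError("each group needs >=3 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = mean_a - mean_b
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    df = na + nb - 2
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    if np.all(s2 == 0):
        warnings.warn("zero within-group variance everywhere; falling back to ordinary t",
                      stacklevel=2)
        d0, s0_sq = 0.0, 0.0
    elif prior_df is not None:
        d0 = prior_df
        _, s0_sq = fit_variance_prior(s2, df) if prior_df > 0 else (0.0, 0.0)
    else:
        d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        s2_post = s2
        df_total = df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(se > 0, p, 1.0)
    return pd.DataFrame({"log2_fc": fc, "t": t, "p": p,
                         "df_total": df_total})


def one_vs_rest_moderated(values: np.ndarray, labels: np.ndarray, cluster_id,
                          prior_df: float | None = None) -> pd.DataFrame:
    """Moderated one-vs-rest contrast with within-cluster residual variance.

    A linear model with one mean per cluster underlies the contrast (the
    lmFit-style treatment): the residual variance pools within-cluster
    variation across *all* clusters (df = n - K), so a multimodal rest group
    does not inflate the standard error.  The contrast itself is
    mean(cluster) - mean(rest samples); its standard error is
    sqrt(s2_post * (1/n_c + 1/n_rest)).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    in_cluster = labels == cluster_id
    n_c, n_rest = int(in_cluster.sum()), int((~in_cluster).sum())
    if n_c < 3 or n_rest < 3:
        raise ValueError("cluster and rest each need >=3 members")
    n = values.shape[1]
    df = n - len(groups)
    ss = np.zeros(values.shape[0])
    for g in groups:
        sub = values[:, labels == g]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
    s2 = ss / df
    fc = values[:, in_cluster].mean(axis=1) - values[:, ~in_cluster].mean(axis=1)
    if np.all(s2 == 0):
        warnings.warn("zero within-group variance everywhere; falling back to ordinary t",
                      stacklevel=2)
        d0, s0_sq = 0.0, 0.0
    elif prior_df is not None:
        d0 = prior_df
        _, s0_sq = fit_variance_prior(s2, df) if prior_df > 0 else (0.0, 0.0)
    else:
        d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post, df_total = np.full_like(s2, s0_sq), np.inf
    elif d0 > 0:
        s2_post, df_total = (d0 * s0_sq + df * s2) / (d0 + df), d0 + df
    else:
        s2_post, df_total = s2, df
    se = np.sqrt(s2_post * (1.0 / n_c + 1.0 / n_rest))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(se > 0, p, 1.0)
    return pd.DataFrame({"log2_fc": fc, "t": t, "p": p, "df_total": df_total})


def cluster_degs(expr, labels, cluster_id, p_threshold: float = 0.05,
                 fc_threshold: float = 2.0, fdr: bool = False,
                 prior_df: float | None = None) -> pd.DataFrame:
    """One-vs-rest DEG screen for one cluster.

    Returns a DataFrame indexed by gene with log2_fc, p (optionally
    BH-adjusted), and the boolean ``passes`` column implementing
    (p < p_threshold) AND (|linear fold change| > fc_threshold).
    """
    res = one_vs_rest_moderated(expr.values, labels, cluster_id, prior_df=prior_df)
    res.index = pd.Index(expr.gene_ids, name="gene_id")
    if fdr:
        res["p"] = multipletests(res["p"], method="fdr_bh")[1]
    log2_fc_threshold = np.log2(fc_threshold)
    res["passes"] = (res["p"] < p_threshold) & (res["log2_fc"].abs() > log2_fc_threshold)
    return res


def intersect_cegs(deg_tables: list[pd.DataFrame]) -> CEGSet:
    """Intersection of passing genes across per-cluster DEG tables."""
    if len(deg_tables) < 2:
        raise ValueError("need >=2 DEG lists to intersect")
    passing = [set(t.index[t["passes"]]) for t in deg_tables]
    members = frozenset(set.intersection(*passing))
    if not members:
        logger.warning("empty CEG intersection")
    return CEGSet(members=members,
                  per_cluster_counts={i + 1: len(s) for i, s in enumerate(passing)})
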