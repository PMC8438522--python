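"""Model-based clustering of the regulator panel and cluster characterization.

``fit_model_clusters`` fits Gaussian mixtures by EM over a compact family
sweep (spherical, diagonal, shared full, per-cluster full covariance) and
keeps the fit with the best BIC — the canonical mclust-style treatment of
"model-based clustering".  Genes are z-scored before fitting.  EM runs in
single-iteration warm-started steps so the log-likelihood trajectory is
recorded and its monotonicity is checkable.

``characterize_clusters`` applies the highest / lowest / median labelling
rule: a Kruskal-Wallis screen per feature, then Dunn pairwise z-tests
(Holm-adjusted); a cluster is "highest" only when its median exceeds every
other cluster with all of its pairwise comparisons significant, symmetric for
"lowest", and "median" when significantly above one group and below the other.

``consensus_cluster`` is a Monti-style subsampled consensus used to confirm
the stability of gene-level clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COVARIANCE_FAMILIES = ("spherical", "diag", "tied", "full")


@dataclass
class ClusterAssignment:
    labels: np.ndarray               # per-sample, 1..K
    K: int
    responsibilities: np.ndarray     # samples x K, rows sum to 1
    model_bic: float
    covariance_family: str
    sample_ids: list[str]
    loglik_trajectory: list[float] = field(default_factory=list)
    bic_by_family: dict[str, float] = field(default_factory=dict)
    consensus: np.ndarray | None = None

    def __post_init__(self) -> None:
        sums = self.responsibilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("responsibilities must sum to 1 per sample")
        if not np.array_equal(self.labels, self.responsibilities.argmax(axis=1) + 1):
            raise ValueError("labels must be the argmax responsibility")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _fit_gmm_tracked(X, K, family, seed, max_steps=500, tol=1e-7):
    """Fit one GMM by warm-started single-iteration EM; returns (gmm, trajectory)."""
    gmm = GaussianMixture(n_components=K, covariance_type=family,
                          max_iter=1, n_init=1, init_params="k-means++",
                          random_state=seed, warm_start=True, tol=1e-12,
                          reg_covar=1e-6)
    trajectory: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-step non-convergence chatter
        for _ in range(max_steps):
            gmm.fit(X)
            ll = float(gmm.lower_bound_)
            if trajectory and ll - trajectory[-1] < tol:
                trajectory.append(ll)
                break
            trajectory.append(ll)
    return gmm, trajectory


def fit_model_clusters(expr, K: int = 3,
                       families: tuple[str, ...] = COVARIANCE_FAMILIES,
                       seed: int = 0, n_init: int = 3, standardize: bool = True,
                       min_panel_genes: int = 16, max_restarts: int = 5) -> ClusterAssignment:
    """Gaussian-mixture regulation patterns from a panel-restricted matrix.

    ``expr`` is an :class:`~m6apattern.io_formats.ExpressionMatrix` already
    restricted to the regulator panel (a panel gene missing from the cohort
    is tolerated down to ``min_panel_genes``).  The best-BIC fit across
    covariance families is returned; labels are argmax responsibilities with
    ties broken toward the lowest cluster index.
    """
    values = expr.values
    if values.shape[0] < min_panel_genes:
        raise ValueError(f"only {values.shape[0]} panel genes present (< {min_panel_genes})")
    n = values.shape[1]
    if n < 5 * K:
        raise ValueError(f"need >= {5 * K} samples for K={K}")
    X = _zscore_rows(values).T if standardize else values.T  # samples x genes

    rng = np.random.default_rng(seed)
    best = None
    bic_by_family: dict[str, float] = {}
    for family in families:
        fam_best = None
        for restart in range(max_restarts):
            ok = True
            for init in range(n_init):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                gmm, traj = _fit_gmm_tracked(X, K, family, sub_seed)
                labels = gmm.predict_proba(X).argmax(axis=1)
                counts = np.bincount(labels, minlength=K)
                if (counts < 2).any():
                    ok = False
                    continue
                bic = float(gmm.bic(X))
                if fam_best is None or bic < fam_best[0]:
                    fam_best = (bic, gmm, traj)
            if fam_best is not None:
                break
            if not ok:
                logger.info("degenerate EM fit (family=%s, restart %d); restarting", family, restart)
        if fam_best is None:
            raise RuntimeError(f"EM degenerate for family {family!r} after {max_restarts} restarts")
        bic_by_family[family] = fam_best[0]
        if best is None or fam_best[0] < best[0]:
            best = (*fam_best, family)
    bic, gmm, traj, family = best
    resp = gmm.predict_proba(X)
    labels = resp.argmax(axis=1) + 1  # argmax picks the lowest index on ties
    return ClusterAssignment(labels=labels, K=K, responsibilities=resp,
                             model_bic=bic, covariance_family=family,
                             sample_ids=expr.sample_ids,
                             loglik_trajectory=traj, bic_by_family=bic_by_family)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn characterization

def dunn_posthoc(values: np.ndarray, groups: np.ndarray, adjust: str = "holm") -> pd.DataFrame:
    """Dunn pairwise z-tests on ranks after a Kruskal-Wallis screen.

    Returns a long DataFrame with columns group_a, group_b, z, p (adjusted).
    """
    labels = np.unique(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            ra, rb = ranks[groups == a], ranks[groups == b]
            na, nb = len(ra), len(rb)
            var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
            z = (ra.mean() - rb.mean()) / np.sqrt(var) if var > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust and len(df):
        df["p"] = multipletests(df["p"], method=adjust)[1]
    return df


def _feature_label(medians: pd.Series, pairwise: pd.DataFrame, alpha: float) -> dict:
    """highest/lowest/median/ns labels for one feature from Dunn results."""
    labels = {g: "ns" for g in medians.index}
    sig = {}
    for _, row in pairwise.iterrows():
        sig[frozenset((row.group_a, row.group_b))] = row.p < alpha
    groups = list(medians.index)
    for g in groups:
        others = [h for h in groups if h != g]
        all_sig = all(sig.get(frozenset((g, h)), False) for h in others)
        above = [medians[g] > medians[h] for h in others]
        below = [medians[g] < medians[h] for h in others]
        if all_sig and all(above):
            labels[g] = "highest"
        elif all_sig and all(below):
            labels[g] = "lowest"
        elif all_sig and any(above) and any(below):
            labels[g] = "median"
    return labels


def characterize_clusters(values: pd.DataFrame, labels, alpha: float = 0.05,
                          adjust: str = "holm") -> pd.DataFrame:
    """Label each feature highest/lowest/median/ns per cluster.

    ``values``: samples x features; ``labels``: per-sample cluster labels
    aligned with ``values``.  The Kruskal-Wallis p gates the Dunn tests; the
    labelling rule assigns at most one "highest" and one "lowest" per feature.
    Returns a long DataFrame (feature, cluster, label, kw_p, median).
    """
    labels = np.asarray(labels)
    clusters, counts = np.unique(labels, return_counts=True)
    if len(clusters) < 2 or (counts < 2).any():
        raise ValueError("need >=2 clusters with >=2 members each")
    records = []
    for feature in values.columns:
        x = values[feature].to_numpy(dtype=float)
        groups = [x[labels == c] for c in clusters]
        if np.ptp(x) == 0:  # all values tied
            kw_p, lab = 1.0, {c: "ns" for c in clusters}
            meds = pd.Series({c: np.median(g) for c, g in zip(clusters, groups)})
        else:
            try:
                kw_stat, kw_p = stats.kruskal(*groups)
            except ValueError:  # all numbers identical
                kw_stat, kw_p = 0.0, 1.0
            meds = pd.Series({c: np.median(g) for c, g in zip(clusters, groups)})
            if kw_p < alpha:
                pw = dunn_posthoc(x, labels, adjust=adjust)
                lab = _feature_label(meds, pw, alpha)
            else:
                lab = {c: "ns" for c in clusters}
        for c in clusters:
            records.append((feature, c, lab[c], float(kw_p), float(meds[c])))
    return pd.DataFrame(records, columns=["feature", "cluster", "label", "kw_p", "median"])


# ---------------------------------------------------------------------------
# Monti-style consensus clustering

def consensus_cluster(expr, K: int, n_resamples: int = 100, sample_frac: float = 0.8,
                      seed: int = 0, method: str = "kmeans") -> ClusterAssignment:
    """Subsampled consensus clustering of samples on a gene-restricted matrix.

    Each resample draws ``sample_frac`` of the samples without replacement and
    partitions them into K groups; consensus(i, j) = co-clustered count /
    co-sampled count.  Pairs never co-sampled get 0.5 with a warning.  Final
    labels cut an average-linkage tree of (1 - consensus).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_resamples < 10:
        raise ValueError("need >= 10 resamples")
    X = _zscore_rows(expr.values).T  # samples x genes
    n = X.shape[0]
    m = max(K + 1, int(round(sample_frac * n)))
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        if method == "kmeans":
            km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(X[idx])
        else:
            sub_link = linkage(X[idx], method="ward")
            lab = fcluster(sub_link, t=K, criterion="maxclust")
        sampled[np.ix_(idx, idx)] += 1
        same = lab[:, None] == lab[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = together / sampled
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} sample pairs never co-sampled; "
                      "consensus set to 0.5", stacklevel=2)
        consensus[never] = 0.5
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=K, criterion="maxclust")
    resp = np.zeros((n, labels.max()))
    resp[np.arange(n), labels - 1] = 1.0
    return ClusterAssignment(labels=labels, K=int(labels.max()), responsibilities=resp,
                             model_bic=float("nan"), covariance_family="consensus",
                             sample_ids=expr.sample_ids, consensus=consensus)
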