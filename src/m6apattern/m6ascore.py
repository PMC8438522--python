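"""The m6Ascore: PCA of CEG expression, summed over the first two components.

Each CEG is standardized across samples, the sample x CEG matrix is
decomposed by PCA, and the per-sample score is the sum of the projections on
the first two principal components.  Because an eigenvector's sign is
arbitrary, each component is oriented so that its largest-magnitude gene
loading is positive (first such gene on ties); the applied orientation is
recorded, making scores and the downstream high/low grouping deterministic
across linear-algebra backends.

Dichotomization against survival delegates to the maximally selected
log-rank cutpoint (:func:`m6apattern.survival_stats.maxstat_cutpoint`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival_stats import maxstat_cutpoint

logger = logging.getLogger(__name__)


@dataclass
class M6AScoreTable:
    table: pd.DataFrame                   # index sample_id; pc1, pc2, score, [group]
    loadings: pd.DataFrame | None = None  # genes x (pc1, pc2)
    explained_variance: np.ndarray | None = None
    orientation: tuple[int, int] = (1, 1)
    cutpoint: float | None = None
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        if "group" not in self.table.columns:
            raise ValueError("scores not yet dichotomized")
        return self.table["group"]


def compute_m6ascore(expr, standardize: bool = True) -> M6AScoreTable:
    """PCA score table from a CEG-restricted expression matrix.

    ``expr`` holds genes x samples; zero-variance genes are dropped with a
    warning; fewer than two usable genes or three samples is an error.
    """
    values = expr.values.astype(float)  # genes x samples
    gene_ids = list(expr.gene_ids)
    sds = values.std(axis=1)
    dropped = [g for g, s in zip(gene_ids, sds) if s == 0]
    if dropped:
        logger.warning("dropping %d zero-variance genes from the score", len(dropped))
        keep = sds > 0
        values, gene_ids = values[keep], [g for g, k in zip(gene_ids, keep) if k]
    if values.shape[0] < 2:
        raise ValueError("insufficient CEGs (need >=2 non-constant genes)")
    if values.shape[1] < 3:
        raise ValueError("need >=3 samples")
    X = values.T  # samples x genes
    X = X - X.mean(axis=0)
    if standardize:
        X = X / X.std(axis=0)
    # covariance eigen-decomposition (population normalization; only the
    # projection directions matter)
    cov = (X.T @ X) / X.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    signs = []
    for k in (0, 1):
        v = eigvec[:, k]
        idx = int(np.argmax(np.abs(v)))  # first index on ties
        s = 1 if v[idx] >= 0 else -1
        eigvec[:, k] = s * v
        signs.append(s)
    pc1 = X @ eigvec[:, 0]
    pc2 = X @ eigvec[:, 1]
    table = pd.DataFrame({"pc1": pc1, "pc2": pc2, "score": pc1 + pc2},
                         index=pd.Index(expr.sample_ids, name="sample_id"))
    loadings = pd.DataFrame(eigvec[:, :2], index=gene_ids, columns=["pc1", "pc2"])
    return M6AScoreTable(table=table, loadings=loadings,
                         explained_variance=eigval[:2],
                         orientation=(signs[0], signs[1]), dropped_genes=dropped)


def dichotomize(score_table: M6AScoreTable, clinical, min_group_frac: float = 0.1) -> M6AScoreTable:
    """Split samples into high/low score groups at the maxstat cutpoint.

    ``clinical`` is a :class:`~m6apattern.io_formats.ClinicalTable`; the join
    is by sample ID.  The low group is score <= cutpoint.
    """
    common = [s for s in score_table.table.index if s in clinical.data.index]
    if len(common) < len(score_table.table):
        logger.info("dichotomize: %d scored samples lack clinical records",
                    len(score_table.table) - len(common))
    scores = score_table.table.loc[common, "score"].to_numpy()
    time = clinical.data.loc[common, "pfs_time"].to_numpy(dtype=float)
    event = clinical.data.loc[common, "pfs_event"].to_numpy(dtype=int)
    cut, _, labels = maxstat_cutpoint(scores, time, event, min_group_frac=min_group_frac)
    table = score_table.table.copy()
    table["group"] = pd.Series(
        np.where(table["score"] > cut, "high", "low"), index=table.index)
    score_table.table = table
    score_table.cutpoint = cut
    return score_table
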