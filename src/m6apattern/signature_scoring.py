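"""Per-sample signature scoring by ssGSEA, plus ingestion of precomputed tables.

The single-sample enrichment score walks the sample's genes in descending
expression order and accumulates, at every rank position, the difference
between the weighted in-set empirical CDF and the uniform out-of-set CDF:

    ES = sum_i [ P_in(i) - P_out(i) ]

where P_in steps by |r|^alpha at in-set genes (r is the descending rank
statistic, N at the top gene down to 1) and P_out steps by 1/(N - |S|) at
out-of-set genes.  With alpha = 0 this reduces to a pure rank statistic:
monotone transforms of expression leave the score unchanged, and reversing
the ranking negates it exactly.

Ties in expression are broken by gene ID (ascending) so scores are
deterministic across platforms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


def _descending_order(values: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices sorting genes by (expression desc, gene ID asc)."""
    id_rank = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object)))
    # lexsort: last key is primary
    return np.lexsort((id_rank, -values))


def ssgsea_score(values, gene_ids: Sequence[str], gene_set: Iterable[str],
                 alpha: float = DEFAULT_ALPHA) -> float:
    """Enrichment score of ``gene_set`` in one sample's expression profile."""
    values = np.asarray(values, dtype=float)
    gene_ids = list(gene_ids)
    if len(values) != len(gene_ids):
        raise ValueError("values and gene_ids must align")
    if len(gene_ids) < 2:
        raise ValueError("need >=2 genes")
    members = set(gene_set)
    in_set = np.array([g in members for g in gene_ids])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError("gene set has no overlap with the profile")
    if n_in == len(gene_ids):
        raise ValidationError("gene set covers the whole profile; complement undefined")
    order = _descending_order(values, gene_ids)
    in_sorted = in_set[order]
    n = len(gene_ids)
    rank_stat = np.arange(n, 0, -1, dtype=float)  # N at top, 1 at bottom
    w = np.where(in_sorted, np.abs(rank_stat) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def score_matrix(expr: ExpressionMatrix, sets: Sequence[GeneSet],
                 alpha: float = DEFAULT_ALPHA, normalize: bool = False) -> pd.DataFrame:
    """ssGSEA scores for every (sample, gene set); samples as rows.

    Sets with no overlap in the matrix yield a column of NaN with a warning.
    With ``normalize`` each signature is min-max scaled to [0, 1] across
    samples.
    """
    gene_ids = expr.gene_ids
    values = expr.values  # genes x samples
    out = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"),
                       columns=[gs.name for gs in sets], dtype=float)
    members_per_set = []
    for gs in sets:
        overlap = gs.members.intersection(gene_ids)
        if not overlap:
            logger.warning("gene set %s has no overlap with the matrix; scores absent", gs.name)
            members_per_set.append(None)
        else:
            members_per_set.append(overlap)
    for j, sample in enumerate(expr.sample_ids):
        profile = values[:, j]
        for gs, overlap in zip(sets, members_per_set):
            if overlap is None:
                continue
            out.loc[sample, gs.name] = ssgsea_score(profile, gene_ids, overlap, alpha=alpha)
    if normalize:
        rng = out.max() - out.min()
        rng = rng.replace(0, 1.0)
        out = (out - out.min()) / rng
    return out


def ingest_signature_table(path, cohort_samples: Sequence[str] | None = None,
                           dialect: str | None = None) -> pd.DataFrame:
    """Load a precomputed per-sample signature score table (CSV/TSV).

    The first column is the sample ID.  Samples absent from
    ``cohort_samples`` (when given) are dropped and counted; duplicate sample
    rows are an error; no overlap at all is an error.
    """
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        raise ValidationError("duplicated sample rows in signature table")
    if cohort_samples is not None:
        common = [s for s in cohort_samples if s in df.index]
        if not common:
            raise ValidationError("no overlapping samples between signature table and cohort")
        dropped = len(df) - len(common)
        if dropped:
            logger.info("signature table: %d samples outside the cohort dropped", dropped)
        df = df.loc[common]
    return df
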