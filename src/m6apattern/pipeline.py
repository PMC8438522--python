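"""End-to-end orchestration: cluster -> characterize -> score -> survive -> respond.

``run_pipeline`` executes the full analysis on either a real input bundle
(expression + clinical + gene sets) or a synthetic cohort configuration,
persisting each stage's table and a JSON manifest (seed, parameters, sample
counts) so every reported number is traceable to a stage output.  A single
global seed derives per-stage seeds through ``numpy.random.SeedSequence``
spawn keys, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .coexpression_resampling import DEFAULT_SCREEN_REGULATORS, run_multicoexp
from .deg_ceg import cluster_degs, intersect_cegs
from .io_formats import (ClinicalTable, ExpressionMatrix, RegulatorPanel,
                         read_clinical, read_expression, read_gmt, read_panel_gmt,
                         write_clinical, write_expression)
from .m6ascore import compute_m6ascore, dichotomize
from .regulator_clustering import (characterize_clusters, consensus_cluster,
                                   fit_model_clusters)
from .response_eval import binarize_response, contingency_test, response_rate_table, roc_auc
from .signature_scoring import ingest_signature_table, score_matrix
from .survival_stats import logrank_test, univariate_cox
from .synthetic_cohort import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("cluster", "characterize", "signatures", "deg", "consensus",
          "score", "survival", "coexpression", "response")


@dataclass
class PipelineConfig:
    # exactly one of (expression_path, synthetic) must be set
    expression_path: str | None = None
    clinical_path: str | None = None
    panel_path: str | None = None
    signatures_gmt_path: str | None = None
    signature_table_path: str | None = None
    synthetic: CohortConfig | None = None
    K: int = 3
    alpha: float = 0.25
    normalize_signatures: bool = False
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    frac: float = 0.6
    n_reps: int = 100
    min_group_frac: float = 0.1
    consensus_resamples: int = 50
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        real = self.expression_path is not None
        if real == (self.synthetic is not None):
            raise ValueError("exactly one of real inputs or a synthetic config is required")
        if real and self.clinical_path is None:
            raise ValueError("real inputs need a clinical table")


@dataclass
class RunReport:
    cluster_sizes: dict[int, int]
    covariance_family: str
    characterization: pd.DataFrame
    ceg_count: int
    per_cluster_deg_counts: dict[int, int]
    score_summary: dict[str, float]
    cutpoint: float
    survival: dict[str, dict[str, float]]
    coexpression_hits: pd.DataFrame | None
    response_tests: dict[str, float] | None
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        payload = {k: getattr(self, k) for k in
                   ("cluster_sizes", "covariance_family", "characterization",
                    "ceg_count", "per_cluster_deg_counts", "score_summary",
                    "cutpoint", "survival", "coexpression_hits",
                    "response_tests", "manifest")}
        return json.dumps(payload, default=default, indent=2, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31 - 1))


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        expr, clinical, gene_sets, truth = generate_cohort(syn)
        return expr, clinical, gene_sets["panel"], gene_sets["signatures"], truth
    expr = read_expression(config.expression_path,
                           "csv" if str(config.expression_path).endswith(".csv") else "tsv")
    clinical = read_clinical(config.clinical_path)
    panel = read_panel_gmt(config.panel_path) if config.panel_path else RegulatorPanel()
    sigs = read_gmt(config.signatures_gmt_path) if config.signatures_gmt_path else []
    return expr, clinical, panel, sigs, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def persist(name: str, df: pd.DataFrame) -> None:
        if out_dir is not None:
            df.to_csv(out_dir / f"{name}.tsv", sep="\t")

    expr, clinical, panel, signature_sets, truth = _load_inputs(config)
    clinical, expr = clinical.join_expression(expr)
    logger.info("post-join cohort size: %d samples", expr.n_samples)
    if out_dir:
        write_expression(expr, out_dir / "expression.tsv")
        write_clinical(clinical, out_dir / "clinical.csv")

    # --- regulation patterns
    panel_expr = expr.restrict_genes(panel.genes)
    assignment = fit_model_clusters(panel_expr, K=config.K,
                                    seed=_stage_seed(config.seed, "cluster"))
    labels = assignment.as_series()
    persist("cluster_labels", labels.to_frame())
    cluster_sizes = labels.value_counts().sort_index().to_dict()

    # --- characterization of the patterns on the panel genes
    characterization = characterize_clusters(panel_expr.data.T, labels.to_numpy())
    persist("characterization", characterization)

    # --- signature scores
    if config.signature_table_path:
        signatures = ingest_signature_table(config.signature_table_path, expr.sample_ids)
        signature_source = "ingested"
    elif signature_sets:
        signatures = score_matrix(expr, signature_sets, alpha=config.alpha,
                                  normalize=config.normalize_signatures)
        signature_source = "ssgsea"
    else:
        signatures = None
        signature_source = "none"
    if signatures is not None:
        persist("signature_scores", signatures)

    # --- DEG screen and CEG intersection
    deg_tables = [cluster_degs(expr, labels.to_numpy(), c, config.p_threshold,
                               config.fc_threshold)
                  for c in sorted(labels.unique())]
    cegs = intersect_cegs(deg_tables)
    if out_dir:
        for c, t in zip(sorted(labels.unique()), deg_tables):
            persist(f"deg_cluster{c}", t)
        (out_dir / "ceg.txt").write_text("\n".join(sorted(cegs.members)) + "\n")
    if len(cegs.members) < 2:
        raise RuntimeError("stage deg: fewer than 2 CEGs; cannot build the score")

    # --- gene clusters on the CEGs (stability check)
    ceg_expr = expr.restrict_genes(sorted(cegs.members))
    gene_clusters = consensus_cluster(ceg_expr, K=config.K,
                                      n_resamples=config.consensus_resamples,
                                      seed=_stage_seed(config.seed, "consensus"))
    persist("gene_clusters", gene_clusters.as_series().to_frame())

    # --- score + dichotomization
    score_table = compute_m6ascore(ceg_expr)
    score_table = dichotomize(score_table, clinical, config.min_group_frac)
    persist("m6ascore", score_table.table)
    scores = score_table.scores

    # --- survival
    t = clinical.data["pfs_time"].to_numpy(dtype=float)
    e = clinical.data["pfs_event"].to_numpy(dtype=int)
    survival: dict[str, dict[str, float]] = {}
    chi2, p = logrank_test(t, e, labels.to_numpy())
    survival["pattern_clusters"] = {"chi2": chi2, "p": p}
    group = score_table.groups.loc[clinical.sample_ids]
    chi2, p = logrank_test(t, e, group.to_numpy())
    cox = univariate_cox(t, e, scores.loc[clinical.sample_ids].to_numpy())
    survival["score_groups"] = {"chi2": chi2, "p": p}
    survival["score_cox"] = {"hr": cox.hr, "p": cox.p,
                             "ci_low": cox.ci95[0], "ci_high": cox.ci95[1]}

    # --- co-expression screen
    coexp_hits = None
    if signatures is not None:
        screen_regs = [g for g in DEFAULT_SCREEN_REGULATORS if g in expr.data.index]
        coexp = run_multicoexp(expr, signatures, cegs.members, regulators=screen_regs,
                               frac=config.frac, n_reps=config.n_reps,
                               seed=_stage_seed(config.seed, "coexpression"))
        persist("coexpression_triples", coexp.triples)
        coexp_hits = coexp.hits()

    # --- response evaluation
    response_tests = None
    if "response" in clinical.data.columns and clinical.data["response"].notna().any():
        response_tests = evaluate_response(scores, group, clinical)
        persist("response_tests", pd.DataFrame([response_tests]))

    report = RunReport(
        cluster_sizes=cluster_sizes,
        covariance_family=assignment.covariance_family,
        characterization=characterization,
        ceg_count=len(cegs.members),
        per_cluster_deg_counts=cegs.per_cluster_counts,
        score_summary={"mean": float(scores.mean()), "sd": float(scores.std()),
                       "n_high": int((group == "high").sum()),
                       "n_low": int((group == "low").sum())},
        cutpoint=float(score_table.cutpoint),
        survival=survival,
        coexpression_hits=coexp_hits,
        response_tests=response_tests,
        manifest={
            "seed": config.seed,
            "version": __version__,
            "n_samples": expr.n_samples,
            "n_genes": expr.n_genes,
            "signature_source": signature_source,
            "parameters": {
                "K": config.K, "alpha": config.alpha,
                "p_threshold": config.p_threshold, "fc_threshold": config.fc_threshold,
                "frac": config.frac, "n_reps": config.n_reps,
                "min_group_frac": config.min_group_frac,
            },
        },
    )
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report


def evaluate_response(scores: pd.Series, groups: pd.Series,
                      clinical: ClinicalTable) -> dict[str, float]:
    """Group-vs-response contingency test plus responder ROC of the score."""
    response = clinical.data["response"]
    common = response.dropna().index.intersection(scores.index)
    table = response_rate_table(groups.loc[common], response.loc[common])
    out: dict[str, float] = {}
    if table.shape == (2, 2) and (table.to_numpy() > 0).all(axis=1).all():
        chi2, p = contingency_test(table.to_numpy(), method="chi2")
        out["group_response_chi2"] = chi2
        out["group_response_p"] = p
        rates = table["responder"] / table.sum(axis=1)
        out["response_rate_high"] = float(rates.get("high", np.nan))
        out["response_rate_low"] = float(rates.get("low", np.nan))
    binary = binarize_response(response.loc[common])
    if binary.nunique() == 2:
        roc = roc_auc(scores.loc[common].to_numpy(), binary.to_numpy(),
                      positive_direction="lower")
        out["auc_lower_score_responds"] = roc.auc
        out["auc_ci_low"], out["auc_ci_high"] = roc.ci95
    return out


def compare_groups_clinical(clinical: ClinicalTable, groups: pd.Series) -> pd.DataFrame:
    """Clinical-field tests between score groups.

    Categorical fields go through the auto chi-square/Fisher path; continuous
    fields (PSA) through the Wilcoxon rank-sum test.  Fields that are absent
    or degenerate are skipped with a note.  Long-format output.
    """
    df = clinical.data.loc[groups.index.intersection(clinical.data.index)]
    g = groups.loc[df.index]
    rows = []
    categorical = ["t_stage", "n_stage", "m_stage", "gleason", "immune_subtype", "response"]
    for fieldname in categorical:
        if fieldname not in df.columns:
            rows.append((fieldname, "absent", np.nan, np.nan))
            continue
        sub = pd.DataFrame({"g": g, "v": df[fieldname]}).dropna()
        table = pd.crosstab(sub["g"], sub["v"])
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append((fieldname, "degenerate", np.nan, np.nan))
            continue
        stat, p = contingency_test(table.to_numpy(), method="auto")
        rows.append((fieldname, "contingency", stat, p))
    if "psa" in df.columns:
        sub = pd.DataFrame({"g": g, "v": df["psa"]}).dropna()
        parts = [sub.loc[sub["g"] == lev, "v"] for lev in sub["g"].unique()]
        if len(parts) == 2 and all(len(x) >= 2 for x in parts):
            stat, p = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
            rows.append(("psa", "wilcoxon", float(stat), float(p)))
        else:
            rows.append(("psa", "degenerate", np.nan, np.nan))
    else:
        rows.append(("psa", "absent", np.nan, np.nan))
    return pd.DataFrame(rows, columns=["field", "test", "statistic", "p"])
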