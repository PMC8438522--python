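"""Synthetic tumor cohorts with the statistical structure the analysis assumes.

A cohort is built from three latent regulation patterns.  Marker regulators
carry prescribed per-cluster mean shifts on the log2 scale (cluster 3 high
METTL14/ZC3H13 and low KIAA1429/HNRNPA2B1, cluster 2 the reverse, and
IGF2BP1/IGF2BP3/YTHDF1 lowest in cluster 3); a block of cluster-linked
co-expressed genes (CEGs) carries shifts ordered cluster 3 > cluster 1 >
cluster 2, so the derived PCA score reproduces the pattern ordering; immune
signature genes carry cluster-linked activity (Th1/Th17 highest in cluster 3,
Th2 highest in cluster 2); the remaining genes are null.  Noise is i.i.d.
Gaussian on the log2 scale.

Survival is exponential with hazard proportional to exp(-hazard_beta *
true_score) — high score, better progression-free survival — with
independent censoring (each sample censored with probability
``censor_rate`` at a uniform fraction of its event time).  Responder status
is Bernoulli with logit = intercept + response_beta * true_score; the default
``response_beta`` is negative, making the low-score stratum the responsive
one, and responders/non-responders are spread over CR/PR and SD/PD.

``true_score`` is exactly the PCA score the pipeline would compute on the
noiseless CEG means: with every CEG carrying the same standardized
cluster profile z, the score is sqrt(n_ceg) * z per sample.  That identity is
part of the module contract and is asserted in the test suite.

The moderator scenario plants an interaction: the coupling between one
regulator and one signature's genes scales linearly with a designated
moderator gene, so the regulator-signature correlation within a subsample is
a monotone function of the moderator's subsample level — the structure the
multiple co-expression screen is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ClinicalTable, ExpressionMatrix, GeneSet, RegulatorPanel

N_CLUSTERS = 3

#: Per-cluster log2 mean shifts of the seven marker regulators (clusters 1, 2, 3).
DEFAULT_REGULATOR_EFFECTS: dict[str, tuple[float, float, float]] = {
    "METTL14": (-1.0, 0.0, 1.0),
    "ZC3H13": (-1.0, 0.0, 1.0),
    "KIAA1429": (0.0, 1.0, -1.0),
    "HNRNPA2B1": (0.0, 1.0, -1.0),
    "IGF2BP1": (0.5, 1.0, -1.0),
    "IGF2BP3": (0.5, 1.0, -1.0),
    "YTHDF1": (0.5, 1.0, -1.0),
}

#: Per-cluster activity shifts of the immune signatures.
DEFAULT_SIGNATURE_LINK: dict[str, tuple[float, float, float]] = {
    "Th1 cells": (0.0, -1.0, 1.0),
    "Th17 cells": (0.0, -1.0, 1.0),
    "Th2 cells": (0.0, 1.0, -1.0),
}

#: CEG per-cluster shifts, in units of ``ceg_effect`` (ordering c3 > c1 > c2).
CEG_PROFILE = (0.0, -1.0, 1.0)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_cluster: tuple[int, int, int] = (157, 36, 212)
    regulator_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGULATOR_EFFECTS))
    n_ceg: int = 54
    ceg_effect: float = 1.5
    n_background: int = 200
    noise_sd: float = 0.5
    signature_link: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_LINK))
    n_signature_genes: int = 15
    hazard_beta: float = 0.08
    baseline_hazard: float = 7e-4          # events/day; median ~ 1000 days at score 0
    censor_rate: float = 0.3
    response_beta: float = -0.12
    response_intercept: float = -0.5
    stage_link: float = 0.8                # log-odds of low stage in cluster 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) != N_CLUSTERS:
            raise ConfigError("the design has exactly 3 regulation patterns")
        if any(n < 0 for n in self.n_per_cluster):
            raise ConfigError("cluster sizes must be >= 0")
        if self.n_ceg < 0 or self.n_background < 0 or self.n_signature_genes < 0:
            raise ConfigError("gene counts must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError("censor_rate must be in [0, 1]")
        for gene, eff in self.regulator_effects.items():
            if len(eff) != N_CLUSTERS:
                raise ConfigError(f"regulator effect for {gene} must have 3 entries")
        for sig, eff in self.signature_link.items():
            if len(eff) != N_CLUSTERS:
                raise ConfigError(f"signature link for {sig} must have 3 entries")

    def null(self) -> "CohortConfig":
        """Same cohort geometry with every planted effect removed."""
        return replace(
            self,
            regulator_effects={g: (0.0, 0.0, 0.0) for g in self.regulator_effects},
            ceg_effect=0.0,
            signature_link={s: (0.0, 0.0, 0.0) for s in self.signature_link},
            hazard_beta=0.0, response_beta=0.0, stage_link=0.0)


@dataclass
class SyntheticTruth:
    true_cluster: pd.Series          # per-sample label 1..3
    true_score: pd.Series            # oracle PCA score
    planted_moderator_genes: list[str]
    config: CohortConfig

    def __post_init__(self) -> None:
        if len(self.true_cluster) != len(self.true_score):
            raise ValueError("truth vectors must align")


def oracle_true_score(config: CohortConfig, cluster_labels: np.ndarray) -> np.ndarray:
    """Closed-form PCA score of the noiseless CEG block.

    Every CEG shares the cluster profile ``ceg_effect * CEG_PROFILE``; after
    per-gene standardization the score reduces to sqrt(n_ceg) times the
    standardized profile value of each sample's cluster.
    """
    shifts = config.ceg_effect * np.asarray(CEG_PROFILE)
    per_sample = shifts[cluster_labels - 1].astype(float)
    sd = per_sample.std()
    if sd == 0 or config.n_ceg == 0:
        return np.zeros(len(per_sample))
    z = (per_sample - per_sample.mean()) / sd
    return np.sqrt(config.n_ceg) * z


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_cohort(config: CohortConfig):
    """Generate ``(ExpressionMatrix, ClinicalTable, gene_sets, SyntheticTruth)``.

    ``gene_sets`` is a dict with the regulator panel under ``"panel"``, one
    :class:`GeneSet` per immune signature under ``"signatures"`` and the CEG
    ID list under ``"cegs"``.  Byte-identical outputs for identical
    config + seed.
    """
    rng = np.random.default_rng(config.seed)
    n = sum(config.n_per_cluster)
    clusters = np.repeat([1, 2, 3], config.n_per_cluster)
    rng.shuffle(clusters)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    panel = RegulatorPanel()
    ceg_names = _gene_names("CEG", config.n_ceg)
    sig_gene_map = {
        sig: [f"{sig.split()[0].upper()}G{i + 1:03d}" for i in range(config.n_signature_genes)]
        for sig in config.signature_link
    }
    bg_names = _gene_names("BG", config.n_background)
    gene_ids = (panel.genes + ceg_names
                + [g for genes in sig_gene_map.values() for g in genes] + bg_names)

    baselines = rng.uniform(4.0, 10.0, size=len(gene_ids))
    mean_grid = np.tile(baselines[:, None], (1, n))
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    cl_idx = clusters - 1
    for gene, eff in config.regulator_effects.items():
        if gene in gene_index:
            mean_grid[gene_index[gene]] += np.asarray(eff)[cl_idx]
    ceg_shifts = config.ceg_effect * np.asarray(CEG_PROFILE)[cl_idx]
    for g in ceg_names:
        mean_grid[gene_index[g]] += ceg_shifts
    for sig, eff in config.signature_link.items():
        shift = np.asarray(eff)[cl_idx]
        for g in sig_gene_map[sig]:
            mean_grid[gene_index[g]] += shift

    values = mean_grid + rng.normal(0.0, config.noise_sd, size=mean_grid.shape)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    true_score = oracle_true_score(config, clusters)
    clinical = _generate_clinical(config, rng, sample_ids, clusters, true_score)

    gene_sets = {
        "panel": panel,
        "signatures": [GeneSet(sig, "synthetic immune signature", frozenset(genes))
                       for sig, genes in sig_gene_map.items()],
        "cegs": list(ceg_names),
    }
    truth = SyntheticTruth(
        true_cluster=pd.Series(clusters, index=sample_ids, name="true_cluster"),
        true_score=pd.Series(true_score, index=sample_ids, name="true_score"),
        planted_moderator_genes=[], config=config)
    return expr, clinical, gene_sets, truth


def _generate_clinical(config, rng, sample_ids, clusters, true_score) -> ClinicalTable:
    n = len(sample_ids)
    hazard = config.baseline_hazard * np.exp(-config.hazard_beta * true_score)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    obs_time = np.where(censored, event_time * rng.random(n), event_time)
    obs_time = np.maximum(obs_time, 1e-3)
    event = (~censored).astype(int)

    logit = config.response_intercept + config.response_beta * true_score
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    depth = rng.random(n)
    response = np.where(responder, np.where(depth < 0.4, "CR", "PR"),
                        np.where(depth < 0.4, "SD", "PD"))

    # staging / grade / PSA with a mild cluster link (cluster 3 less advanced,
    # cluster 2 most advanced), strength controlled by stage_link
    link = config.stage_link * np.select([clusters == 3, clusters == 2], [1.0, -1.0], 0.0)
    p_t1 = 1.0 / (1.0 + np.exp(-(-0.3 + link)))
    u = rng.random(n)
    t_stage = np.where(u < p_t1, "T1", np.where(u < p_t1 + 0.35, "T2", "T3"))
    n_stage = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-(-1.8 + link))), "N1", "N0")
    m_stage = np.where((clusters == 2) & (rng.random(n) < 0.08 * np.sign(config.stage_link)),
                       "M1", "M0")
    gleason = np.clip(np.round(rng.normal(7.0 - 0.4 * link, 1.0)), 6, 10).astype(int)
    psa = np.round(np.exp(rng.normal(2.0 - 0.3 * link, 0.6)), 2)
    subtype_p = 1.0 / (1.0 + np.exp(-(0.8 + 1.5 * link)))
    immune_subtype = np.where(rng.random(n) < subtype_p, "C3",
                              rng.choice(["C1", "C2", "C4"], size=n))
    df = pd.DataFrame({
        "pfs_time": np.round(obs_time, 2),
        "pfs_event": event,
        "t_stage": t_stage,
        "n_stage": n_stage,
        "m_stage": m_stage,
        "gleason": gleason,
        "psa": psa,
        "immune_subtype": immune_subtype,
        "response": response,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return ClinicalTable(df)


def generate_moderator_scenario(config: CohortConfig, regulator: str = "HNRNPA2B1",
                                signature: str = "Th1 cells", moderator: str = "MSMB",
                                base_coupling: float = 0.6, moderation: float = 1.0,
                                direct_effect: float = 1.0):
    """Cohort with a planted moderator of a regulator-signature correlation.

    The moderator gene is appended to the CEG list with unit-variance
    expression; each gene of ``signature`` becomes

        baseline + (base_coupling + moderation * m) * r + direct_effect * m + noise

    with ``m`` the standardized moderator and ``r`` the standardized
    regulator.  The interaction term makes the within-subsample correlation
    r1 between regulator and signature score rise (or fall, for negative
    ``moderation``) with the subsample's moderator level — the structure the
    resampling screen detects.  The direct term makes high-moderator samples
    score higher within *each* regulator stratum of a median split, the
    attenuation pattern the 2x2 contrast visualizes.  ``moderation = 0`` is
    the null scenario.
    """
    if signature not in config.signature_link:
        raise ConfigError(f"unknown signature {signature!r}")
    expr, clinical, gene_sets, truth = generate_cohort(config)
    rng = np.random.default_rng(config.seed + 987_654)
    n = expr.n_samples

    m_raw = rng.normal(6.0, 1.0, size=n)
    m = (m_raw - m_raw.mean()) / m_raw.std()
    r_raw = expr.data.loc[regulator].to_numpy()
    r = (r_raw - r_raw.mean()) / r_raw.std()

    sig_set = next(gs for gs in gene_sets["signatures"] if gs.name == signature)
    coupling = base_coupling + moderation * m
    data = expr.data.copy()
    baselines = rng.uniform(4.0, 10.0, size=len(sig_set.members))
    for b, g in zip(baselines, sorted(sig_set.members)):
        data.loc[g] = (b + coupling * r + direct_effect * m
                       + rng.normal(0.0, config.noise_sd, size=n))
    data.loc[moderator] = m_raw
    expr = ExpressionMatrix(data)
    gene_sets["cegs"] = gene_sets["cegs"] + [moderator]
    truth.planted_moderator_genes = [moderator]
    return expr, clinical, gene_sets, truth
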