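# m6apattern

Tools for studying how N6-methyladenosine (m6A) regulation shapes the tumor
immune microenvironment and the response to immune-checkpoint blockade, built
for bulk tumor expression cohorts such as TCGA prostate cancer.

m6A is a reversible mRNA methylation mark controlled by a 24-gene panel of
*writers* (methyltransferases: WTAP, KIAA1429, CBLL1, RBM15, RBM15B, ZC3H13,
METTL3, METTL14), *erasers* (demethylases: FTO, ALKBH5) and *readers*
(binding proteins such as YTHDF1-3, IGF2BP1-3, HNRNPA2B1). The package
implements the full analysis that turns that panel into a per-patient
prognostic and predictive score:

1. **Regulation patterns** — Gaussian-mixture (model-based) clustering of
   samples on the z-scored panel, with BIC selection over covariance
   families, and a Kruskal–Wallis + Dunn *highest / lowest / median*
   characterization of each pattern.
2. **Co-expressed genes (CEGs)** — a moderated one-vs-rest t screen per
   pattern (empirical-Bayes shrunken variances, `p < 0.05` and
   `|fold change| > 2`), intersected across patterns.
3. **m6Ascore** — per-sample sum of the first two principal-component
   projections of standardized CEG expression,
   `score_i = PC1_i + PC2_i`, with deterministic sign orientation;
   dichotomized into high/low groups by the maximally selected log-rank
   statistic against progression-free survival (PFS).
4. **Immune context** — per-sample ssGSEA scores for immune signatures
   (Th1/Th2/Th17 cells and Thorsson-style signature tables can be ingested
   directly), Kaplan–Meier / log-rank / univariate Cox survival machinery,
   and ROC/AUC with DeLong comparisons for immunotherapy response
   (CR/PR vs SD/PD).
5. **Multiple co-expression screen** — the resampling procedure that asks
   whether a CEG moderates a regulator–signature correlation: 100 draws of
   60% of the cohort, Spearman `r1` between regulator and signature within
   each draw (kept when `p < 0.05`), CEG medians per draw, then Spearman of
   medians against `r1` across draws.

A synthetic-cohort generator (`m6apattern.synthetic_cohort`) emulates the
statistical structure this analysis assumes — three latent regulation
patterns with prescribed marker shifts, cluster-linked CEGs and signature
activity, proportional-hazards survival tied to the score, and response
probabilities inversely tied to it — so the whole pipeline is testable
without any data download and ships with ground truth for recovery tests.

## Worked example

```python
from m6apattern.pipeline import PipelineConfig, run_pipeline
from m6apattern.synthetic_cohort import CohortConfig

report = run_pipeline(PipelineConfig(synthetic=CohortConfig(), seed=7,
                                     n_reps=25, consensus_resamples=20))
print(report.cluster_sizes)                      # {1: 39, 2: 212, 3: 154}
print(report.ceg_count)                          # 51
print(report.survival["score_groups"])           # {'chi2': 81.68, 'p': 1.6e-19}
print(report.survival["score_cox"]["hr"])        # 0.910
print(report.response_tests["response_rate_low"])   # 0.756
print(report.response_tests["response_rate_high"])  # 0.346
```

On this cohort the fitted mixture recovers the three planted regulation
patterns (labels are arbitrary; 212 samples land in the large pattern-3-like
cluster), 51 co-expressed genes survive the DEG intersection, and the
m6Ascore separates survival strongly: the high-score group progresses later
(log-rank χ² = 81.7, p ≈ 2·10⁻¹⁹; hazard ratio 0.91 per score unit, i.e.
higher score → lower hazard). The immunotherapy contrast runs the other way:
75.6% of low-score patients respond versus 34.6% of high-score patients —
the score is prognostic and inversely predictive of checkpoint-inhibitor
benefit.

The same stages are available from the shell:

```sh
m6apattern simulate --seed 7 --out cohort/
m6apattern cluster  --expr cohort/expression.tsv --k 3 --seed 7 --out clust/
m6apattern deg      --expr cohort/expression.tsv --labels clust/labels.tsv --out deg/
m6apattern score    --expr cohort/expression.tsv --ceg deg/ceg.txt \
                    --clinical cohort/clinical.csv --out scores.tsv
m6apattern run      --config run.yaml
```

## Layout

- `m6apattern.io_formats` — expression/GMT/clinical readers with validation
- `m6apattern.synthetic_cohort` — cohort generator and moderator scenarios
- `m6apattern.regulator_clustering` — GMM patterns, Dunn characterization, consensus clustering
- `m6apattern.signature_scoring` — ssGSEA and signature-table ingestion
- `m6apattern.deg_ceg` — moderated DEG screen and CEG intersection
- `m6apattern.m6ascore` — PCA score and survival dichotomization
- `m6apattern.survival_stats` — KM, log-rank, univariate Cox, maxstat cutpoint
- `m6apattern.coexpression_resampling` — the multiple co-expression screen
- `m6apattern.response_eval` — contingency tests, ROC/AUC, DeLong
- `m6apattern.pipeline` / `m6apattern.cli` — orchestration and the `m6apattern` command

See `docs/methods.md` for the statistical details and design choices.
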