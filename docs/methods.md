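# Methods

This note documents the statistical procedures, the synthetic study
conditions, and the numerical choices behind `m6apattern`.

## Regulation patterns (model-based clustering)

Samples are clustered on the 24-gene m6A regulator panel after z-scoring
each gene across samples. The model is a K-component Gaussian mixture fit by
EM; four covariance families are fit — spherical, diagonal, shared full
(tied) and per-cluster full — and the family with the best BIC is kept, a
compact analogue of the mclust family sweep. K defaults to 3 (the
three-pattern design this analysis is built around); other K are available
to library callers. EM details:

- initialization by k-means++; several restarts per family, best final
  likelihood kept;
- EM runs as warm-started single-iteration steps so the log-likelihood
  trajectory is recorded; its monotonicity is asserted in the test suite;
- a component collapsing below 2 members triggers a reseeded restart and,
  after 5 failures, an error;
- hard labels are argmax responsibilities, ties broken toward the lowest
  cluster index (determinism).

Pattern characterization uses a per-feature Kruskal–Wallis screen
(α = 0.05); on passing features, Dunn pairwise z-tests on the joint ranks
with Holm adjustment across the three pairs. A cluster is *highest* when its
median exceeds every other cluster and all of its pairwise tests are
significant; *lowest* symmetric; *median* when significantly above one
cluster and below the other; otherwise *ns*. At most one highest and one
lowest can exist per feature by construction.

Gene-level cluster stability is assessed with Monti-style consensus
clustering: repeated subsampling (default 80% of samples), k-means
partitioning per draw, and the co-clustering proportion among co-sampled
pairs; final labels cut an average-linkage tree of 1 − consensus. Pairs
never co-sampled get consensus 0.5 with a warning.

## DEG screen and co-expressed genes

Each pattern is contrasted one-vs-rest on log2 expression. The underlying
model is a per-gene linear model with one mean per cluster: the residual
variance pools within-cluster variation across all clusters
(df = n − K). This matters — pooling variance across the two contrast
groups instead would fold the between-cluster spread of the "rest" group
into the standard error and mask genuinely differential genes. Variances
are moderated by empirical Bayes: the prior (d0, s0²) is moment-matched on
the log-variance scale (digamma/trigamma inversion) and the posterior
variance is s²_post = (d0·s0² + df·s²)/(d0 + df) with df_total = d0 + df.

A gene passes for a cluster when p < 0.05 (unadjusted, matching the stated
rule; BH available behind a flag) and |fold change| > 2 on the linear scale
(|log2FC| > 1). The CEG set is the intersection of the per-cluster passing
sets; an empty intersection is valid but the score stage refuses it.

## The m6Ascore

CEG expression is standardized per gene and decomposed by PCA (eigendecomposition
of the sample covariance). The per-sample score is the sum of the
projections on the first two components. Because eigenvector signs are
arbitrary, each component is oriented so its largest-magnitude loading is
positive (first gene on ties); the orientation is recorded. With the
generator's CEG design (all CEGs sharing one cluster profile) PC1 aligns
with the pattern axis and the orientation rule makes the score increase
from pattern 2 through pattern 1 to pattern 3.

Dichotomization uses the maximally selected log-rank statistic: every
observed score value is a candidate cut (low group = score ≤ cut), splits
leaving either group under `min_group_frac` (default 0.1) are excluded, and
the argmax is returned with ties broken toward the smaller cut. No
Hothorn/Lausen correction of the post-selection p-value is applied: the
cutpoint is used descriptively and the reported log-rank p for the induced
groups is selection-biased, which callers should treat as such. Note that
the exhaustive scan can legitimately prefer off-center splits even on
cleanly separated data — the hypergeometric variance shrinks faster than
the observed-minus-expected term — so a balanced split can be enforced only
through `min_group_frac`.

## Survival machinery

- Kaplan–Meier: product-limit estimator (via lifelines), S(0) = 1.
- Log-rank: the classical observed-minus-expected quadratic form with
  hypergeometric variance, vectorized over distinct event times (it runs
  inside the cutpoint scan); k-group version with df = k − 1 via the
  pseudo-inverse of the (k−1)-dimensional covariance.
- Univariate Cox: Breslow tie convention, Newton–Raphson with step-halving
  on the partial likelihood, Wald CI and p. Breslow was chosen over Efron
  because the synthetic cohorts use continuous times (ties are rare) and
  Breslow admits a simple independent oracle. A standardized effect
  |beta|·sd(x) > 10 is reported as monotone likelihood (separation) with
  `converged=False`.

## ssGSEA

Genes are ranked by expression descending, ties broken by gene ID
(deterministic across platforms). The enrichment score accumulates, at each
rank position, the weighted in-set ECDF minus the uniform out-of-set ECDF;
in-set steps are weighted |r|^α where r is the descending rank statistic
(N…1) and α defaults to 0.25 (the original ssGSEA convention). With α = 0
the score is a pure rank statistic: invariant under monotone transforms and
exactly antisymmetric under rank reversal. Per-signature min–max
normalization across samples is optional and off by default. Scores used
downstream may instead come from an ingested table (e.g. published
CIBERSORT-derived signature scores); provenance is recorded in the run
manifest.

## Multiple co-expression screen

Per replicate (default 100): draw 60% of the cohort without replacement;
compute Spearman r1 between each screen regulator (default METTL14, ZC3H13,
IGF2BP1, KIAA1429, HNRNPA2B1, IGF2BP3, YTHDF1) and each signature score
within the draw, keeping r1 only when its p < 0.05 (the relevance rule; a
flag retains all); record each CEG's median expression in the draw. Then,
per (regulator, signature, CEG) triple, Spearman between the CEG's medians
and the r1 series across replicates. Replicates with filtered r1 are
dropped pairwise; triples with fewer than 10 valid replicates report no
correlation. No multiplicity correction across triples by default (BH via
flag). This is a correlational screen, not a causal mediation model.

Spearman p-values use the t approximation, except for small tie-free
samples (n ≤ 8) where the exact permutation null is enumerated; full
enumeration beyond that is computationally out of reach and the
approximation is accurate there.

## Response evaluation

RECIST categories collapse to responder = CR/PR (configurable). Group-vs-
outcome tables use chi-square (df = (r−1)(c−1), no continuity correction)
or, for sparse 2×2 tables, Fisher's exact test with the two-sided
"sum of no-more-likely tables" convention. AUC is the trapezoid area under
the empirical ROC (equal to the Mann–Whitney pair-counting probability with
half-weight ties); `positive_direction="lower"` scores markers whose low
values predict response, the direction the m6Ascore shows under checkpoint
blockade. DeLong's structural-components covariance provides AUC confidence
intervals (logit scale near the boundaries to stay inside [0, 1]) and the
paired-AUC z-test; identical scores take a degenerate path (difference 0,
p = 1).

## Synthetic study conditions

The default cohort emulates the structure the analysis assumes:

- **Sizes:** 157 / 36 / 212 samples in patterns 1–3 (405 total).
- **Markers** (log2 shifts per pattern 1/2/3): METTL14 and ZC3H13 (−1, 0, +1);
  KIAA1429 and HNRNPA2B1 (0, +1, −1); IGF2BP1, IGF2BP3, YTHDF1
  (+0.5, +1, −1) — pattern 3 high in METTL14/ZC3H13, low in the rest, and
  pattern 2 the reverse. The other 17 panel genes are null.
- **CEGs:** 54 genes with shifts (0, −1.5, +1.5)·(pattern 1/2/3). The ±1.5
  magnitude is the smallest round value whose one-vs-rest fold changes clear
  the |log2FC| > 1 gate in *all three* contrasts at the default size ratios
  (the pattern-1 contrast is the binding one at ≈ −1.06); it also orders the
  true score pattern 3 > 1 > 2. Cohorts with very different size ratios can
  push the pattern-1 contrast under the gate — that is a property of the
  one-vs-rest design, not a bug.
- **Signatures:** 15 genes each for Th1/Th17 (0, −1, +1) and Th2
  (0, +1, −1); 200 null background genes; i.i.d. Gaussian noise, sd 0.5
  log2 units; per-gene baselines uniform on [4, 10] log2.
- **True score:** defined as the PCA score of the noiseless CEG block,
  which reduces to √n_ceg times the standardized pattern profile; the test
  suite asserts this identity against `compute_m6ascore`.
- **Survival:** exponential with hazard 7·10⁻⁴·exp(−0.08·true_score)
  events/day (median ≈ 1000 days at score 0); censoring is an independent
  Bernoulli(0.3) with uniform back-dating, so the realized censor fraction
  is binomial around 30%. The score sd is ≈ 7, so the planted
  prognostic effect is strong and clearly directional.
- **Response:** responder ~ Bernoulli with logit −0.5 − 0.12·true_score —
  low score responds more; responders split CR/PR 40/60, non-responders
  SD/PD 40/60.
- **Clinical covariates:** T/N/M stage, Gleason and PSA get a mild
  pattern link (pattern 3 less advanced, pattern 2 most advanced, log-odds
  0.8) mirroring the qualitative staging contrasts such cohorts show.

The **moderator scenario** rewrites one signature's genes as
baseline + (0.6 + 1.0·m)·r + 1.0·m + noise, with r the standardized
regulator (default HNRNPA2B1) and m a standardized planted moderator gene
(named MSMB after the motivating example). The base coupling 0.6 keeps the
within-draw r1 routinely significant (so the relevance filter retains it);
the interaction slope 1.0 defines the "strong moderation" condition the
screen must recover; the direct term makes high-moderator samples score
higher within each half of a regulator median split, the attenuation
pattern the 2×2 contrast displays. Setting the slope to 0 (and, for
calibration studies, using the effect-free `CohortConfig.null()` cohort)
gives the null condition. On the *default* cohort the CEGs and regulators
are both pattern-linked, so subsample composition genuinely couples CEG
medians to r1 — null-calibration checks therefore use the effect-free
cohort, where no such confounding exists.

What the generator does **not** emulate: batch effects, heavy-tailed or
count-scale noise, correlated gene-gene structure beyond the planted
blocks, informative censoring, and cohort heterogeneity between discovery
and immunotherapy populations. Passing recovery tests on these cohorts
demonstrates the pipeline's correctness and calibration under its own
assumptions, not robustness to those real-data complications.

## Problem sizes in the test suite

The acceptance tests run the oracle comparisons at the sizes stated in
their docstrings (50 ssGSEA instances, 100 maxstat instances at n ≤ 60,
2000 null log-rank cohorts at n = 100, 100 Cox cohorts at n = 400, 1000
DeLong null comparisons, 100 seeded moderator cohorts, 100 seeded
direction-reproduction runs at n = 405). These sizes give the binomial
bands quoted in the tests (e.g. ±1.5 points on a 5% rejection rate at
2000 draws) while keeping the default suite fast on a single CPU.

## Known limitations

- The maxstat p-value is not corrected for cutpoint selection.
- The DEG screen offers no covariate adjustment or expression filtering;
  input matrices are assumed normalized and log2-scale (a log2(x+1) flag
  exists for raw-scale input).
- The co-expression screen's relevance filter discards replicates pairwise;
  with weak regulator-signature coupling this can leave too few replicates
  and the triple is reported as missing rather than estimated.
- k-group log-rank uses the chi-square reference; exact small-sample
  inference is available only implicitly through the oracles in the tests.
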