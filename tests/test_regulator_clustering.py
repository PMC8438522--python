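"""Mixture-model clustering, the highest/lowest/median rule, consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from m6apattern.io_formats import ExpressionMatrix
from m6apattern.regulator_clustering import (characterize_clusters,
                                             consensus_cluster, dunn_posthoc,
                                             fit_model_clusters)


def _matrix(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])]))


class TestFitModelClusters:
    def test_separated_clouds_perfect_recovery(self):
        rng = np.random.default_rng(0)
        centers = np.array([0.0, 10.0])
        truth = np.repeat([0, 1], 30)
        X = rng.normal(size=(4, 60)) + centers[truth]
        a = fit_model_clusters(_matrix(X), K=2, seed=1, min_panel_genes=2,
                               standardize=False)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_single_component_bic_matches_closed_form(self):
        """K=1 full-covariance BIC equals the Gaussian MLE BIC computed from
        first principles (log-likelihood of N(mean, cov_mle), parameter count
        d + d(d+1)/2)."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3, 40))
        a = fit_model_clusters(_matrix(X), K=1, families=("full",), seed=0,
                               min_panel_genes=2, standardize=False)
        data = X.T
        n, d = data.shape
        mu = data.mean(axis=0)
        cov = (data - mu).T @ (data - mu) / n + 1e-6 * np.eye(d)
        ll = stats.multivariate_normal(mu, cov).logpdf(data).sum()
        k_params = d + d * (d + 1) // 2
        bic_oracle = -2.0 * ll + k_params * np.log(n)
        assert abs(a.model_bic - bic_oracle) < 1e-6

    def test_recovers_planted_patterns(self, default_cohort):
        expr, _, gene_sets, truth = default_cohort
        panel = expr.restrict_genes(gene_sets["panel"].genes)
        a = fit_model_clusters(panel, K=3, seed=2)
        assert adjusted_rand_score(truth.true_cluster, a.labels) >= 0.9

    def test_loglik_nondecreasing_and_responsibilities_proper(self, default_cohort):
        expr, _, gene_sets, _ = default_cohort
        panel = expr.restrict_genes(gene_sets["panel"].genes)
        a = fit_model_clusters(panel, K=3, seed=3)
        ll = np.asarray(a.loglik_trajectory)
        assert (np.diff(ll) >= -1e-9).all()
        np.testing.assert_allclose(a.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(a.labels, a.responsibilities.argmax(axis=1) + 1)

    def test_deterministic_given_seed(self, default_cohort):
        expr, _, gene_sets, _ = default_cohort
        panel = expr.restrict_genes(gene_sets["panel"].genes)
        a = fit_model_clusters(panel, K=3, seed=4)
        b = fit_model_clusters(panel, K=3, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.covariance_family == b.covariance_family

    def test_too_few_samples_rejected(self):
        X = np.zeros((2, 10))
        with pytest.raises(ValueError, match="samples"):
            fit_model_clusters(_matrix(X), K=3, min_panel_genes=2)


class TestCharacterize:
    def test_fully_separated_ranks(self):
        values = pd.DataFrame({"f": np.arange(1.0, 31.0)})
        labels = np.repeat([1, 2, 3], 10)
        out = characterize_clusters(values, labels)
        lab = out.set_index("cluster")["label"]
        assert lab[1] == "lowest" and lab[2] == "median" and lab[3] == "highest"

    def test_identical_groups_all_ns(self):
        values = pd.DataFrame({"f": np.ones(30)})
        labels = np.repeat([1, 2, 3], 10)
        out = characterize_clusters(values, labels)
        assert (out["label"] == "ns").all()
        assert (out["kw_p"] == 1.0).all()

    def test_kw_statistic_direct_rank_formula(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: H = 7.2 by the rank-sum formula, so
        the stored p must equal chi2.sf(7.2, df=2)."""
        values = pd.DataFrame({"f": np.arange(1.0, 10.0)})
        labels = np.repeat([1, 2, 3], 3)
        out = characterize_clusters(values, labels)
        assert np.isclose(out["kw_p"].iloc[0], stats.chi2.sf(7.2, df=2))

    def test_at_most_one_highest_and_lowest(self, default_cohort):
        expr, _, gene_sets, truth = default_cohort
        panel = expr.restrict_genes(gene_sets["panel"].genes)
        out = characterize_clusters(panel.data.T, truth.true_cluster.to_numpy())
        per_feature = out.groupby("feature")["label"]
        assert (per_feature.apply(lambda s: (s == "highest").sum()) <= 1).all()
        assert (per_feature.apply(lambda s: (s == "lowest").sum()) <= 1).all()

    def test_recovers_planted_marker_labels(self, default_cohort):
        expr, _, gene_sets, truth = default_cohort
        panel = expr.restrict_genes(gene_sets["panel"].genes)
        out = characterize_clusters(panel.data.T, truth.true_cluster.to_numpy())
        lab = out.set_index(["feature", "cluster"])["label"]
        assert lab[("METTL14", 3)] == "highest"
        assert lab[("METTL14", 1)] == "lowest"
        assert lab[("HNRNPA2B1", 2)] == "highest"
        assert lab[("HNRNPA2B1", 3)] == "lowest"

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame({"f": rng.normal(size=60) + np.repeat([0, 2, 4], 20)})
        labels = np.repeat([1, 2, 3], 20)
        out1 = characterize_clusters(values, labels)
        perm = {1: 3, 2: 1, 3: 2}
        out2 = characterize_clusters(values, np.vectorize(perm.get)(labels))
        m1 = out1.set_index("cluster")["label"]
        m2 = out2.set_index("cluster")["label"]
        for c in (1, 2, 3):
            assert m1[c] == m2[perm[c]]

    def test_dunn_pairwise_count(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        out = dunn_posthoc(x, np.repeat([1, 2, 3], 10))
        assert len(out) == 3  # three pairwise comparisons


class TestConsensus:
    def test_separated_blobs_binary_consensus(self):
        rng = np.random.default_rng(1)
        truth = np.repeat([0, 1], 15)
        X = rng.normal(scale=0.1, size=(5, 30)) + 10.0 * truth
        a = consensus_cluster(_matrix(X), K=2, n_resamples=50, seed=0)
        c = a.consensus
        within = c[np.ix_(truth == 0, truth == 0)]
        between = c[np.ix_(truth == 0, truth == 1)]
        assert np.allclose(within, 1.0)
        assert np.allclose(between, 0.0)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_symmetric_unit_diagonal(self, default_cohort):
        expr, _, gene_sets, _ = default_cohort
        sub = expr.restrict_genes(gene_sets["cegs"][:10]).restrict_samples(
            expr.sample_ids[:60])
        a = consensus_cluster(sub, K=3, n_resamples=20, seed=1)
        assert np.allclose(a.consensus, a.consensus.T)
        assert np.allclose(np.diag(a.consensus), 1.0)

    def test_null_mean_consensus_near_half(self):
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(8, 40))
            a = consensus_cluster(_matrix(X), K=2, n_resamples=60, seed=seed)
            off = a.consensus[~np.eye(40, dtype=bool)]
            means.append(off.mean())
        assert abs(np.mean(means) - 0.5) < 0.1
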