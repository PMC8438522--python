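"""KM / log-rank / Cox / maxstat against hand-rolled oracles and lifelines."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy.optimize import minimize_scalar

import pandas as pd

from conftest import random_survival
from m6apattern.survival_stats import (km_estimate, logrank_test,
                                       maxstat_cutpoint, univariate_cox)


def km_product_oracle(time, event):
    """Direct product over risk sets."""
    times = np.sort(np.unique(time[event == 1]))
    s, out = 1.0, []
    for t in times:
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_risk
        out.append((t, s))
    return out


def logrank_sum_oracle(time, event, group):
    """Direct O-E / hypergeometric-variance sums for two groups."""
    labels = np.unique(group)
    o_minus_e, var = 0.0, 0.0
    for t in np.sort(np.unique(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == labels[1])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[1])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0


def cox_partial_loglik(beta, time, event, x):
    """Direct O(n^2) Breslow partial log-likelihood."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestKM:
    def test_all_events_closed_form(self):
        t, s = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(s[np.searchsorted(t, [1, 2, 3])],
                                   [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_all_censored_flat_at_one(self):
        _, s = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        np.testing.assert_array_equal(s, np.ones_like(s))

    def test_matches_product_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            time, event, _ = random_survival(rng, 25)
            t, s = km_estimate(time, event)
            for et, es in km_product_oracle(time, event):
                assert s[np.searchsorted(t, et)] == pytest.approx(es, abs=1e-12)

    def test_curve_starts_at_one_non_increasing(self):
        rng = np.random.default_rng(1)
        time, event, _ = random_survival(rng, 50)
        t, s = km_estimate(time, event)
        assert s[0] == 1.0 and t[0] == 0.0
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.repeat([0, 1], 4)
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            time, event, _ = random_survival(rng, 40)
            group = rng.integers(0, 2, size=40)
            if event.sum() == 0 or len(np.unique(group)) < 2:
                continue
            chi2, _ = logrank_test(time, event, group)
            assert chi2 == pytest.approx(logrank_sum_oracle(time, event, group),
                                         abs=1e-10)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        time, event, x = random_survival(rng, 80, beta=0.7)
        group = (x > 0).astype(int)
        chi2, p = logrank_test(time, event, group)
        ref = ll_logrank(time[group == 0], time[group == 1],
                         event[group == 0], event[group == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        time, event, _ = random_survival(rng, 50)
        group = rng.integers(0, 2, size=50)
        chi2_a, _ = logrank_test(time, event, group)
        chi2_b, _ = logrank_test(np.log1p(time), event, group)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-12)

    def test_three_group_statistic_df(self):
        rng = np.random.default_rng(5)
        time, event, _ = random_survival(rng, 90)
        group = np.repeat([0, 1, 2], 30)
        chi2, p = logrank_test(time, event, group)
        from scipy import stats
        assert p == pytest.approx(stats.chi2.sf(chi2, df=2))

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test([1.0, 2.0], [0, 0], [0, 1])
        assert p == 1.0


class TestCox:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        time, event, x = random_survival(rng, 60, beta=0.8)
        r1 = univariate_cox(time, event, x)
        r2 = univariate_cox(time, event, 2.0 * x)
        assert r1.beta == pytest.approx(2.0 * r2.beta, rel=1e-6)

    def test_matches_brute_force_likelihood_maximum(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            time, event, x = random_survival(rng, 30, beta=0.5)
            res = univariate_cox(time, event, x)
            brute = minimize_scalar(
                lambda b: -cox_partial_loglik(b, time, event, x),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-8})
            assert res.beta == pytest.approx(brute.x, abs=1e-4)

    def test_matches_lifelines_tie_free(self):
        rng = np.random.default_rng(8)
        time, event, x = random_survival(rng, 120, beta=0.6)
        res = univariate_cox(time, event, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": time, "E": event, "x": x}),
                duration_col="T", event_col="E")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_loglik_nondecreasing_over_accepted_steps(self):
        rng = np.random.default_rng(9)
        time, event, x = random_survival(rng, 80, beta=1.0)
        res = univariate_cox(time, event, x)
        assert res.converged
        assert (np.diff(res.loglik_trajectory) >= -1e-10).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox([1.0, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_separation_flagged_not_crashed(self):
        # covariate perfectly orders event times -> monotone likelihood
        time = np.arange(1.0, 13.0)
        event = np.ones(12, dtype=int)
        x = np.arange(12.0)
        res = univariate_cox(time, event, x)
        assert not res.converged
        assert res.warning is not None


class TestMaxstat:
    def test_separated_fixture_cutpoint_three(self):
        # balanced-split guard (min_group_frac = 0.5) makes the gap between
        # the early-event and late-censored score blocks the admissible cut
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        time = np.array([5.0, 6, 7, 100, 100, 100])
        event = np.array([1, 1, 1, 0, 0, 0])
        cut, stat, labels = maxstat_cutpoint(scores, time, event, 0.5)
        assert cut == 3.0
        assert list(labels) == ["low"] * 3 + ["high"] * 3

    def test_matches_independent_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(15, 61))
            time, event, x = random_survival(rng, n, beta=0.5)
            if event.sum() < 2 or len(np.unique(x)) < 2:
                continue
            cut, stat, _ = maxstat_cutpoint(x, time, event, 0.1)
            # independent scan with the direct-sum oracle
            best = (-np.inf, None)
            min_n = int(np.ceil(0.1 * n))
            for c in np.unique(x)[:-1]:
                low = x <= c
                if low.sum() < min_n or (~low).sum() < min_n:
                    continue
                s = logrank_sum_oracle(time, event, low.astype(int))
                if s > best[0] + 1e-12:
                    best = (s, c)
            assert cut == best[1]
            assert stat == pytest.approx(best[0], abs=1e-10)

    def test_selected_statistic_at_least_median_split(self):
        rng = np.random.default_rng(11)
        time, event, x = random_survival(rng, 60, beta=0.8)
        _, stat, _ = maxstat_cutpoint(x, time, event, 0.1)
        med_low = x <= np.median(x)
        assert stat >= logrank_sum_oracle(time, event, med_low.astype(int)) - 1e-10

    def test_min_group_frac_half_odd_n_rejected(self):
        rng = np.random.default_rng(12)
        time, event, x = random_survival(rng, 21)
        with pytest.raises(ValueError, match="min_group_frac"):
            maxstat_cutpoint(x, time, event, min_group_frac=0.5)
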