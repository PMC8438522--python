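"""Survival machinery: Kaplan-Meier, log-rank, univariate Cox, maxstat cutpoint.

The log-rank statistic is implemented directly (vectorized over event times)
because the maximally-selected-cutpoint scan evaluates it for every candidate
split and needs it to be cheap; the Kaplan-Meier estimator delegates to
lifelines.  The univariate Cox model uses the Breslow tie convention with a
Newton-Raphson solver and step-halving, and records the partial-log-likelihood
trajectory of accepted steps.

The selected cutpoint from :func:`maxstat_cutpoint` maximizes the two-group
log-rank statistic over all admissible splits.  No correction for the implied
multiple testing is applied: the log-rank p reported for the resulting groups
is selection-biased and is meant descriptively, the way surv-cutpoint output
is conventionally used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class CoxResult:
    beta: float
    hr: float
    ci95: tuple[float, float]
    se: float
    p: float
    converged: bool
    n_events: int
    loglik_trajectory: list[float] = field(default_factory=list)
    warning: str | None = None


def _as_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if (time < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_estimate(time, event):
    """Product-limit survival estimate.

    Returns ``(times, survival)`` step-function arrays: ``survival[i]`` is
    S(t) for t in ``[times[i], times[i+1])``, with S(0) = 1 prepended.
    """
    time, event = _as_arrays(time, event)
    if len(time) == 0:
        raise ValueError("no samples")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(time, event, group):
    """K-sample log-rank test.

    ``group`` holds arbitrary hashable labels; the statistic is the classical
    observed-minus-expected quadratic form with hypergeometric variance,
    referred to a chi-square with (k-1) degrees of freedom.
    """
    time, event = _as_arrays(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs >=2 groups")
    if event.sum() == 0:
        warnings.warn("no events: log-rank variance is zero, p set to 1", stacklevel=2)
        return 0.0, 1.0
    if k == 2:
        chi2 = _logrank_two_group(time, event, group == labels[1])
    else:
        chi2 = _logrank_k_group(time, event, group, labels)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


def _logrank_two_group(time, event, in_g1):
    """Two-group log-rank chi-square, vectorized over distinct event times."""
    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in_g1[order].astype(float)
    n = len(t)
    # at position i (sorted), number at risk = n - i; risk in group1 = suffix sum
    at_risk = n - np.arange(n)
    risk_g1 = np.cumsum(g1[::-1])[::-1]
    # aggregate per distinct time
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)                    # events at each time
    d1 = np.add.reduceat(e * g1, first)              # events in group1
    nrisk = at_risk[first].astype(float)
    n1 = risk_g1[first]
    mask = d > 0
    d, d1, nrisk, n1 = d[mask], d1[mask], nrisk[mask], n1[mask]
    expected = d * n1 / nrisk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / nrisk) * (1 - n1 / nrisk) * (nrisk - d) / np.maximum(nrisk - 1, 1)
    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        warnings.warn("zero log-rank variance, p set to 1", stacklevel=3)
        return 0.0
    return o_minus_e ** 2 / v


def _logrank_k_group(time, event, group, labels):
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    n = len(t)
    k = len(labels)
    onehot = np.stack([(g == lab).astype(float) for lab in labels], axis=1)
    at_risk = (n - np.arange(n)).astype(float)
    risk_g = np.cumsum(onehot[::-1], axis=0)[::-1]
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first).astype(float)
    dg = np.add.reduceat(e[:, None] * onehot, first, axis=0)
    nrisk = at_risk[first]
    ng = risk_g[first]
    mask = d > 0
    d, dg, nrisk, ng = d[mask], dg[mask], nrisk[mask], ng[mask]
    prop = ng / nrisk[:, None]
    o_minus_e = (dg - d[:, None] * prop).sum(axis=0)
    # covariance: V_ab = sum_t d (n-d)/(n-1) * (delta_ab p_a - p_a p_b)
    factor = d * (nrisk - d) / np.maximum(nrisk - 1, 1)
    V = np.einsum("t,ta,tb->ab", factor, prop, -prop)
    V[np.diag_indices(k)] += np.einsum("t,ta->a", factor, prop)
    # drop last group (singular otherwise)
    u = o_minus_e[:-1]
    Vm = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(Vm) @ u)
    return max(chi2, 0.0)


# ---------------------------------------------------------------------------
# univariate Cox (Breslow ties, Newton-Raphson with step-halving)

def _cox_derivatives(beta, t_desc, e_desc, x_desc, tie_last):
    """Partial log-likelihood and its first two derivatives (Breslow)."""
    w = np.exp(beta * x_desc)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_desc)
    s2 = np.cumsum(w * x_desc ** 2)
    # risk set at time t = all with time >= t; with descending sort the risk
    # set for the i-th sample is prefix [0..j] where j is the last index of
    # the tie block containing i
    s0r, s1r, s2r = s0[tie_last], s1[tie_last], s2[tie_last]
    ev = e_desc.astype(bool)
    ll = float(np.sum(beta * x_desc[ev] - np.log(s0r[ev])))
    mean = s1r[ev] / s0r[ev]
    grad = float(np.sum(x_desc[ev] - mean))
    info = float(np.sum(s2r[ev] / s0r[ev] - mean ** 2))
    return ll, grad, info


def univariate_cox(time, event, covariate, max_iter: int = 50, tol: float = 1e-9) -> CoxResult:
    """Cox proportional-hazards fit for a single continuous covariate.

    Breslow tie handling; Newton-Raphson with step-halving on the partial
    likelihood.  Monotone-likelihood (perfect separation) is reported via
    ``converged=False`` with a diagnostic warning string.
    """
    time, event = _as_arrays(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.std() == 0:
        raise ValueError("covariate is constant")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need >=2 events")
    order = np.argsort(-time, kind="stable")
    t_desc, e_desc, x_desc = time[order], event[order], x[order]
    # index of the last member of each tie block (risk set boundary)
    n = len(t_desc)
    tie_last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_desc[j + 1] == t_desc[i]:
            j += 1
        tie_last[i:j + 1] = j
        i = j + 1

    beta = 0.0
    ll, grad, info = _cox_derivatives(beta, t_desc, e_desc, x_desc, tie_last)
    trajectory = [ll]
    converged = False
    warning = None
    for _ in range(max_iter):
        if info <= 0:
            warning = "non-positive information (degenerate likelihood)"
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_derivatives(new_beta, t_desc, e_desc, x_desc, tie_last)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_derivatives(new_beta, t_desc, e_desc, x_desc, tie_last)
            halvings += 1
        beta, delta_ll = new_beta, new_ll - ll
        ll, grad, info = new_ll, new_grad, new_info
        trajectory.append(ll)
        if abs(grad) < tol and delta_ll < 1e-9:
            converged = True
            break
    # an absurd standardized effect (HR > e^10 per covariate sd) signals a
    # monotone partial likelihood: the MLE does not exist
    if abs(beta) * x.std() > 10:
        converged = False
        warning = "monotone likelihood (possible perfect separation)"
    elif not converged and warning is None:
        warning = "Newton-Raphson did not converge"
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (float(np.exp(np.clip(beta - 1.959963984540054 * se, -700, 700))),
          float(np.exp(np.clip(beta + 1.959963984540054 * se, -700, 700))))
    return CoxResult(beta=float(beta), hr=float(np.exp(beta)), ci95=ci, se=se,
                     p=p, converged=converged, n_events=n_events,
                     loglik_trajectory=trajectory, warning=warning)


# ---------------------------------------------------------------------------
# maximally selected rank statistic

def maxstat_cutpoint(scores, time, event, min_group_frac: float = 0.1):
    """Cutpoint maximizing the two-group log-rank statistic.

    Candidates are the observed score values; the low group is ``score <= c``.
    Splits leaving either group below ``min_group_frac`` of the cohort are
    excluded (the standard maxstat guard).  Ties in the maximal statistic are
    broken toward the smaller cutpoint.

    Returns ``(cutpoint, max_statistic, labels)`` with labels in
    ``{"low", "high"}``.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _as_arrays(time, event)
    if len(np.unique(scores)) < 2:
        raise ValueError("no candidate cutpoints: all scores identical")
    if event.sum() < 2:
        raise ValueError("need >=2 events")
    n = len(scores)
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    candidates = np.unique(scores)[:-1]  # splitting above the max is void
    best_stat = -np.inf
    best_cut = None
    for c in candidates:
        low = scores <= c
        n_low = int(low.sum())
        if n_low < min_n or n - n_low < min_n:
            continue
        stat = _logrank_two_group(time, event, low)
        if stat > best_stat + 1e-12:
            best_stat = stat
            best_cut = c
    if best_cut is None:
        raise ValueError("no candidate split respects min_group_frac")
    labels = np.where(scores <= best_cut, "low", "high")
    return float(best_cut), float(best_stat), labels
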