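"""The multiple co-expression resampling screen.

The screen asks whether a co-expressed gene (CEG) modulates the correlation
between an m6A regulator and an immune signature.  Per replicate, a fixed
fraction of the cohort (default 60%) is drawn without replacement; within the
subsample the Spearman correlation r1 between each regulator's expression and
each signature score is computed (kept only when its p < 0.05, the stated
relevance rule), along with every CEG's median expression.  After the default
100 replicates, each (regulator, signature, CEG) triple correlates the CEG's
medians with the r1 series across replicates — again by Spearman — and the
resulting rho and p flag candidate moderators.

Replicates whose r1 fails the relevance filter are dropped pairwise for that
triple (both vectors trimmed to the valid replicates); a flag retains all r1s
instead.  This is a correlational screen, not a causal mediation model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Marker regulators carried into the screen by default.
DEFAULT_SCREEN_REGULATORS = ("METTL14", "ZC3H13", "IGF2BP1", "KIAA1429",
                             "HNRNPA2B1", "IGF2BP3", "YTHDF1")

EXACT_PERMUTATION_MAX_N = 8


def spearman(x, y, exact_max_n: int = EXACT_PERMUTATION_MAX_N):
    """Spearman rank correlation with a small-sample exact permutation p.

    Average ranks handle ties.  For n <= ``exact_max_n`` and tie-free data the
    two-sided p enumerates all n! rank permutations; otherwise the
    t-approximation is used.  Zero variance in either vector returns
    ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not has_ties:
        perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum()) * math.sqrt(((perms[0] - perms[0].mean())**2).sum())
        rhos = (perms - (n + 1) / 2.0) @ rx_c / denom
        # two-sided: fraction of permutations at least as extreme
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class CoexpResult:
    """Long-format screen output plus per-replicate intermediates."""

    triples: pd.DataFrame       # regulator, signature, ceg, rho, p, n_valid
    r1: pd.DataFrame            # replicates x (regulator, signature) MultiIndex columns
    medians: pd.DataFrame       # replicates x CEG
    n_reps: int
    frac: float

    def hits(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.triples
        return t[(t["p"] < alpha) & t["rho"].notna()].sort_values("p")


def run_multicoexp(expr, signatures: pd.DataFrame, cegs, regulators=DEFAULT_SCREEN_REGULATORS,
                   frac: float = 0.6, n_reps: int = 100, seed: int = 0,
                   relevance_alpha: float | None = 0.05, min_valid: int = 10,
                   missing_frac_limit: float = 0.5) -> CoexpResult:
    """Run the resampling screen.

    ``expr``: ExpressionMatrix with regulators and CEGs among its genes;
    ``signatures``: samples x signatures score table; ``cegs``: iterable of
    CEG gene IDs.  ``relevance_alpha=None`` retains every r1 regardless of
    significance.  Triples with fewer than ``min_valid`` contributing
    replicates report rho = NaN.
    """
    ceg_list = sorted(set(cegs))
    reg_list = [r for r in regulators if r in expr.data.index]
    skipped = sorted(set(regulators) - set(reg_list))
    if skipped:
        logger.warning("screen regulators absent from matrix: %s", ", ".join(skipped))
    common = [s for s in expr.sample_ids if s in signatures.index]
    if len(common) < 20:
        raise ValueError("need >=20 joined samples")
    sig_cols = []
    for col in signatures.columns:
        frac_missing = signatures.loc[common, col].isna().mean()
        if frac_missing > missing_frac_limit:
            logger.warning("signature %s missing for %.0f%% of samples; skipped",
                           col, 100 * frac_missing)
        else:
            sig_cols.append(col)
    expr_mat = expr.restrict_samples(common)
    reg_values = expr_mat.data.loc[reg_list].to_numpy()
    ceg_values = expr_mat.data.loc[[g for g in ceg_list if g in expr_mat.data.index]]
    ceg_names = list(ceg_values.index)
    ceg_values = ceg_values.to_numpy()
    sig_values = signatures.loc[common, sig_cols].to_numpy(dtype=float)

    n = len(common)
    m = int(round(frac * n))
    rng = np.random.default_rng(seed)

    pairs = [(r, s) for r in reg_list for s in sig_cols]
    r1 = np.full((n_reps, len(pairs)), np.nan)
    medians = np.empty((n_reps, len(ceg_names)))
    for rep in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        medians[rep] = np.median(ceg_values[:, idx], axis=1)
        sub_sig = sig_values[idx]
        for k, (ri, si) in enumerate(
                (i, j) for i in range(len(reg_list)) for j in range(len(sig_cols))):
            x = reg_values[ri, idx]
            y = sub_sig[:, si]
            ok = ~np.isnan(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            if relevance_alpha is None or p < relevance_alpha:
                r1[rep, k] = rho

    rows = []
    for k, (reg, sig) in enumerate(pairs):
        r1_col = r1[:, k]
        valid = ~np.isnan(r1_col)
        for c, ceg in enumerate(ceg_names):
            med = medians[valid, c]
            rr = r1_col[valid]
            n_valid = int(valid.sum())
            if n_valid < min_valid or len(np.unique(med)) < 2 or len(np.unique(rr)) < 2:
                rows.append((reg, sig, ceg, np.nan, np.nan, n_valid))
                continue
            rho, p = spearman(med, rr)
            rows.append((reg, sig, ceg, rho, p, n_valid))
    triples = pd.DataFrame(rows, columns=["regulator", "signature", "ceg", "rho", "p", "n_valid"])
    r1_df = pd.DataFrame(r1, columns=pd.MultiIndex.from_tuples(pairs, names=["regulator", "signature"]))
    med_df = pd.DataFrame(medians, columns=ceg_names)
    return CoexpResult(triples=triples, r1=r1_df, medians=med_df, n_reps=n_reps, frac=frac)


def median_split_contrast(expr, regulator: str, moderator: str,
                          signatures: pd.DataFrame, signature_name: str) -> pd.DataFrame:
    """2x2 median-split contrast of a signature by regulator and moderator level.

    Samples are split at the median expression of the regulator and of the
    candidate moderator; per-group mean signature scores and pairwise
    Wilcoxon rank-sum p-values are returned (long format).  Deterministic.
    """
    for g in (regulator, moderator):
        if g not in expr.data.index:
            raise ValueError(f"gene {g!r} absent from matrix")
    common = [s for s in expr.sample_ids if s in signatures.index]
    reg = expr.data.loc[regulator, common].to_numpy(dtype=float)
    mod = expr.data.loc[moderator, common].to_numpy(dtype=float)
    sig = signatures.loc[common, signature_name].to_numpy(dtype=float)
    reg_high = reg > np.median(reg)
    mod_high = mod > np.median(mod)
    for name, mask in (("regulator", reg_high), ("moderator", mod_high)):
        frac = max(mask.mean(), 1 - mask.mean())
        if frac > 0.7:
            logger.warning("median ties place %.0f%% of samples on one side of the %s split",
                           100 * frac, name)
    groups = {}
    for rh in (True, False):
        for mh in (True, False):
            key = f"{regulator}_{'high' if rh else 'low'}|{moderator}_{'high' if mh else 'low'}"
            groups[key] = sig[(reg_high == rh) & (mod_high == mh)]
    rows = []
    keys = list(groups)
    for key in keys:
        g = groups[key]
        rows.append(("group_mean", key, "", float(np.mean(g)) if len(g) else np.nan, len(g)))
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = groups[keys[i]], groups[keys[j]]
            if len(a) >= 2 and len(b) >= 2:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                p = np.nan
            rows.append(("wilcoxon_p", keys[i], keys[j], float(p), len(a) + len(b)))
    return pd.DataFrame(rows, columns=["kind", "group_a", "group_b", "value", "n"])
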