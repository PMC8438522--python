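"""Shared fixtures: synthetic cohorts and small engineered matrices."""

import numpy as np
import pandas as pd
import pytest

from m6apattern.io_formats import ExpressionMatrix
from m6apattern.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def deg_fixture():
    """Engineered matrix: 54 genes differential in every one-vs-rest contrast.

    Cluster sizes (20, 60, 100); the 54 target genes carry means (0, +5, -5)
    whose one-vs-rest log2 fold changes are (-1.25, +9.17, -8.75) — all beyond
    the |log2FC| > 1 gate.  Three decoy families each null out exactly one
    contrast (mean set to the weighted mean of the other clusters), and 40
    pure null genes round out the matrix.
    """
    rng = np.random.default_rng(42)
    sizes = (20, 60, 100)
    labels = np.repeat([1, 2, 3], sizes)
    n = sum(sizes)

    def block(name, means, count, sd=0.3):
        mu = np.asarray(means, dtype=float)[labels - 1]
        vals = mu + rng.normal(0, sd, size=(count, n))
        return [f"{name}{i:03d}" for i in range(count)], vals

    names, mats = [], []
    for nm, means, count in [
        ("ALL", (0.0, 5.0, -5.0), 54),     # passes in all three contrasts
        ("NC1", (-1.0, 4.0, -4.0), 10),    # fold change ~0 vs rest for cluster 1
        ("NC2", (4.0, -8 / 3, -4.0), 10),  # ~0 for cluster 2
        ("NC3", (4.0, -4.0, -2.0), 10),    # ~0 for cluster 3
        ("NULL", (0.0, 0.0, 0.0), 40),
    ]:
        nm_list, vals = block(nm, means, count)
        names.extend(nm_list)
        mats.append(vals)
    data = pd.DataFrame(np.vstack(mats), index=names,
                        columns=[f"S{i:03d}" for i in range(n)])
    return ExpressionMatrix(data), labels


def random_survival(rng, n, censor_frac=0.3, beta=0.0, covariate=None):
    """Exponential survival with uniform censoring; optional PH covariate."""
    if covariate is None:
        covariate = rng.normal(size=n)
    hazard = 0.01 * np.exp(beta * covariate)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_frac
    time = np.where(censored, event_time * rng.random(n), event_time)
    return np.maximum(time, 1e-6), (~censored).astype(int), covariate
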