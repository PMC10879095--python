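"""Shared fixtures: small deterministic synthetic inputs."""

import numpy as np
import pandas as pd
import pytest

from rcdgp.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest bulk cohort with planted structure (reused read-only)."""
    spec = CohortSpec(n_samples=150, n_genes=400, n_sets=8, set_size=20,
                      seed=3)
    expr, surv, truth = generate_cohort(spec)
    return expr, surv, truth


@pytest.fixture()
def toy_expr():
    """5 genes x 4 samples with distinct values (hand-checkable ranks)."""
    rng = np.random.default_rng(11)
    vals = rng.permutation(20).reshape(5, 4).astype(float)
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(1, 6)],
                        columns=[f"s{i}" for i in range(1, 5)])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def weibull_survival(lp, rng, scale=24.0, shape=1.2, censor_quantile=0.7):
    """Helper used by several tests: PH Weibull times + exponential censoring."""
    n = len(lp)
    t = scale * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1.0 / shape)
    c = rng.exponential(np.quantile(t, censor_quantile), size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample")
    return pd.DataFrame({"time_months": time, "event": event}, index=idx)
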