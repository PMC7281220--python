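import numpy as np
import pandas as pd
import pytest

from methylmss import CohortSpec, generate_cohort, normalize_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """Default-size synthetic cohort (2,000 probes, 200 samples/class)."""
    spec = CohortSpec(seed=1)
    cohort, ann, truth = generate_cohort(spec)
    return spec, cohort, ann, truth


@pytest.fixture(scope="session")
def normalized(default_bundle):
    _, cohort, ann, _ = default_bundle
    return normalize_cohort(cohort, ann)


@pytest.fixture(scope="session")
def small_bundle():
    """Fast cohort for structural tests: 300 probes, 30 samples/class."""
    spec = CohortSpec(n_ec=30, n_gc_per_subtype=8, n_probes=300, n_planted=20, n_cohorts=2, seed=7)
    cohort, ann, truth = generate_cohort(spec)
    return spec, cohort, ann, truth


@pytest.fixture
def two_cluster_matrix():
    """Two well-separated clusters of 6 samples each over 5 probes."""
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 0.1, size=(5, 12))
    x[:, 6:] += 4.0
    cols = [f"s{i:02d}" for i in range(12)]
    matrix = pd.DataFrame(x, index=[f"p{i}" for i in range(5)], columns=cols)
    labels = pd.Series(["EC"] * 6 + ["GC"] * 6, index=cols)
    return matrix, labels
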