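import numpy as np
import pytest

from updrs.consensus import ClusterEnsemble, Partition
from updrs.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_table():
    """A compact telemonitoring table with clear 3-cluster structure."""
    cfg = SyntheticConfig(n_subjects=12, recordings_per_subject=15, n_clusters=3,
                          cluster_separation=8.0, feature_correlation=0.3, seed=7)
    table, truth, params = generate(cfg)
    return table, truth, params


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_ensemble(rng, n_rows, n_partitions, max_k=4):
    parts = []
    for _ in range(n_partitions):
        k = int(rng.integers(2, max_k + 1))
        labels = rng.integers(0, k, size=n_rows)
        # guarantee the declared k is an upper bound, not necessarily attained
        parts.append(Partition(labels=labels, k=k, source="rand"))
    return ClusterEnsemble(partitions=parts, target_k=2)
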