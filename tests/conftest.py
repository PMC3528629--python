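import numpy as np
import pytest

from simfuse import (
    FusionConfig,
    PlantedScenario,
    generate_all,
    pearson_similarity,
    tanimoto_similarity,
)


@pytest.fixture
def small_scenario():
    """15 compounds, 3 planted clusters, mild noise in both views."""
    return PlantedScenario(
        n=15, k_true=3, view_noise=(0.2, 0.2), profile_dim=20, fp_bits=64,
        targets_per_cluster=2, annotation_noise=0.0, seed=7,
    )


@pytest.fixture
def small_views(small_scenario):
    profiles, fps, net, labels = generate_all(small_scenario)
    return (
        pearson_similarity(profiles),
        tanimoto_similarity(fps),
        net,
        labels,
    )


@pytest.fixture
def fast_config():
    """Fusion settings scaled for unit tests."""
    return FusionConfig(eta=3.0, k=3, seed=11, n_restarts=2, max_em=300, max_outer=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_symmetric_similarity(rng, n):
    """A valid similarity matrix: symmetric, unit diagonal, entries in [0,1]."""
    S = rng.random((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S
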