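import numpy as np
import pytest

import chemomark as cm


@pytest.fixture(scope="session")
def default_dataset():
    """The emulated study layout: 8 animals x 3 timepoints x 3 technical
    replicates, one female t12 biological sample discarded."""
    spec = cm.SyntheticSpec(seed=7)
    dataset, truth = cm.synthesize(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def two_cluster_matrix():
    """Two well-separated Gaussian clusters in 5 dimensions (planted
    distance >> noise), with labels."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.3, size=(30, 5))
    b = rng.normal(0.0, 0.3, size=(30, 5)) + 4.0
    X = np.vstack([a, b])
    y = np.array([0] * 30 + [1] * 30)
    return X, y
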