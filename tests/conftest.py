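import numpy as np
import pytest

import stabclust as sc


@pytest.fixture(scope="session")
def iris_ref():
    return sc.load_iris_reference()


@pytest.fixture(scope="session")
def two_blobs():
    """Trivially separable toy: two tight, distant blobs in 6 dimensions."""
    rng = np.random.default_rng(42)
    n = 30
    a = rng.normal(0.0, 0.05, size=(n, 6)) + np.array([5, 5, 5, 0, 0, 0])
    b = rng.normal(0.0, 0.05, size=(n, 6)) + np.array([0, 0, 0, 5, 5, 5])
    X = np.vstack([a, b])
    y = np.repeat([0, 1], n)
    # z-scored, as pipelines expect preprocessed input
    X = (X - X.mean(0)) / X.std(0)
    return X, y


@pytest.fixture(scope="session")
def medium_sim(iris_ref):
    """A small simulated dataset (medium separation, a few noise columns)."""
    params = sc.derive_mixture_params(iris_ref, "medium")
    ds = sc.simulate_dataset(
        params, sc.SimulationConfig("medium", n_obs=300, n_noise=10, seed=7)
    )
    pp = sc.fit_preprocess(ds.features)
    return sc.apply_preprocess(pp, ds.features), ds.ground_truth
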