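import numpy as np
import pytest

import coactivity as ca


@pytest.fixture(scope="session")
def corr_dataset():
    """Correlation-coded two-state dataset at the standard study scale."""
    cfg = ca.SyntheticStateConfig(n_neurons=100, n_frames=6000, n_assemblies=5, seed=7)
    raster, labels, slices = ca.two_state_dataset(cfg, "correlation")
    part = ca.alternating_blocks(raster.shape[1])
    return cfg, raster, labels, slices, part


@pytest.fixture(scope="session")
def rate_dataset():
    """Rate-coded two-state dataset (modulation bound 0.5)."""
    cfg = ca.SyntheticStateConfig(
        n_neurons=100, n_frames=6000, modulation_bound=0.5, seed=3
    )
    raster, labels, slices = ca.two_state_dataset(cfg, "rate")
    part = ca.alternating_blocks(raster.shape[1])
    return cfg, raster, labels, slices, part


@pytest.fixture(scope="session")
def trained_corr_clf(corr_dataset):
    """One classifier trained on the correlation-coded dataset."""
    _, raster, labels, _, part = corr_dataset
    rng = np.random.default_rng(11)
    clf = ca.build_network(100, 0.3, 1000, rng)
    return ca.train(clf, raster, labels, part, rng)


@pytest.fixture(scope="session")
def trained_rate_clf(rate_dataset):
    """One classifier trained on the rate-coded dataset."""
    _, raster, labels, _, part = rate_dataset
    rng = np.random.default_rng(13)
    clf = ca.build_network(100, 0.3, 1000, rng)
    return ca.train(clf, raster, labels, part, rng)


def random_raster(n_neurons, n_frames, p, seed):
    rng = np.random.default_rng(seed)
    return (rng.random((n_neurons, n_frames)) < p).astype(np.uint8)
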