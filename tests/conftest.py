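import numpy as np
import pytest

import stmmr


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_run():
    """One small trained model on an 80-spot synthetic slice (shared)."""
    cfg = stmmr.SynthConfig(n_spots=80, grid_shape=(8, 10), seed=7)
    ds, labels, true_means = stmmr.generate(cfg)
    ds = stmmr.preprocess(ds, n_hvg=200)
    g = stmmr.normalize_adjacency(
        stmmr.gaussian_adjacency(ds.coords, stmmr.auto_bandwidth(ds.coords), 6)
    )
    model = stmmr.train(ds, g, cfg=stmmr.TrainConfig(epochs=40, seed=0))
    return {"ds": ds, "graph": g, "model": model, "labels": labels, "true_means": true_means}
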