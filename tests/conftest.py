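import numpy as np
import pytest

import remmlite as r


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset: 60 positives, 1:100 imbalance, 20 bands."""
    return r.simulate(
        r.SimConfig(
            n_pos=60, imbalance=100, n_bands=20, band_length=5000,
            pos_band_fraction=0.25, effect_size=0.6, seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_model(small_sim):
    """Ensemble trained on the full small dataset."""
    y = np.array([v.label for v in small_sim.variants])
    imputer = r.fit_imputer(
        small_sim.features, r.policy_from_metadata(small_sim.features.metadata)
    )
    return r.fit_ensemble(
        r.impute(small_sim.features, imputer),
        y,
        r.HyperSmurfConfig(n_partitions=10, seed=11),
        imputer=imputer,
    )
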