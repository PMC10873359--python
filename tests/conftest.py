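import numpy as np
import pytest

from normatlas import (
    AtlasConfig,
    FeatureSimConfig,
    SlideSimConfig,
    fit_atlas,
    simulate_feature_dataset,
    simulate_holdout_vectors,
    simulate_slide,
)


@pytest.fixture(scope="session")
def sim_cfg():
    return FeatureSimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_dataset(sim_cfg):
    return simulate_feature_dataset(sim_cfg)


@pytest.fixture(scope="session")
def normal_bags(sim_dataset):
    return sim_dataset[0]


@pytest.fixture(scope="session")
def labeled_bags(sim_dataset):
    return sim_dataset[1]


@pytest.fixture(scope="session")
def holdout(sim_cfg):
    return simulate_holdout_vectors(sim_cfg, n_normal=500, n_abnormal=500)


@pytest.fixture(scope="session")
def ocsvm_atlas(normal_bags):
    return fit_atlas(normal_bags, AtlasConfig(method="ocsvm", seed=5))


@pytest.fixture(scope="session")
def iforest_atlas(normal_bags):
    return fit_atlas(normal_bags, AtlasConfig(method="isolation_forest", seed=5))


@pytest.fixture(scope="session")
def small_slide():
    cfg = SlideSimConfig(width=1536, height=1536, lesion_fraction=0.3, seed=3)
    return simulate_slide(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
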