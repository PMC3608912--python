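import numpy as np
import pytest

from glasslearn.synthetic import VoxelPatternModel, simulate_trial_patterns


@pytest.fixture(scope="session")
def young_observer():
    from glasslearn.synthetic import ObserverModel

    return ObserverModel.from_group_norms("young")


@pytest.fixture(scope="session")
def post_design():
    from glasslearn.design import build_behavioral_session

    return build_behavioral_session("post_test", "young", seed=11)


@pytest.fixture(scope="session")
def small_pattern_model():
    """Compact but decodable generative model for MVPA tests."""
    return VoxelPatternModel(n_voxels=60, informative_fraction=0.4,
                             kappa_pre=1.5, kappa_post=3.0, n_runs=4,
                             trials_per_condition=8, seed=202)


@pytest.fixture(scope="session")
def informative_dataset(small_pattern_model):
    return simulate_trial_patterns(small_pattern_model, "pre", group="young",
                                   seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
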