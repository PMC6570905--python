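import numpy as np
import pytest

from autorep.params import RateParameters
from autorep.synthetic_data import TrajectoryGenConfig, gen_trajectories, paper_hmm


@pytest.fixture(scope="session")
def default_params():
    return RateParameters()


@pytest.fixture(scope="session")
def birth_death_params():
    """Pure birth-death reduction: no operator binding, no inducer coupling."""
    return RateParameters(
        h=0.0, f=0.0, g11=2.0, g10=2.0, g01=2.0, g00=2.0, b=0.0, c=0.0
    )


@pytest.fixture(scope="session")
def reference_hmm():
    return paper_hmm()


@pytest.fixture(scope="session")
def synthetic_trajectories():
    """One default-config synthetic data set with ground truth."""
    cfg = TrajectoryGenConfig(seed=101)
    return gen_trajectories(cfg)
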