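import numpy as np
import pytest

from taainv import gr_membrane as gm
from taainv import grf_insults as gi
from taainv.domain import GridSpec


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def kernel():
    return gi.GRFKernel(length_z=0.25)


@pytest.fixture(scope="session")
def wall_params():
    return gm.homeostatic_calibration()


@pytest.fixture(scope="session")
def profile(grid, kernel):
    return gi.sample_insult_profile(grid, kernel, seed=1234,
                                    profile_id="pfix")


@pytest.fixture(scope="session")
def small_records(wall_params):
    """Eight records: four templates, one mixed and one skewed combo each."""
    return gi.build_dataset(n_profiles=4, combos=(0.25, 0.75), base_seed=7,
                            sim_params=wall_params)


@pytest.fixture(scope="session")
def small_arrays(small_records):
    from taainv import maps as mp
    from taainv import operators as op
    split = mp.split_dataset(small_records, n_train=6, seed=5)
    X, Y, P = op.prepare_arrays(small_records, split.train + split.test, 2,
                                "grayscale")
    return X, Y, P
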