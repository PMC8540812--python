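import numpy as np
import pytest

import trapdensity as td


@pytest.fixture(scope="session")
def codling():
    return td.get_preset("codling_moth")


@pytest.fixture(scope="session")
def sawfly():
    return td.get_preset("pine_sawfly")


@pytest.fixture(scope="session")
def all_presets():
    return td.load_presets()


def make_noiseless_dataset(params, distances, n_released=10**9):
    """Exact-curve recapture table: counts rounded at a huge cohort size.

    With n_released = 1e9 the rounding error on each proportion is 5e-10,
    far below every fit tolerance used in the tests.
    """
    records = tuple(
        td.DistanceCatchRecord(
            float(d), n_released, round(td.sp_t_fer(d, params) * n_released)
        )
        for d in distances
    )
    return td.ReleaseRecaptureDataset(records, species=params.label)


@pytest.fixture
def noiseless_dataset():
    return make_noiseless_dataset


def ladder(d50, rmax, rel=(0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4)):
    """Distance ladder proportional to d50, clipped at the collection radius."""
    return np.unique(np.minimum(np.asarray(rel, dtype=float) * d50, rmax))


@pytest.fixture
def distance_ladder():
    return ladder
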