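import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from radpipe import (ImageVolume, PhantomSpec, RoiMask,
                     generate_phantom_patient, preprocess_patient)

#: small but fully featured phantom geometry used across tests
SMALL_PHANTOM = dict(grid_shape=(48, 48, 16), voxel_spacing=(1.0, 1.0, 3.0),
                     tumor_radii=(11.0, 9.0, 8.0))


@pytest.fixture(scope="session")
def phantom_patient():
    """One deterministic phantom patient (raw, unpreprocessed)."""
    return generate_phantom_patient(PhantomSpec(seed=11, **SMALL_PHANTOM))


@pytest.fixture(scope="session")
def preprocessed_patient(phantom_patient):
    """The same patient after the full preprocessing chain (2 mm iso)."""
    p = phantom_patient
    return preprocess_patient(p.t1, p.t2, p.mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_discretized_roi(rng, max_side=5, n_bins=4):
    """A random small DiscretizedRoi for brute-force texture checks."""
    from radpipe.radiomics import discretize_fixed_bin_count

    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    data = rng.integers(0, 10, size=shape).astype(float)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    return discretize_fixed_bin_count(data, mask, n_bins)
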