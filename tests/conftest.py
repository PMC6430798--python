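import numpy as np
import pytest

import specklescope as sp

# canonical optical parameters used throughout (NA 0.77, 532 nm, oil index)
LAMBDA = 532.0
NA = 0.77
INDEX = 1.515
PX = 130.0  # nm, below the Nyquist bound lambda/(4 NA) = 172.7 nm


def optical_config(n=128, nz=9, dz=500.0, px=PX):
    z = tuple(float(v) for v in (np.arange(nz) - nz // 2) * dz)
    return sp.OpticalConfig(LAMBDA, NA, INDEX, px, (n, n), z)


def intensity_stack(config, seed):
    """Normalized speckle intensity stack for one random pupil."""
    return sp.intensity(sp.propagate(sp.build_pupil(config, seed)))


@pytest.fixture(scope="session")
def cfg_small():
    return optical_config()


@pytest.fixture(scope="session")
def speckle_small(cfg_small):
    return intensity_stack(cfg_small, seed=1)
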