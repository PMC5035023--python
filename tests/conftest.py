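import logging

import numpy as np
import pytest

from dixoncomp import phantom as ph
from dixoncomp import preprocess as pp

logging.getLogger("dixoncomp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom_s3():
    """Default phantom at a mid desk scale, with its merged composite."""
    res = ph.generate_phantom(ph.PhantomSpec(scale=3, seed=42))
    vol = pp.merge_slabs(res.slabs)
    return res, vol


@pytest.fixture(scope="session")
def phantom_s3_noiseless():
    """Noiseless, bias-free phantom for exact calibration properties."""
    res = ph.generate_phantom(
        ph.PhantomSpec(scale=3, seed=7, noise_sd=0.0, bias_amplitude=0.0)
    )
    vol = pp.merge_slabs(res.slabs)
    return res, vol


@pytest.fixture(scope="session")
def calibrated_s5():
    """Calibrated composite at the registration working scale."""
    res = ph.generate_phantom(ph.PhantomSpec(scale=5, seed=11))
    vol = pp.calibrate_volume(pp.merge_slabs(res.slabs))
    return res, vol


def make_constant_slabs(value=100.0, n_slices=44, overlap=8, dz=4.5,
                        shape=(12, 10)):
    """Two aligned constant-intensity slabs with a given slice overlap."""
    slabs = []
    for i in range(2):
        z0 = dz / 2 + i * (n_slices - overlap) * dz
        arr = np.full(shape + (n_slices,), value, dtype=np.float32)
        slabs.append(ph.DixonSlab(
            water=arr.copy(), fat=arr.copy(), voxel_size=(2.0, 2.0, dz),
            z_offset=z0, slab_index=i + 1,
        ))
    return slabs
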