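import os

# single-threaded BLAS: deterministic reductions and no oversubscription on
# the small matmuls these tests run
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from lirnet import NetworkConfig, SceneSpec, build_model, generate_sample


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(
        in_channels=1, base_channels=4, depth=2, n_residual_blocks=3, seed=11, dtype="float64"
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config)


@pytest.fixture()
def small_sample():
    spec = SceneSpec(
        height=32,
        width=32,
        nuclei_count_range=(5, 7),
        radius_range=(2.0, 3.0),
        min_center_spacing=6.0,
        intensity_range=(0.7, 1.0),
        stain_mode="fluor_like",
        noise_sd=0.01,
        seed=5,
    )
    return generate_sample(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
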