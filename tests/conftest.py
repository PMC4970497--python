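import numpy as np
import pytest

import emcspi as E

AMO_LOW_CONFIG = """\
# AMO endstation, low-fluence setting
[parameters]
detd = 300
lambda = 6.2
detsize = 150
pixsize = 0.512
stoprad = 10.0
polarization = x
"""

TINY_CONFIG = """\
[parameters]
detd = 200
lambda = 6.2
detsize = 16
pixsize = 1.2
stoprad = 2.0
polarization = x

[emc]
num_div = 1
seed = 11

[make_data]
num_data = 50
mean_count = 40
"""


@pytest.fixture(scope="session")
def amo_cfg():
    return E.parse_config(AMO_LOW_CONFIG)


@pytest.fixture(scope="session")
def tiny_cfg():
    return E.parse_config(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_det(tiny_cfg):
    return E.make_detector(tiny_cfg)


def random_photon_set(rng, num_data=8, num_pix=64, mean=5.0):
    """Seeded random sparse set built through the dense route."""
    frames = rng.poisson(mean / num_pix * 4.0, size=(num_data, num_pix))
    return E.SparsePhotonSet.from_dense(frames, num_pix=num_pix)


@pytest.fixture
def small_photons():
    return random_photon_set(np.random.default_rng(5))


@pytest.fixture(scope="session")
def tiny_problem(tiny_cfg, tiny_det):
    """A tiny but complete simulated problem: phantom, model, frames."""
    geom = E.compute_geometry(tiny_cfg)
    side = E.model_size(tiny_det)
    density = E.make_phantom_density(3.2 * geom.a, geom.a, n_blobs=3, seed=2)
    model = E.make_intensities(density, side)
    ps, truth = E.simulate_frames(model, tiny_det, 60, 40.0, seed=4)
    return {"cfg": tiny_cfg, "det": tiny_det, "geom": geom, "side": side,
            "density": density, "model": model, "photons": ps, "truth": truth}
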