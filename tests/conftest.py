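import numpy as np
import pytest

from tpvdeploy.config import default_config
from tpvdeploy.geometry import StentSpec
from tpvdeploy.materials import RVOT_BASELINE
from tpvdeploy.rings import RingSpec, deploy


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def baseline_materials(config):
    return {"vessel": config.baseline_hgo()}


@pytest.fixture(scope="session")
def waist_ring():
    """A single stenotic station of the default vessel."""
    return RingSpec(R_i=9.0, H=1.5, sectors=((1.0, "vessel"),), n_layers=4, z=0.0)


@pytest.fixture(scope="session")
def simple_stent():
    """Constant free-radius device covering one station."""
    return StentSpec(z=np.array([-1.0, 1.0]), r_free=np.array([12.5, 12.5]), K_s=50.0)


@pytest.fixture(scope="session")
def default_deployment(config, baseline_materials):
    geom = config.vessel()
    stent = config.stent_for(geom)
    return deploy(geom, stent, baseline_materials)


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
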