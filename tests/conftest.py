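import numpy as np
import pytest

from cordfc.synth.fmri import FmriGenConfig, make_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(5, (32, 32))


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(3, (24, 24))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_cfg():
    """Generator config with motion and physiology switched off."""
    return FmriGenConfig(seed=7, volumes=120, motion_sd=0.0, motion_rot_sd_deg=0.0,
                         physio_amp_gm_pct=0.0, physio_amp_noise_pct=0.0)
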