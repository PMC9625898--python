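import numpy as np
import pytest

from monaural import evaluation as ev
from monaural import make_frozen_noise, preset
from monaural.maps import greenwood_cf

FS = 48000.0


@pytest.fixture(scope="session")
def dau_cfg():
    return preset("dau1997")


@pytest.fixture(scope="session")
def osses_cfg():
    return preset("osses2021")


@pytest.fixture(scope="session")
def king_cfg():
    return preset("king2019")


@pytest.fixture(scope="session")
def frozen_noise_40():
    return make_frozen_noise(3.0, 40.0)


@pytest.fixture(scope="session")
def q_sections_cfs():
    return [greenwood_cf(n) for n in ev.QFACTOR_SECTIONS]


@pytest.fixture(scope="session")
def dau_q40(dau_cfg, frozen_noise_40, q_sections_cfs):
    """Q estimates of the linear gammatone chain for the 40-dB noise."""
    return ev.estimate_q3db(dau_cfg, q_sections_cfs, frozen_noise_40)
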