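import math

import numpy as np
import pytest

from stillmerge.geometry import Beam, MosaicModel, crystal_from_cell
from stillmerge.simdata import SimConfig, generate_frames, generate_truth


@pytest.fixture(scope="session")
def beam():
    return Beam(wavelength=1.269)


@pytest.fixture(scope="session")
def mosaic():
    # thermolysin-like fitted values: block size 4220 Å, 0.168° half-width
    return MosaicModel.from_degrees(4220.0, 0.168, half_width=True)


@pytest.fixture(scope="session")
def ortho_crystal(mosaic):
    return crystal_from_cell((55, 60, 70, 90, 90, 90), "P 21 21 21", mosaic)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(n_frames=8, seed=11, gain=0.0, background_sigma=0.0,
                     orientation_err_deg=0.03)


@pytest.fixture(scope="session")
def noiseless_data(noiseless_config):
    truth, flags = generate_truth(noiseless_config)
    frames, truths = generate_frames(truth, noiseless_config)
    return truth, flags, frames, truths


@pytest.fixture(scope="session")
def noisy_config():
    return SimConfig(n_frames=20, seed=7)


@pytest.fixture(scope="session")
def noisy_data(noisy_config):
    truth, flags = generate_truth(noisy_config)
    frames, truths = generate_frames(truth, noisy_config)
    return truth, flags, frames, truths
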