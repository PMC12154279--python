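import dataclasses

import numpy as np
import pytest

from hpcsi.config import PipelineConfig
from hpcsi.experiments import acquisition_from_sim, make_phantom
from hpcsi.phantom import roi_masks
from hpcsi.recon import phase_correct, reconstruct
from hpcsi.simulate import synthesize_kspace


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_acq(cfg):
    return acquisition_from_sim(cfg.sim)


@pytest.fixture(scope="session")
def naive_phantom(cfg):
    return make_phantom(cfg.sim, cfg.cohort, injured=False)


@pytest.fixture(scope="session")
def injured_phantom(cfg):
    return make_phantom(cfg.sim, cfg.cohort, injured=True)


@pytest.fixture(scope="session")
def noiseless_kspace(naive_phantom, default_acq):
    return synthesize_kspace(naive_phantom, default_acq)


@pytest.fixture(scope="session")
def noiseless_image(noiseless_kspace):
    return phase_correct(reconstruct(noiseless_kspace))


@pytest.fixture(scope="session")
def injured_image(injured_phantom, default_acq):
    return phase_correct(reconstruct(synthesize_kspace(injured_phantom, default_acq)))


@pytest.fixture(scope="session")
def injured_rois(injured_phantom):
    return roi_masks(injured_phantom, upsample=2)


@pytest.fixture(scope="session")
def noisy_injured_image(injured_phantom, cfg):
    """Injured subject at the cohort's calibrated SNR (seed fixed)."""
    from hpcsi.simulate import calibrate_noise_sigma

    acq = acquisition_from_sim(cfg.sim)
    sigma = calibrate_noise_sigma(injured_phantom, acq, cfg.cohort.target_snr)
    acq = dataclasses.replace(acq, noise_sigma=sigma, seed=7)
    return phase_correct(reconstruct(synthesize_kspace(injured_phantom, acq)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
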