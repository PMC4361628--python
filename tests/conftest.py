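import numpy as np
import pytest

from nawmperf import AcquisitionProtocol, CohortConfig, build_phantom


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def phantom():
    """Default-scale phantom shared across tests (read-only)."""
    return build_phantom((64, 64, 27), seed=1)


@pytest.fixture()
def noiseless_config():
    """Small cohort with every noise source switched off."""
    return CohortConfig(n_subjects=4, n_hi=2, seed=11,
                        between_subject_sd_cbv=0.0,
                        between_subject_sd_cbf=0.0,
                        voxel_noise_sd_fraction=0.0,
                        signal_noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
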