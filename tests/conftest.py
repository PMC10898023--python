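import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from oppscreen import phantom, qct

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def desk_spec():
    return phantom.PhantomSpec.desk(96)


@pytest.fixture(scope="session")
def quiet_spec(desk_spec):
    """Noise-free, vessel-free variant for exactness checks."""
    return dataclasses.replace(desk_spec, trabecular_noise_sd=0.0,
                               vessel_probability=0.0,
                               background_noise_sd=0.0)


@pytest.fixture(scope="session")
def desk_roi():
    return qct.RoiSpec.for_image_size(96)


@pytest.fixture(scope="session")
def small_cohort(desk_spec):
    """21-subject cohort at the reference class mix (deterministic)."""
    spec = phantom.CohortSpec.scaled(21, seed=42)
    subjects, meta = phantom.generate_cohort(spec, desk_spec)
    return subjects, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
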