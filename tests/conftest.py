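import logging

import numpy as np
import pytest

from iolens import synthetic
from iolens.synthetic import NoiseModel

logging.getLogger("iolens").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sn60wf_cohort():
    """Default monofocal cohort with the calibrated noise model."""
    return synthetic.generate_cohort("SN60WF", seed=11)


@pytest.fixture(scope="session")
def zero_noise_linear_cohort():
    """Noise-free, unquantized cohort with a linear (Haigis-like) true ELP."""
    return synthetic.generate_cohort(
        "SN60WF",
        n=120,
        gt_kind="linear",
        seed=21,
        noise=NoiseModel(0.0, 0.0, 0.0),
        elp_noise_sd=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
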