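import numpy as np
import pytest

from ecvlge import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    return generate_phantom(PhantomSpec(mode="clean", seed=7))


@pytest.fixture(scope="session")
def patchy_noisefree():
    """Patchy phantom with exact contrast k=8 and no noise."""
    return generate_phantom(
        PhantomSpec(mode="non-ischemic", patch_contrast_k=8.0, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def patchy_noisy():
    """Patchy phantom at moderate contrast (k=8) with default noise."""
    return generate_phantom(
        PhantomSpec(mode="non-ischemic", patch_contrast_k=8.0, seed=11))


@pytest.fixture(scope="session")
def ischemic_phantom():
    return generate_phantom(PhantomSpec(mode="ischemic", seed=3))
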