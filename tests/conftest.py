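import numpy as np
import pytest

import mridenoise as md


@pytest.fixture(scope="session")
def small_phantom():
    """Ground truth, noisy acquisition and mask at a fast test size."""
    truth = md.generate_head_phantom(md.PhantomSpec(dims=(48, 48, 11)))
    noisy = md.simulate_acquisition(truth, sigma=4.0, seed=101)
    return truth, noisy, md.brain_mask(truth)


@pytest.fixture(scope="session")
def small_denoise(small_phantom):
    """Denoised result for the small phantom, shared across tests."""
    truth, noisy, mask = small_phantom
    result = md.run_map_denoise(noisy, sigma=4.0)
    return truth, noisy, mask, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
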