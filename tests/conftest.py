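import numpy as np
import pytest

from abrstab.synthetic_abr import NoiseModel, make_template, simulate_sweeps

BUFFER_LAYOUT = [("A", "condensation"), ("A", "rarefaction"),
                 ("B", "condensation"), ("B", "rarefaction")]


@pytest.fixture(scope="session")
def click_template():
    return make_template("click", 20000)


@pytest.fixture(scope="session")
def da_template():
    return make_template("da40", 20000, 100.0)


def make_da_buffer_set(template, noise_model, n_sweeps, seed0=0):
    """Four (channel, polarity) buffers for one simulated participant."""
    return [
        simulate_sweeps(template, noise_model, n_sweeps, ch, pol, seed=seed0 + i)
        for i, (ch, pol) in enumerate(BUFFER_LAYOUT)
    ]


@pytest.fixture(scope="session")
def quiet_noise():
    """Low-noise white model: fast to simulate, near-noiseless stability."""
    return NoiseModel(noise_sd=0.2, jitter_sd=0.0, amp_cv=0.0, noise_band=None)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(noise_sd=0.0, jitter_sd=0.0, amp_cv=0.0)
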