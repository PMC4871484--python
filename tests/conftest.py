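import numpy as np
import pytest

import prflash as pf

TRUE_LIFETIMES = np.array([3.5e-6, 84e-6, 11e-3, 82e-3])


@pytest.fixture(scope="session")
def default_scheme():
    return pf.e17r_scheme()


@pytest.fixture(scope="session")
def noiseless_dataset(default_scheme):
    """Full-size noiseless two-oscilloscope dataset (computed once)."""
    acq = pf.AcquisitionConfig(seed=0, noise_sd=0.0)
    return pf.make_photocycle_dataset(default_scheme, acq)


@pytest.fixture(scope="session")
def noisy_merged(default_scheme):
    """Reduced+merged default dataset at 0.3 mOD noise, fixed seed."""
    acq = pf.AcquisitionConfig(seed=1)
    fast, slow = pf.make_photocycle_dataset(default_scheme, acq)
    return pf.merge_traces(pf.reduce_log_blocks(fast), pf.reduce_log_blocks(slow))


@pytest.fixture(scope="session")
def noiseless_merged(noiseless_dataset):
    fast, slow = noiseless_dataset
    return pf.merge_traces(pf.reduce_log_blocks(fast), pf.reduce_log_blocks(slow))


@pytest.fixture(scope="session")
def toy_sequences():
    return pf.make_toy_sequences(seed=0)


def two_state_scheme(k: float, excited_name: str = "E") -> pf.PhotocycleScheme:
    """Excited state decaying to ground at rate k (k = 0 allowed)."""
    states = [
        pf.PhotocycleState(excited_name, pf.SpectralBand(560.0, 100.0, 52_000.0)),
        pf.PhotocycleState("ground", pf.SpectralBand(524.0, 100.0, 50_000.0), is_ground=True),
    ]
    K = np.array([[-k, 0.0], [k, 0.0]])
    return pf.PhotocycleScheme(states, K, np.array([1.0, 0.0]))


def chain_scheme(k1: float, k2: float) -> pf.PhotocycleScheme:
    """A -> B -> C(ground) with distinct bands."""
    states = [
        pf.PhotocycleState("A", pf.SpectralBand(560.0, 100.0, 52_000.0)),
        pf.PhotocycleState("B", pf.SpectralBand(600.0, 110.0, 42_000.0)),
        pf.PhotocycleState("ground", pf.SpectralBand(524.0, 100.0, 50_000.0), is_ground=True),
    ]
    K = np.array([[-k1, 0.0, 0.0], [k1, -k2, 0.0], [0.0, k2, 0.0]])
    return pf.PhotocycleScheme(states, K, np.array([1.0, 0.0, 0.0]))
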