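import numpy as np
import pytest

import bgoctr
from bgoctr.preprocess import extract_timing_records


@pytest.fixture(scope="session")
def selection():
    return bgoctr.SelectionConfig()


@pytest.fixture(scope="session")
def small_ds():
    """2000 default-config coincidence pairs, shared across tests."""
    return bgoctr.generate_dataset(bgoctr.SimConfig(n_events=2000, seed=11))


@pytest.fixture(scope="session")
def small_records(small_ds, selection):
    return extract_timing_records(small_ds, selection)


def ideal_sim_config(**overrides) -> bgoctr.SimConfig:
    """A jitter-free, noise-free single-Cherenkov-photon configuration.

    Every channel detects exactly one prompt photon with a fixed-amplitude
    pulse, so the low-threshold crossing is an exact, deterministic
    function of the interaction time.
    """
    base = dict(noise_sigma=0.0, cell_amplitude_cv=0.0, sptr_sigma=0.0,
                transit_spread_coeff=0.0, detected_scint_yield=0.0,
                cherenkov_count_fixed=1, photopeak_fraction=1.0,
                energy_resolution_fwhm_frac=0.0)
    base.update(overrides)
    return bgoctr.SimConfig(**base)


def make_kernel(r_c, sigma_c, sigma_s, mu=0.0, N=1.0) -> bgoctr.KernelFit:
    return bgoctr.KernelFit(N=N, mu=mu, r_c=r_c, sigma_c=sigma_c,
                            sigma_s=sigma_s)


def sample_mixture(rng, n, r_c, sigma_c, sigma_s, mu=0.0) -> np.ndarray:
    """Direct sampler of the two-Gaussian TOF kernel (test oracle)."""
    narrow = rng.random(n) < r_c
    sd = np.where(narrow, sigma_c, sigma_s)
    return mu + sd * rng.standard_normal(n)
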