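import numpy as np
import pytest

from lungjac.phantom import PhantomParams, simulate_phantom


@pytest.fixture(scope="session")
def noiseless_case():
    """Default-geometry phantom without noise (mass-conservation holds exactly)."""
    return simulate_phantom(
        PhantomParams(noise_sd_frc=0.0, noise_sd_tlc=0.0, seed=11, case_id="noiseless")
    )


@pytest.fixture(scope="session")
def default_case():
    """Default phantom with dose-dependent noise."""
    return simulate_phantom(PhantomParams(seed=7, case_id="default"))


@pytest.fixture(scope="session")
def affine_case():
    """Pure-effort phantom: uniform J = 2 in the FRC frame."""
    return simulate_phantom(
        PhantomParams(effort=2.0, heterogeneity=0.0, disease_fraction=0.0,
                      noise_sd_frc=0.0, noise_sd_tlc=0.0, seed=5, case_id="affine")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
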