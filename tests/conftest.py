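import numpy as np
import pytest

from agegrowth import GrowthParams, SpecimenRecord, SyntheticConfig
from agegrowth.simulate import generate_age_length, generate_population

VBG3_TRUTH = GrowthParams("VBG3", l_inf=81.87, k=0.168, t0=-1.384)


@pytest.fixture(scope="session")
def truth_params():
    return VBG3_TRUTH


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_age_length():
    """Deterministic mid-size age-length sample for fitting tests."""
    ages, lengths = generate_age_length(400, VBG3_TRUTH, sigma_length=0.06, seed=7)
    return ages, lengths


@pytest.fixture(scope="session")
def default_population():
    config = SyntheticConfig(n_specimens=120, seed=11)
    return generate_population(config)


@pytest.fixture(scope="session")
def noisefree_population():
    config = SyntheticConfig(
        n_specimens=120, sigma_length=0.0, vr_noise_sd=0.0, seed=11
    )
    return generate_population(config)


def make_specimen(
    specimen_id="S1",
    sex="female",
    total_length=60.0,
    capture_year=2014,
    capture_month=5,
    vertebral_radius=5.0,
    band_radii=(0.8, 2.0, 3.1, 4.0),
    edge_type="opaque",
):
    return SpecimenRecord(
        specimen_id=specimen_id,
        sex=sex,
        total_length=total_length,
        capture_year=capture_year,
        capture_month=capture_month,
        vertebral_radius=vertebral_radius,
        band_radii=band_radii,
        edge_type=edge_type,
    )
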