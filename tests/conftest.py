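import numpy as np
import pytest

from condrop import shapes, synth_data


@pytest.fixture(scope="session")
def hemisphere_cap():
    return shapes.SphericalCap(theta_deg=90.0, r_contact=15.0)


@pytest.fixture(scope="session")
def hemisphere_stack(hemisphere_cap):
    prof = shapes.cap_profile(hemisphere_cap, n_points=400)
    return synth_data.voxelize(prof, spacing=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def yl_profile_120():
    """Noiseless Young-Laplace profile: theta 120 deg, r_contact 15 um,
    lc 500 um."""
    profile, params = shapes.profile_for_contact(120.0, 15.0, 500.0, n_points=150)
    return profile, params


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
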