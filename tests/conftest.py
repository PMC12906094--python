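import numpy as np
import pytest
from scipy import ndimage

import mrdose as m
from mrdose import phantoms as ph

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def water_phantom():
    """Homogeneous water cylinder, 64^3 at 3 mm, air density zero."""
    return ph.build_phantom("water_cylinder", air_density=0.0)


@pytest.fixture(scope="session")
def delta4_phantom():
    return ph.build_phantom("delta4_like")


@pytest.fixture(scope="session")
def film_phantom():
    return ph.build_phantom("waterbag_film")


@pytest.fixture(scope="session")
def clean_model():
    return m.BeamModel(noise_rel_sd=0.0)


@pytest.fixture(scope="session")
def noisy_model():
    return m.BeamModel(noise_rel_sd=0.05)


@pytest.fixture(scope="session")
def open_aperture():
    return m.Aperture.open_field(10.0, 10.0)


@pytest.fixture(scope="session")
def small_plan():
    return ph.make_plan(4, 7.0, 7.5, seed=1, total_mu=28.0)


@pytest.fixture(scope="session")
def textured_volume():
    """Smooth random intensity volume for registration tests."""
    rng = np.random.default_rng(0)
    vals = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 4.0)
    vals = (vals - vals.min()) / (vals.max() - vals.min())
    return m.Volume(vals, (3.0, 3.0, 3.0), (-70.5, -70.5, -70.5))


def make_message(t, mu, beam_on, aperture=None, gantry=0.0):
    ap = aperture or m.Aperture.open_field(10.0, 10.0)
    return m.LinacStateMessage(t, gantry, ap, mu, beam_on)
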