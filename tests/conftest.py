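import numpy as np
import pytest
from hypothesis import settings

import camoquant as cq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def obs():
    """The triplefin observer shared by all tests."""
    return cq.triplefin_observer()


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced-scale scene configuration for fast pipeline tests.

    45 px/cm keeps the acuity-blur sampling requirement satisfied
    (>2 px per cycle at 7 cpd and 20 cm) while staying far cheaper than the
    experimental 83 px/cm.
    """
    return cq.SceneConfig(canvas_size_px=(240, 320), px_per_cm=45.0, seed=0)


def constant_catches(value, shape=(20, 20), px_per_cm=45.0):
    """A uniform three-channel catch image for filter/metric tests."""
    q = np.full(shape + (3,), float(value))
    return cq.ConeCatchImage(q, ("468", "517", "530"), px_per_cm=px_per_cm)


@pytest.fixture
def make_catches():
    def _make(lum_array, px_per_cm=45.0):
        lum_array = np.asarray(lum_array, dtype=float)
        q = np.repeat(lum_array[..., None], 3, axis=-1)
        return cq.ConeCatchImage(q, ("468", "517", "530"), px_per_cm=px_per_cm)
    return _make
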