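import numpy as np
import pytest

from phycosat.rlc import DEFAULT_ACTINIC_STEPS, RapidLightCurve, webb_yield


@pytest.fixture
def rng():
    return np.random.default_rng(20210920)


def make_curve(alpha, ek, noise_sd=0.0, rng=None, plant_id="p1", day_label="D9"):
    """Curve on the nine standard actinic steps from the Webb surface."""
    e = np.asarray(DEFAULT_ACTINIC_STEPS, dtype=float)
    phi = webb_yield(e, alpha, ek)
    if noise_sd > 0:
        phi = phi + rng.normal(0, noise_sd, size=e.shape)
    phi = np.clip(phi, 0.0, 1.0)
    return RapidLightCurve.from_arrays(plant_id, day_label, e, phi)


@pytest.fixture
def curve_factory():
    return make_curve
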