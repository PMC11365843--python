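import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bvlkit.phantom import AtrophySpec, PhantomSpec, make_pair
from bvlkit.volumetry import CalibrationParams

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

# Desk-scale geometry for fast unit tests: same proportions as the default
# phantom, 32^3 grid.
SMALL_SPEC = PhantomSpec(
    grid_size=(32, 32, 32),
    skull_radii_mm=(10.0, 12.0, 10.0),
    tiv_radii_mm=(8.0, 9.6, 8.0),
    ventricle_radii_mm=(2.0, 2.4, 2.0),
)


@pytest.fixture
def small_spec() -> PhantomSpec:
    return SMALL_SPEC


@pytest.fixture
def unit_cal() -> CalibrationParams:
    return CalibrationParams.unit()


@pytest.fixture
def small_pair():
    """A noise-free 32^3 pair with 2% atrophy and exact truth."""
    return make_pair(SMALL_SPEC, AtrophySpec(-2.0, "radial", 1.0, seed=3))


@pytest.fixture(scope="session")
def trained_setup():
    """Desk-scale registration training shared across the suite.

    Trains the U-Net once (16 jittered phantom pairs, 40 epochs, 64^3) and
    fits the rescaling calibration on the training cohort; the same procedure
    the acceptance script runs.
    """
    from bvlkit import study

    backend, train_pairs, history = study.train_desk_backend(seed=1)
    cal = study.fit_rescale_for_backend(backend, train_pairs)
    return {"backend": backend, "train_pairs": train_pairs, "history": history, "cal": cal}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
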