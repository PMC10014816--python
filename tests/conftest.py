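import numpy as np
import pytest
from hypothesis import settings

from dpdcm.model import (DEFAULT_PHYSIO, PhysioParams, RegionGraphSpec, StimulusSet,
                         validate_model)
from dpdcm.presets import preset_models, simulate_preset
from dpdcm.profiles import make_stimulus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DT = 1.0 / 32


@pytest.fixture(scope="session")
def params() -> PhysioParams:
    return DEFAULT_PHYSIO


@pytest.fixture(scope="session")
def case_a():
    return preset_models("three_region_case_a")


@pytest.fixture(scope="session")
def case_a_truth(case_a):
    """Noiseless ground-truth trajectory of the 3-region preset."""
    return simulate_preset(case_a)


def two_region_model(duration: float = 30.0, a01: float = 0.3, c: float = 0.1,
                     dt: float = DT):
    """Small driven 2-region chain used across unit tests."""
    n = int(round(duration / dt)) + 1
    grid = np.arange(n) * dt
    u = make_stimulus("block", grid, 1.0, 2.0, duration - 5.0)
    stim = StimulusSet(dt=dt, duration=duration, driving=u[None, :],
                       modulatory=np.zeros((0, n)), mu_context=np.zeros((0, n)),
                       lambda_context=np.zeros((0, n)))
    graph = RegionGraphSpec(n_regions=2, edges={(0, 1): a01},
                            driving_map={(0, 0): c})
    return validate_model(graph, DEFAULT_PHYSIO, stim)


@pytest.fixture()
def small_model():
    return two_region_model()


def random_hemo_states(rng: np.random.Generator, n: int):
    """Physiologically plausible random (a, f, v, q) draws."""
    a = rng.normal(0, 0.3, n)
    f = rng.uniform(0.5, 2.0, n)
    v = rng.uniform(0.7, 1.5, n)
    q = rng.uniform(0.5, 1.5, n)
    return a, f, v, q
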