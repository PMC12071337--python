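import numpy as np
import pytest
from hypothesis import settings

import tgephys as tg

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

DT = 5e-5  # 20 kHz


@pytest.fixture(scope="session")
def group_specs():
    """The packaged nine-group parameterization."""
    return tg.default_group_specs()


@pytest.fixture(scope="session")
def quiet():
    """Zero trace noise for exact round-trip checks."""
    return tg.NoiseLevels(mv=0.0, pa=0.0)


@pytest.fixture(scope="session")
def tiny_cohort(quiet):
    """A small noise-free cohort (about one neuron per group)."""
    specs = tg.default_group_specs(n_scale=0.05)
    return tg.simulate_cohort(specs, noise=quiet, seed=11)


def random_ap_params(rng: np.random.Generator) -> tg.APShapeParams:
    """A random but geometrically feasible AP parameterization."""
    shape = rng.choice(["linear", "double_peak", "deflection"])
    rmp = rng.uniform(-70, -45)
    peak = rng.uniform(25, 40)
    ahp_peak = rng.uniform(-15, -2)
    ahp80 = rng.uniform(5, 60)
    if shape == "linear":
        db, hump = rng.uniform(1.5, 10), 0.0
    elif shape == "deflection":
        db, hump = rng.uniform(3.0, 8.0), rng.uniform(-1.2, -0.2)
    else:
        db = rng.uniform(5.2, 12.0)
        drop = peak - (rmp + ahp_peak)
        cap = drop / (1.3 * 0.6375 * (db - 0.7))
        hump = -min(rng.uniform(6.5, 15.0), 0.999 * cap)
        if cap < 6.5:  # not enough drop for a detectable hump at this width
            db = 0.7 + drop / (1.3 * 0.6375 * 6.6)
            hump = -6.5
    return tg.APShapeParams(
        rmp=rmp,
        peak_v=peak,
        target_db=db,
        shape_class=shape,
        hump_metric=hump,
        ahp_peak=ahp_peak,
        ahp80=ahp80,
    )
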