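import numpy as np
import pytest

import mixkin
from mixkin.datasets import lassi_spec, load_fixtures


@pytest.fixture(scope="session")
def spec():
    return lassi_spec()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def optimum_pseudo(spec):
    """The optimum formulation mapped to pseudo-component proportions."""
    return mixkin.to_pseudo([9.189, 60.0, 15.311], spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_feasible_amounts(spec, rng, n):
    """Uniform sample of feasible actual amounts on the bounded simplex."""
    lo = np.asarray(spec.lower_bounds)
    hi = np.asarray(spec.upper_bounds)
    scale = spec.pseudo_scale
    out = np.empty((n, 3))
    i = 0
    while i < n:
        # Dirichlet on the pseudo simplex, rejected against upper bounds
        p = rng.dirichlet(np.ones(3))
        x = lo + p * scale
        if np.all(x <= hi + 1e-12):
            out[i] = x
            i += 1
    return out
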