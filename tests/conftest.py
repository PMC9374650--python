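import numpy as np
import pytest

import paircomp as pc
from paircomp.model import ModelSpec, ParameterSet
from paircomp.simulate import SimulationDesign, simulate_contests

LAMBDA_TRUE = np.array([1.0, 0.5, 0.0, -0.5, -1.0])


@pytest.fixture(scope="session")
def bt_fit():
    """One moderately sized Bradley-Terry fit shared across tests.

    5 players with centered true abilities, 2000 round-robin contests,
    2 chains x 1000 retained draws.
    """
    spec = ModelSpec.from_string("bt")
    data, truth = simulate_contests(SimulationDesign(
        spec=spec, true_params=ParameterSet(lam=LAMBDA_TRUE.copy()),
        n_contests=2000, seed=101))
    draws = pc.sample_posterior(
        spec, data,
        pc.SamplerConfig(chains=2, iterations=1500, warmup=500, seed=202))
    return spec, data, truth, draws


@pytest.fixture(scope="session")
def davidson_fit():
    """A Davidson fit with ties, for three-outcome posterior products."""
    spec = ModelSpec.from_string("davidson")
    data, truth = simulate_contests(SimulationDesign(
        spec=spec,
        true_params=ParameterSet(lam=np.array([0.6, 0.0, -0.6]), nu=-0.2),
        n_contests=900, seed=303))
    draws = pc.sample_posterior(
        spec, data,
        pc.SamplerConfig(chains=2, iterations=1200, warmup=500, seed=404))
    return spec, data, truth, draws
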