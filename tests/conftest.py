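import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from antithetic import (
    AIFParams,
    GeneExpressionProcess,
    SaturationFunctions,
    aif_loop,
)
from antithetic.crn import Reaction, ReactionNetwork

# Canonical study conditions used across the suite: the basic AIF loop with
# unit-rate gene expression (setpoint 10), and the saturated loop with Hill
# actuation/sensing (theta=15, k=8, kappa=5; output setpoint 10).


@pytest.fixture
def gene_process():
    return GeneExpressionProcess()  # unit rates, no basal transcription


@pytest.fixture
def birth_death():
    return ReactionNetwork(
        species_names=["x"],
        reactions=[
            Reaction((1,), lambda x, t: 2.0, "birth"),
            Reaction((-1,), lambda x, t: 1.0 * x[0], "death"),
        ],
        parameters={"lam": 2.0, "gamma": 1.0},
    )


@pytest.fixture
def basic_aif_params():
    return AIFParams(mu=10.0, theta=1.0, eta=100.0, k=1.0)


@pytest.fixture
def basic_aif_loop(gene_process, basic_aif_params):
    return aif_loop(gene_process, basic_aif_params)


@pytest.fixture
def sat_params():
    return AIFParams(mu=10.0, theta=15.0, eta=100.0, k=8.0)


@pytest.fixture
def sat_sats():
    return SaturationFunctions.hill_pair(5.0, 5.0)


@pytest.fixture
def sat_loop(sat_params, sat_sats):
    return aif_loop(GeneExpressionProcess(delta=5.0), sat_params, sat_sats)


@pytest.fixture
def rng():
    return np.random.default_rng(20240821)
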