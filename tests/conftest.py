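import numpy as np
import pytest

from acoscale.aco import AcoConfig, CandidateEvaluator
from acoscale.simulate import (
    implied_latent_correlation,
    make_default_true_model,
    simulate_responses,
)


@pytest.fixture(scope="session")
def tiny_model():
    """28-item pool (7 per domain), hierarchical truth with mixed loadings."""
    return make_default_true_model((7, 7, 7, 7), structure="hierarchical", seed=11)


@pytest.fixture(scope="session")
def tiny_table(tiny_model):
    return simulate_responses(tiny_model, 300, 100, seed=12)


@pytest.fixture(scope="session")
def tiny_evaluator(tiny_table, tiny_model):
    return CandidateEvaluator(tiny_table, tiny_model.scale_map, AcoConfig())


@pytest.fixture(scope="session")
def full_model():
    """Default 97-item hierarchical generating model."""
    return make_default_true_model(structure="hierarchical", seed=3)


@pytest.fixture(scope="session")
def full_population_matrix(full_model):
    return implied_latent_correlation(full_model)
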