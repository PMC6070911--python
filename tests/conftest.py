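import pytest

from ansaflux.synthetic import (
    ExpressionSim,
    ToyModelSpec,  # noqa: F401  (re-export convenience)
    default_condition_specs,
    make_expression,
    make_toy_model,
)


@pytest.fixture(scope="session")
def toy_model():
    """The default seeded toy GSMM (read-only across tests; copy before mutating)."""
    return make_toy_model()


@pytest.fixture()
def toy_model_copy(toy_model):
    return toy_model.copy()


@pytest.fixture(scope="session")
def toy_profile(toy_model):
    return make_expression(toy_model, ExpressionSim(seed=0))


@pytest.fixture(scope="session")
def condition_specs():
    return default_condition_specs()
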