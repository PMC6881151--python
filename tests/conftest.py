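import numpy as np
import pytest

from lagcausal import LaggedVariable, Link, StructuralModel, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def chain_model():
    """X1 -> X2 -> X3, each at lag 1 with coefficient 0.6, plus weak
    autodependencies — the canonical indirect-path fixture."""
    return StructuralModel(
        N=3,
        links=[
            [Link(LaggedVariable(0, 1), 0.5)],
            [Link(LaggedVariable(1, 1), 0.5), Link(LaggedVariable(0, 1), 0.6)],
            [Link(LaggedVariable(2, 1), 0.5), Link(LaggedVariable(1, 1), 0.6)],
        ],
    )


@pytest.fixture
def chain_data(chain_model):
    return simulate(chain_model, 2000, seed=42)


def ar1_noise_model(N: int, a: float) -> StructuralModel:
    """N mutually independent AR(1) processes with coefficient a."""
    links = [[Link(LaggedVariable(j, 1), a)] for j in range(N)] if a != 0 else [[] for _ in range(N)]
    return StructuralModel(N=N, links=links)
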