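import numpy as np
import pytest

from crisprlv import ModelSpec, Params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_params(rng, model: ModelSpec) -> Params:
    """A parameter draw kept inside the numerically well-behaved box the
    package documents (rates O(0.01..1), burst factors O(10..200))."""
    s = float(rng.uniform(0.05, 0.5))
    return Params(
        l=float(rng.uniform(0.05, 1.2)),
        e=float(rng.uniform(0.05, 1.0)),
        d=float(rng.uniform(0.5, 2.0)),
        M=float(np.exp(rng.uniform(np.log(5.0), np.log(200.0)))),
        b=float(np.exp(rng.uniform(np.log(0.01), np.log(0.2)))),
        a=1.0 if model.growth == "logistic" else 0.0,
        k=float(rng.uniform(0.1, 1.0)),
        s=s,
        p_const=float(rng.uniform(s, 1.0)) if model.immunity_mode == "constant" else None,
    )


@pytest.fixture
def fig2_setup():
    model = ModelSpec("three", "logistic", "virus_dependent")
    params = Params(l=0.1, e=0.5, d=1.0, M=98.225, b=0.05, a=1.0, k=0.1, s=0.2)
    return model, params


@pytest.fixture
def fig1_setup():
    model = ModelSpec("three", "malthusian", "virus_dependent")
    params = Params(l=0.9, e=0.1, d=1.0, M=100.0, b=0.01, a=0.0, k=0.5, s=0.1)
    return model, params
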