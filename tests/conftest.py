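import numpy as np
import pytest
from hypothesis import settings

from obscstr.config import DEFAULT_KINETIC_BOUNDS, DEFAULT_PARAMS
from obscstr.model import SubstituteKinetics, build_affine_model, \
    mean_parameterize

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def sub_so():
    return mean_parameterize(DEFAULT_KINETIC_BOUNDS, form="SO")


@pytest.fixture(scope="session")
def model_factory(params):
    """AffineModel for a given (output_index, form)."""
    def make(output_index: int, form: str):
        sub = mean_parameterize(DEFAULT_KINETIC_BOUNDS, form=form)
        return build_affine_model(params, sub, output_index)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
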