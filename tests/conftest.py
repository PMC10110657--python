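import numpy as np
import pytest

from retropbtk import synthetic
from retropbtk.parameters import load_parameter_set


@pytest.fixture(scope="session")
def mouse_params():
    return load_parameter_set(species="mouse")


@pytest.fixture(scope="session")
def rat_params():
    return load_parameter_set(species="rat")


@pytest.fixture(scope="session")
def both_params(mouse_params, rat_params):
    return {"mouse": mouse_params, "rat": rat_params}


@pytest.fixture(scope="session")
def synthetic_dataset(both_params):
    """One noisy in vivo dataset generated at the packaged truths."""
    design = synthetic.SyntheticDesign(truth=both_params, seed=42)
    return synthetic.generate_invivo_dataset(design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230311)
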