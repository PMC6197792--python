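import numpy as np
import pytest

from ncfger import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A 40 x 12 synthetic panel with the default statistical structure."""
    spec = SyntheticSpec(m=40, n=12, n_genes=200, seed=3)
    response, expression, fingerprints, truth = generate(spec)
    return {
        "spec": spec,
        "response": response,
        "expression": expression,
        "fingerprints": fingerprints,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
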