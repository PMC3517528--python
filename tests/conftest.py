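import numpy as np
import pytest

import mitekit


@pytest.fixture(scope="session")
def reference():
    """The bundled synthetic 610-bp reference element."""
    return mitekit.load_synthetic_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
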