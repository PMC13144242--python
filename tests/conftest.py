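import numpy as np
import pytest

from catlgm import Condition, condition_to_spec


@pytest.fixture(scope="session")
def shift_large_spec():
    """Growth spec of the shift-pattern / large-slope design cell."""
    return condition_to_spec(Condition("shift", "large", 2, 1000))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
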