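import numpy as np
import pytest

import thickpen as tp


@pytest.fixture
def rng():
    return np.random.default_rng(20260417)


@pytest.fixture(scope="session")
def study_curves():
    """One full synthetic survey design (cell-level curves, shared grid)."""
    return tp.simulate_study(seed=7)


@pytest.fixture(scope="session")
def shared_grid():
    return tp.make_grid(tp.SpectrumScenario(seed=7))
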