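import numpy as np
import pytest

from erpdecode import ParadigmSpec, default_templates


@pytest.fixture
def spec():
    return ParadigmSpec()


@pytest.fixture
def small_spec():
    """Cheap paradigm for pipeline tests: 5 selections, 10 sequences."""
    return ParadigmSpec(n_selections_per_phase=5)


@pytest.fixture
def templates():
    return default_templates()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
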