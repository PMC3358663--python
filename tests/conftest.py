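import random

import pytest

from spliceagree.params import Parameters


@pytest.fixture
def small_params():
    """Thresholds scaled down for compact hand-built instances."""
    return Parameters(ell_E=6, ell_D=8, ell_I=20, min_factor_len=4,
                      end_clip=6, source_window=10)


@pytest.fixture
def rng():
    return random.Random(20260930)
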