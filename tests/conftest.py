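import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from archolimb import make_skeleton  # noqa: E402


@pytest.fixture(scope="session")
def skeleton():
    """One shared synthetic hindlimb skeleton with ground truth."""
    return make_skeleton(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass
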