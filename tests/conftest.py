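import numpy as np
import pytest

from animats.world import builtin_world


def mt(seed: int) -> np.random.Generator:
    """Mersenne-Twister generator, as used throughout the package."""
    return np.random.Generator(np.random.MT19937(seed))


@pytest.fixture(scope="session")
def original_world():
    return builtin_world("original")


@pytest.fixture(scope="session")
def all_worlds():
    from animats.world import WORLD_NAMES

    return {name: builtin_world(name) for name in WORLD_NAMES}
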