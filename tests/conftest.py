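import numpy as np
import pytest

from remapsim import maze as mz


@pytest.fixture(scope="session")
def maze():
    return mz.build_tmaze()


@pytest.fixture(scope="session")
def maze_left():
    return mz.build_tmaze("left")


@pytest.fixture(scope="session")
def ctx_a():
    return mz.ContextSpec(phase_label="A", salience=1.0)


@pytest.fixture(scope="session")
def ctx_b():
    return mz.ContextSpec(phase_label="B", salience=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
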