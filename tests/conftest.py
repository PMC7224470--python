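import logging

import pytest

from fibsrt.grammar import FIB, SKIP, derive
from fibsrt.trials import build_trials

# the listwise-drop warnings are expected under heavy simulation
logging.getLogger("fibsrt.stats").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fib20():
    """Fibonacci derivation up to generation 20."""
    return derive(FIB, "0", 20)


@pytest.fixture(scope="session")
def skip6():
    """Skip derivation up to generation 6."""
    return derive(SKIP, "0", 6)


@pytest.fixture(scope="session")
def default_trials():
    """The 330-trial task with default configuration."""
    return build_trials()
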