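import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.uint8)


@pytest.fixture
def path3():
    """P3: A-B-C."""
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)


@pytest.fixture
def star4():
    """S4: center node 0 with three leaves."""
    a = np.zeros((4, 4), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


@pytest.fixture
def cycle4():
    return np.array(
        [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=np.uint8
    )


@pytest.fixture
def complete4():
    return (np.ones((4, 4)) - np.eye(4)).astype(np.uint8)


@pytest.fixture
def complete5():
    return (np.ones((5, 5)) - np.eye(5)).astype(np.uint8)


@pytest.fixture
def two_disjoint_edges():
    """Four nodes, edges AB and CD only."""
    a = np.zeros((4, 4), dtype=np.uint8)
    a[0, 1] = a[1, 0] = 1
    a[2, 3] = a[3, 2] = 1
    return a
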