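import numpy as np
import pytest

import bsacross as b


@pytest.fixture(scope="session")
def tiny_map():
    """Sixteen markers, one per chromosome (zero within-chromosome recombination)."""
    return b.build_marker_map(16, seed=11)


@pytest.fixture(scope="session")
def small_map():
    """Scaled 400-marker map preserving the real per-marker density."""
    return b.scaled_marker_map(400, seed=5)


@pytest.fixture(scope="session")
def mid_map():
    """Scaled 2,000-marker map used by the end-to-end mapping tests."""
    return b.scaled_marker_map(2000, seed=5)


@pytest.fixture(scope="session")
def rules():
    return b.default_rule_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
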