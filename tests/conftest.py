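import numpy as np
import pytest

from mcistab import make_fixture
from mcistab.stability import SelectionConfig


@pytest.fixture(scope="session")
def separable():
    """Bundled linearly separable cohort (5 planted features at d = 2.5)."""
    return make_fixture("separable")


@pytest.fixture(scope="session")
def null_cohort():
    """Bundled pure-noise cohort (no planted effects)."""
    return make_fixture("null")


@pytest.fixture(scope="session")
def fast_selection():
    """Reduced selection protocol for tests that exercise the full loop.

    Fewer subsamples and a coarser RFE step keep the loop's statistical
    structure (stratified half-splits, filter -> wrapper -> tally) while
    running in seconds.
    """
    return SelectionConfig(n_subsamples=25, rfe_step=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250927)
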