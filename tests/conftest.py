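import numpy as np
import pytest
from shapely.geometry import box

import spatialtme as st


@pytest.fixture(scope="session")
def square_window():
    """1 x 1 mm observation window."""
    return box(0, 0, 1000, 1000)


@pytest.fixture(scope="session")
def big_window():
    """2 x 2 mm observation window (Thomas study conditions)."""
    return box(0, 0, 2000, 2000)


@pytest.fixture(scope="session")
def thomas_pattern(big_window):
    """One Thomas realisation at the study parameters (kappa=10, mu=20, sigma=20)."""
    return st.sim_thomas(10.0, 20.0, 20.0, big_window, seed=42)


@pytest.fixture(scope="session")
def phantom():
    """Default tumor phantom: 5 annotations, 5 marker patterns, ground truth."""
    return st.sim_tumor_phantom(st.PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def phantom_partition(phantom):
    _, _, truth = phantom
    return truth
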