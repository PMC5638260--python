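import numpy as np
import pytest

import encounternet as en


@pytest.fixture(scope="session")
def unit_square_100():
    """100 uniform sites in the unit square with their distance matrix."""
    loc = en.generate_locations(100, seed=7)
    return loc, en.pairwise_distances(loc)


@pytest.fixture(scope="session")
def three_collinear():
    """Hand-checkable 3-site geometry at x = 0, 0.05, 1.0."""
    loc = en.LocationSet(np.array([[0.0, 0.0], [0.05, 0.0], [1.0, 0.0]]))
    return loc, en.pairwise_distances(loc)


@pytest.fixture(scope="session")
def small_synthetic_table():
    """Compact synthetic check-in stream shared across pipeline tests."""
    cfg = en.SyntheticConfig(n_users=12, duration_h=24 * 15, p_hotspot=0.4,
                             n_hotspots=8, seed=42)
    return en.generate(cfg)
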