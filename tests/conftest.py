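import numpy as np
import pytest

from atrophymap.synthetic import CohortSpec, Ellipsoid


@pytest.fixture
def small_spec() -> CohortSpec:
    """A fast-to-generate cohort spec used across test modules."""
    return CohortSpec(
        n_subjects=20,
        grid_shape=(12, 12, 12),
        planted_region=Ellipsoid(center=(6.0, 6.0, 6.0), radii=(3.0, 3.0, 3.0)),
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140528)
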