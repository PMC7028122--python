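import numpy as np
import pytest

from tabvis import CohortConfig, SearchGrid, generate_cohort


@pytest.fixture(scope="session")
def grid():
    return SearchGrid()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (50 participants, 30 with faces data,
    two runs each), shared read-only across the suite."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 8-participant cohort for I/O round trips."""
    cfg = CohortConfig(n_participants=8, n_faces_reported=5, n_face_trials=10)
    return generate_cohort(config=cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
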