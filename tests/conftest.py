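import numpy as np
import pytest

import avoidspace as av
from avoidspace import pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale synthetic cohort with its ground truth."""
    return av.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def aligned(default_cohort):
    """Joint subspace + decomposition for the default cohort."""
    cohort, truth = default_cohort
    rng = np.random.default_rng(211)
    ac = pipeline.align_cohort(cohort, rng)
    basis, motion, avoid = pipeline.decompose_cohort(ac, rng)
    return ac, basis, motion, avoid


@pytest.fixture(scope="session")
def tiny_cohort():
    """A reduced cohort (fewer sessions/trials) for cheap integration tests."""
    return av.generate_cohort(
        n_subjects=2,
        n_cells_per_subject=30,
        seed=3,
        n_trials_per_session=25,
        days={3: 1, 6: 2},
    )
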