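import numpy as np
import pytest

from hubdisrupt.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete cohort shared by the slower integration tests."""
    cfg = CohortConfig(
        n_controls=6, n_patients=6, n_voxels=60, n_volumes=140, seed=7, roi_size=4
    )
    subjects, truth = generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
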