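import numpy as np
import pytest

from livernorm.synthetic import (CohortConfig, LesionSpec,
                                 generate_liver_volume)

# desk-scale phantom geometry reused across tests (≈1550 in-mask voxels)
SMALL_GRID = (32, 32, 32)
SMALL_AXES = (40.0, 30.0, 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240105)


@pytest.fixture
def small_cohort_config():
    return CohortConfig(n_subjects=200, abnormal_fraction=0.1, seed=7)


@pytest.fixture
def small_volume():
    vol, _ = generate_liver_volume(2.06, 0.42, grid_shape=SMALL_GRID,
                                   semi_axes_mm=SMALL_AXES, seed=11,
                                   subject_id="S0")
    return vol


@pytest.fixture
def lesioned_volume_pair():
    """Same-seed phantoms without and with one 2.0-contrast lesion."""
    clean, _ = generate_liver_volume(2.06, 0.42, grid_shape=SMALL_GRID,
                                     semi_axes_mm=SMALL_AXES, seed=5)
    spec = LesionSpec(n_lesions=1, radius_mm=8.0, contrast=2.0,
                      placement_margin_mm=2.0)
    hot, truth = generate_liver_volume(2.06, 0.42, lesions=spec,
                                       grid_shape=SMALL_GRID,
                                       semi_axes_mm=SMALL_AXES, seed=5)
    return clean, hot, truth
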