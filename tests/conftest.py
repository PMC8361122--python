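import numpy as np
import pytest

from olfmri.cohort import ClusterSpec, CohortConfig, generate_gm_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one strong planted pattern cluster (20 + 20)."""
    cfg = CohortConfig(
        n_group_a=20,
        n_group_b=20,
        grid_shape=(14, 14, 14),
        voxel_size_mm=3.0,
        smoothing_fwhm_mm=6.0,
        n_rois=4,
        n_volumes=30,
        n_unscored_b=0,
        planted_clusters=(ClusterSpec((7, 7, 7), 3, "pattern", 3.0),),
        seed=11,
    )
    maps, truth = generate_gm_cohort(cfg)
    return cfg, maps, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
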