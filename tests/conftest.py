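import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from mechspheroid.features_mech import extract_features
from mechspheroid.sim import CohortSpec, generate_cohort

COHORT_SEED = 20240501


@pytest.fixture(scope="session")
def cohort40():
    """Default-phenotype cohort, 40 spheroids per line per day."""
    spec = CohortSpec(n_normal=40, n_cancer=40, days=(2, 5, 8),
                      seed=COHORT_SEED)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def features40(cohort40):
    """Extracted feature table for the 40/group cohort."""
    return extract_features(cohort40.spheroids)


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 40 px."""
    mask = np.zeros((101, 101), dtype=bool)
    rr, cc = draw_disk((50, 50), 40)
    mask[rr, cc] = True
    return mask


@pytest.fixture
def square_mask():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:35, 5:35] = True
    return mask
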