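import numpy as np
import pytest
from shapely.geometry import Polygon

import nftburden as nb


@pytest.fixture(scope="session")
def regions():
    return nb.region_template()


@pytest.fixture()
def unit_square_region():
    """A 10 mm² rectangle at 1 µm/px scale: 5000 x 2000 px."""
    return nb.RegionAnnotation(
        label=nb.HIPPOCAMPUS,
        polygon=Polygon([(0, 0), (5000, 0), (5000, 2000), (0, 2000)]),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-subject spatial cohort shared by pipeline-level tests."""
    params = nb.CohortSimParams(n_subjects=40, seed=11)
    return nb.simulate_cohort(params, spatial=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
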