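import numpy as np
import pytest

from cmnet import SyntheticConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """20/20 subjects, 6 ROIs, one measurement, left hemisphere only."""
    config = SyntheticConfig(
        n_group_a=20,
        n_group_b=20,
        n_rois=6,
        measurements=("cortical_thickness",),
        hemispheres=("lh",),
        seed=5,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def shifted_cohort():
    """30/30 subjects, 8 ROIs, strong shift on ROI 3 in group B."""
    config = SyntheticConfig(
        n_group_a=30,
        n_group_b=30,
        n_rois=8,
        measurements=("sulcal_depth",),
        hemispheres=("lh",),
        injected_effects=(("sulcal_depth", 3, "female", 5.0),),
        seed=11,
    )
    return simulate_cohort(config)
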