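import numpy as np
import pytest

from fibroquant.phantom import CohortSpec, PhantomSpec


@pytest.fixture
def noise_free_spec() -> PhantomSpec:
    """A 128x128 two-tissue slice with no grey noise."""
    return PhantomSpec(target_ratio=0.25, grey_noise_sd=0.0)


@pytest.fixture
def small_cohort_spec() -> CohortSpec:
    """A fast four-group cohort on 64x64 slices, one compartment."""
    groups = {"lean_youth": 0.03, "lean_aged": 0.06, "obese_youth": 0.23, "obese_aged": 0.30}
    sems = {"lean_youth": 0.004, "lean_aged": 0.0104, "obese_youth": 0.0071, "obese_aged": 0.006}
    return CohortSpec(
        ratio_mean={"anterolateral_calf": groups},
        ratio_sem={"anterolateral_calf": sems},
        n_per_group=4,
        bilateral_asymmetry_sd=0.01,
        phantom=PhantomSpec(
            target_ratio=0.0,
            image_height=64,
            image_width=64,
            roi_margin=6,
            blob_scale=3.0,
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
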