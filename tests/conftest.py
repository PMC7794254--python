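import numpy as np
import pytest

from collasig.cohorts import CohortParams, generate_cohort
from collasig.fibers import FiberImageParams, generate_fiber_image
from collasig.image import SHGImage


@pytest.fixture(scope="session")
def default_fiber_image():
    """One 256-px fibrous image with its exact geometry."""
    params = FiberImageParams(image_size_px=256, n_fibers=120, seed=42)
    return generate_fiber_image(params)


@pytest.fixture(scope="session")
def medium_cohort():
    """800-patient cohort with two covariates and known coefficients."""
    params = CohortParams(
        n_patients=800,
        beta_true=(0.9, -0.5),
        p_base=0.35,
        competing_rate=0.25,
        censor_rate=0.20,
        horizon_yr=5.0,
        seed=7,
    )
    return params, generate_cohort(params)


@pytest.fixture()
def bimodal_image():
    """Half the pixels near 10, half near 200 — trivially separable."""
    rng = np.random.default_rng(0)
    arr = np.full((64, 64), 10.0)
    arr[:, 32:] = 200.0
    arr += rng.normal(0.0, 0.5, size=arr.shape)
    return SHGImage(np.clip(arr, 0, None), pixel_size_um=1.0)
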