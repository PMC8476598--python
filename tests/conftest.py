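import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from wsidbm.slide_core import ClassMask, SlideImage
from wsidbm.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, coarse-resolution cohort shared by the stage tests.

    8 µm/px keeps the 200/500 µm fields of view at 25/62 px so slides of
    160 px are several fields wide while training stays fast.
    """
    spec = CohortSpec(
        n_short_patients=4,
        n_long_patients=4,
        slides_per_patient=(2, 3),
        slide_size_px=(160, 160),
        resolution_um_per_px=8.0,
        mixture_bias=0.6,
        contrast=1.0,
        seed=123,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_holdout():
    spec = CohortSpec(
        n_short_patients=3,
        n_long_patients=3,
        slides_per_patient=(1, 1),
        slide_size_px=(160, 160),
        resolution_um_per_px=8.0,
        mixture_bias=0.6,
        contrast=1.0,
        patient_prefix="H",
        seed=321,
    )
    return generate_cohort(spec)


def make_slide(pixels: np.ndarray, res: float = 2.0, slide_id: str = "s1") -> SlideImage:
    return SlideImage(slide_id, "p1", pixels, res)


@pytest.fixture
def checker_slide():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, size=(120, 120, 3), dtype=np.uint8)
    return make_slide(px)


def full_mask(shape, slide_id="s1", cls="tumor", value=True):
    return ClassMask(slide_id, cls, np.full(shape, value, dtype=bool))
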