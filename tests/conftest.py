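import numpy as np
import pytest

from choroidtex import ImageSample, SyntheticConfig, generate_cohort, extract_table


def make_sample(image, mask=None, group="healthy", modality="horizontal", **kw):
    image = np.asarray(image)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    kw.setdefault("eye_id", "E0")
    kw.setdefault("patient_id", "P0")
    kw.setdefault("slice_index", 0)
    return ImageSample(image=image, mask=mask, group=group, modality=modality, **kw)


def random_roi_sample(rng, size=32, margin=4):
    """Random 8-bit image with an irregular random mask (always non-empty)."""
    img = rng.integers(0, 256, size=(size, size)).astype(np.uint8)
    mask = rng.random((size, size)) < 0.6
    mask[margin:-margin, margin:-margin] |= rng.random((size - 2 * margin,) * 2) < 0.8
    if not mask.any():
        mask[size // 2, size // 2] = True
    return make_sample(img, mask)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 healthy / 2 CSCR / 1 fellow eyes, 6 b-scans, 8 en face slices."""
    cfg = SyntheticConfig.desk_scale(
        n_healthy_eyes=2,
        n_cscr_eyes=2,
        n_fellow_eyes=1,
        bscans_per_eye=6,
        enface_slices_per_eye=8,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_features():
    """Feature table of a strong-effect desk cohort, horizontal b-scans only."""
    cfg = SyntheticConfig.desk_scale(seed=11, enface_slices_per_eye=0)
    ds = generate_cohort(cfg)
    return extract_table(ds.samples("horizontal"))
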