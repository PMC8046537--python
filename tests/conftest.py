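import numpy as np
import pytest

from hkls.synthetic import SyntheticSpec, generate_image


@pytest.fixture(scope="session")
def clean_ellipse():
    """Noise- and artifact-free dark ellipse on bright skin, with truth mask.

    Rendered near the method's native image scale so fixed-width
    morphological steps (5-px maximum filter, 5-px erosion) keep their
    intended, relatively small footprint on the lesion border.
    """
    spec = SyntheticSpec(seed=3, image_size=(512, 512), lesion_radii=(120.0, 90.0),
                         n_hairs=0, vignette_strength=0.0,
                         illumination_gradient=0.0, noise_sd=0.0,
                         boundary_irregularity=0.0, contrast_scale=1.0,
                         edge_softness_px=0.0)
    img, mask = generate_image(spec)
    return img, mask, spec


@pytest.fixture(scope="session")
def default_image():
    """One image with the default artifact load (hair, vignette, gradient, noise)."""
    spec = SyntheticSpec(seed=42)
    img, mask = generate_image(spec)
    return img, mask, spec


def random_mask_pair(seed: int, shape=(32, 32), p=0.3):
    """Seeded random blob-free mask pair for metric identity checks."""
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p, rng.random(shape) < p


def random_blob(seed: int, shape=(64, 64)):
    """Seeded random connected-ish blob (thresholded smooth noise)."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), 6)
    return field > np.quantile(field, 0.75)
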