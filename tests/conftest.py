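import numpy as np
import pytest

import phenomap as pm
from phenomap.experiments import build_leaf_study, fit_annotator


@pytest.fixture(scope="session")
def leaf_study():
    """The separable four-class leaf study: 6 templates x 20 images."""
    X, labels, data = build_leaf_study(n_per_class=20, seed=42)
    return X, labels, data


@pytest.fixture(scope="session")
def leaf_annotator(leaf_study):
    X, labels, _ = leaf_study
    return fit_annotator(X, labels, min_confidence=1.0)


@pytest.fixture()
def simple_leaf():
    spec = pm.LeafSpec(
        seed=11,
        lesion_count=6,
        lesion_size_class="medium",
        lesion_shape_class="elliptical",
        lesion_color_class="brown_necrotic",
    )
    return spec, *pm.generate_leaf(spec)


def two_touching_lesion_image():
    """A leaf image with two brown ellipses that overlap by construction."""
    from skimage.draw import ellipse as draw_ellipse
    from phenomap.synthetic import (
        BACKGROUND_COLOR,
        LESION_COLORS,
        TISSUE_COLORS,
        _leaf_mask,
    )

    leaf = _leaf_mask(520, 160)
    img = np.empty((160, 520, 3), dtype=np.uint8)
    img[:] = np.asarray(BACKGROUND_COLOR, np.uint8)
    img[leaf] = np.asarray(TISSUE_COLORS["green"], np.uint8)
    masks = []
    for cx in (245, 275):  # 30 px apart, semi-major 20 -> they touch
        m = np.zeros(leaf.shape, bool)
        rr, cc = draw_ellipse(80, cx, 12, 20, shape=leaf.shape)
        m[rr, cc] = True
        masks.append(m & leaf)
        img[masks[-1]] = np.asarray(LESION_COLORS["brown_necrotic"], np.uint8)
    return img, leaf, masks
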