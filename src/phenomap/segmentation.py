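"""Leaf isolation, tissue classification and per-lesion geometry.

The pre-processing stages of the leaf pipeline: separate the blade from the
solid protocol background, label every leaf pixel as necrotic (brown),
chlorotic (yellow) or normal tissue using HSV gates, and extract connected
lesion components with their geometry (area, centroid, maximum Feret diameter,
perimeter).

Conventions: 8-connected components (so diagonally touching necrosis merges,
as it does on real leaf scans); hue in degrees on [0, 360); coordinates are
0-based with x right / y down and centroids are unweighted pixel means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.color import rgb2hsv
from skimage.measure import perimeter as _sk_perimeter

__all__ = [
    "TissueGates",
    "Lesion",
    "LesionSet",
    "BACKGROUND_LABEL",
    "NORMAL",
    "CHLOROTIC",
    "NECROTIC",
    "segment_leaf",
    "classify_tissue",
    "extract_lesions",
    "max_feret_diameter",
    "export_tissue_png",
]

BACKGROUND_LABEL, NORMAL, CHLOROTIC, NECROTIC = 0, 1, 2, 3

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class TissueGates:
    """HSV range gates for the necrotic/chlorotic decision.

    Hue bounds are degrees on [0, 360); saturation/value on [0, 1].  The gates
    are a declared classifier validated on synthetic imagery: brown necrosis
    sits in the low orange hues at moderate value, yellow chlorosis in the
    yellow hues at high value, everything else on the blade is normal tissue.
    """

    necrotic_hue: tuple[float, float] = (5.0, 45.0)
    necrotic_value_max: float = 0.70
    chlorotic_hue: tuple[float, float] = (45.0, 75.0)
    chlorotic_value_min: float = 0.35
    min_saturation: float = 0.15


@dataclass
class Lesion:
    rows: np.ndarray
    cols: np.ndarray
    tissue_class: str  # "necrotic" | "chlorotic"
    area: int
    centroid: tuple[float, float]  # (x, y)
    max_diameter: float
    perimeter: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class LesionSet:
    lesions: list[Lesion] = field(default_factory=list)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def of_class(self, tissue_class: str) -> list[Lesion]:
        return [l for l in self.lesions if l.tissue_class == tissue_class]


def segment_leaf(
    image: np.ndarray, background_color, tol: float = 40.0
) -> np.ndarray:
    """Largest connected non-background component, holes filled.

    ``image`` is an (H, W, 3) uint8 array (or a ``LabeledImage``); background
    pixels are those within Euclidean RGB distance ``tol`` of
    ``background_color``.
    """
    pixels = getattr(image, "pixels", image)
    bg = np.asarray(background_color, dtype=float)
    dist = np.sqrt(((pixels.astype(float) - bg) ** 2).sum(axis=-1))
    fg = dist > tol
    if not fg.any():
        raise ValueError("empty foreground: image is entirely background")
    labeled, n = ndimage.label(fg, structure=_STRUCT8)
    if n > 1:
        counts = np.bincount(labeled.ravel())
        counts[0] = 0
        fg = labeled == int(counts.argmax())
    return ndimage.binary_fill_holes(fg)


def classify_tissue(
    image: np.ndarray, leaf_mask: np.ndarray, gates: TissueGates = TissueGates()
) -> np.ndarray:
    """Per-pixel tissue label raster (0 bg, 1 normal, 2 chlorotic, 3 necrotic)."""
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    pixels = getattr(image, "pixels", image)
    hsv = rgb2hsv(pixels.astype(float) / 255.0)
    hue = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]

    labels = np.zeros(leaf_mask.shape, dtype=np.uint8)
    labels[leaf_mask] = NORMAL
    sat_ok = sat >= gates.min_saturation
    nec = (
        leaf_mask
        & sat_ok
        & (hue >= gates.necrotic_hue[0])
        & (hue < gates.necrotic_hue[1])
        & (val <= gates.necrotic_value_max)
    )
    chl = (
        leaf_mask
        & sat_ok
        & (hue >= gates.chlorotic_hue[0])
        & (hue < gates.chlorotic_hue[1])
        & (val >= gates.chlorotic_value_min)
    )
    labels[chl] = CHLOROTIC
    labels[nec] = NECROTIC
    return labels


def max_feret_diameter(rows: np.ndarray, cols: np.ndarray) -> float:
    """Largest pairwise distance between pixel centers of a region.

    Computed on the convex hull vertices, which gives the exact Feret diameter
    at far lower cost than all pixel pairs.
    """
    pts = np.stack([rows, cols], axis=1).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # collinear regions
            pass
    return float(pdist(pts).max())


def extract_lesions(
    tissue_labels: np.ndarray, min_lesion_area: int = 5, image_id: str = ""
) -> LesionSet:
    """Connected lesion components per tissue class with geometry.

    Touching regions of the same class form a single lesion (8-connectivity);
    components below ``min_lesion_area`` px^2 are discarded as speckle.
    """
    out = LesionSet(image_id=image_id)
    for value, name in ((NECROTIC, "necrotic"), (CHLOROTIC, "chlorotic")):
        labeled, n = ndimage.label(tissue_labels == value, structure=_STRUCT8)
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(labeled == comp)
            area = rows.size
            if area < min_lesion_area:
                continue
            comp_mask = labeled == comp
            out.lesions.append(
                Lesion(
                    rows=rows,
                    cols=cols,
                    tissue_class=name,
                    area=int(area),
                    centroid=(float(cols.mean()), float(rows.mean())),
                    max_diameter=max(max_feret_diameter(rows, cols), 1.0),
                    perimeter=float(_sk_perimeter(comp_mask)),
                )
            )
    return out


_TISSUE_PALETTE = [0, 0, 0, 40, 160, 40, 170, 170, 170, 255, 255, 255]


def export_tissue_png(tissue_labels: np.ndarray, path) -> None:
    """Indexed PNG mirroring the usual visualization: black background, green
    normal tissue, gray chlorosis, white necrosis."""
    im = Image.fromarray(tissue_labels.astype(np.uint8), mode="P")
    im.putpalette(_TISSUE_PALETTE)
    im.save(path, format="PNG")
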