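"""Seeded generators for labeled leaf and fruit phenotype images.

Real phenotype collections of the kind this package analyses (field images of
maize lesion-mimic mutants, tomato fruit scans) are rarely redistributable, so
this module synthesises images with the statistical structure the downstream
semantics assume: a leaf blade on a solid protocol background carrying brown
necrotic or yellow chlorotic lesions of controlled count, area, ellipticity and
spatial pattern, and single-fruit silhouettes drawn from eight parametric
shape families and three size classes.  Every generated image ships with exact
ground truth (per-lesion masks, fruit outline, semantic labels with a degree of
appearance), which is what makes the generators usable as a segmentation and
rule-mining benchmark.

All outputs are a pure function of the spec, including its ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = [
    "LeafSpec",
    "FruitSpec",
    "LesionTruth",
    "GroundTruth",
    "LabeledImage",
    "PlacementError",
    "SIZE_CLASS_AREAS",
    "COVERAGE_THRESHOLDS",
    "FRUIT_SHAPE_CLASSES",
    "FRUIT_SIZE_RADII",
    "coverage_term",
    "generate_leaf",
    "generate_fruit",
    "generate_training_set",
    "write_image",
    "write_ground_truth",
    "labels_to_csv_rows",
]


class PlacementError(RuntimeError):
    """Raised when the requested lesions cannot be placed on the leaf."""


# ---------------------------------------------------------------------------
# configuration constants (documented defaults; all overridable per spec)
# ---------------------------------------------------------------------------

#: Disjoint, ordered lesion area ranges in px^2 for the three size classes.
SIZE_CLASS_AREAS: dict[str, tuple[float, float]] = {
    "small": (30.0, 80.0),
    "medium": (140.0, 280.0),
    "large": (330.0, 520.0),
}

#: Lesion-count thresholds mapping counts to coverage degree terms.
#: none = 0, few = 1..5, moderate = 6..20, extensive > 20.
COVERAGE_THRESHOLDS: dict[str, int] = {"few": 5, "moderate": 20}

#: Axis-ratio (minor/major) range for elliptical lesions.  Roundness of an
#: ellipse equals its axis ratio, so this range pins elliptical lesions into
#: the mid roundness bins.
ELLIPTICAL_AXIS_RATIO: tuple[float, float] = (0.45, 0.62)

#: Radial-noise amplitude and anisotropic stretch for irregular lesions;
#: chosen so irregular roundness stays well below the elliptical band.
IRREGULAR_NOISE_AMPLITUDE: tuple[float, float] = (0.40, 0.70)
IRREGULAR_STRETCH: tuple[float, float] = (2.2, 3.2)

BACKGROUND_COLOR: tuple[int, int, int] = (150, 150, 160)

TISSUE_COLORS: dict[str, tuple[int, int, int]] = {
    "green": (70, 135, 55),
    "yellow": (205, 190, 80),
    "brown": (115, 70, 35),
}

LESION_COLORS: dict[str, tuple[int, int, int]] = {
    "brown_necrotic": (110, 60, 25),
    "yellow_chlorotic": (215, 205, 70),
}

COLOR_NOISE = 6  # +/- uniform integer noise per channel

FRUIT_SHAPE_CLASSES = (
    "flat",
    "heart",
    "long",
    "obovoid",
    "oxheart",
    "rectangular",
    "round",
    "ellipsoid",
)

#: Height/width aspect of each fruit silhouette family.
_FRUIT_ASPECT = {
    "flat": 0.72,
    "heart": 1.05,
    "long": 1.55,
    "obovoid": 1.20,
    "oxheart": 1.25,
    "rectangular": 1.15,
    "round": 1.00,
    "ellipsoid": 1.25,
}

#: Nominal half-width in px of the three fruit size classes.
FRUIT_SIZE_RADII: dict[str, float] = {"small": 45.0, "medium": 70.0, "large": 100.0}

DEGREES = ("none", "few", "moderate", "extensive")


def coverage_term(lesion_count: int) -> str:
    """Map a lesion count to its coverage degree term."""
    if lesion_count == 0:
        return "none"
    if lesion_count <= COVERAGE_THRESHOLDS["few"]:
        return "few"
    if lesion_count <= COVERAGE_THRESHOLDS["moderate"]:
        return "moderate"
    return "extensive"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafSpec:
    """Generative parameters for one leaf image."""

    seed: int
    image_size: tuple[int, int] = (520, 160)  # (width, height)
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    leaf_tissue_class: str = "green"
    lesion_count: int = 0
    lesion_color_class: str = "brown_necrotic"
    lesion_size_class: str = "small"
    lesion_shape_class: str = "elliptical"
    spatial_pattern: str = "uniform"

    def __post_init__(self) -> None:
        if self.leaf_tissue_class not in TISSUE_COLORS:
            raise ValueError(f"unknown leaf tissue class {self.leaf_tissue_class!r}")
        if self.lesion_color_class not in LESION_COLORS:
            raise ValueError(f"unknown lesion color class {self.lesion_color_class!r}")
        if self.lesion_size_class not in SIZE_CLASS_AREAS:
            raise ValueError(f"unknown lesion size class {self.lesion_size_class!r}")
        if self.lesion_shape_class not in ("elliptical", "irregular"):
            raise ValueError(f"unknown lesion shape class {self.lesion_shape_class!r}")
        if self.spatial_pattern not in ("uniform", "clustered", "tip_biased", "base_biased"):
            raise ValueError(f"unknown spatial pattern {self.spatial_pattern!r}")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")

    @property
    def coverage_degree(self) -> str:
        return coverage_term(self.lesion_count)


@dataclass(frozen=True)
class FruitSpec:
    """Generative parameters for one single-fruit image."""

    seed: int
    shape_class: str = "round"
    size_class: str = "medium"
    fill_color: tuple[int, int, int] = (200, 50, 40)
    image_size: tuple[int, int] = (340, 340)
    background_color: tuple[int, int, int] = BACKGROUND_COLOR

    def __post_init__(self) -> None:
        if self.shape_class not in FRUIT_SHAPE_CLASSES:
            raise ValueError(f"unknown fruit shape class {self.shape_class!r}")
        if self.size_class not in FRUIT_SIZE_RADII:
            raise ValueError(f"unknown fruit size class {self.size_class!r}")


@dataclass
class LesionTruth:
    """Ground-truth geometry of a single generated lesion.

    Pixels are stored as (rows, cols) index arrays rather than dense rasters to
    keep large training sets cheap; :meth:`mask` densifies on demand.
    """

    rows: np.ndarray
    cols: np.ndarray
    tissue_class: str  # "necrotic" | "chlorotic"

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) = (col, row) unweighted pixel mean."""
        return float(self.cols.mean()), float(self.rows.mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class GroundTruth:
    lesions: list[LesionTruth]
    labels: list[tuple[str, str, str]]  # (semantic_class, term, degree)
    leaf_mask: np.ndarray | None = None
    fruit_outline: np.ndarray | None = None  # (n, 2) array of (row, col) vertices

    @property
    def lesion_masks(self) -> list[LesionTruth]:
        return self.lesions


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    image_id: str
    protocol: dict = field(default_factory=dict)
    labels: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# leaf generation
# ---------------------------------------------------------------------------


def _leaf_mask(width: int, height: int) -> np.ndarray:
    """Fixed elongated blade: an ellipse with a long horizontal axis.

    The long axis runs left (base) to right (tip), which gives the spatial
    partition features a well-defined base-to-tip direction.
    """
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = draw_ellipse(
        height / 2.0, width / 2.0, height * 0.42, width * 0.47, shape=mask.shape
    )
    mask[rr, cc] = True
    return mask


def _paint(rng: np.random.Generator, img: np.ndarray, mask: np.ndarray,
           color: tuple[int, int, int]) -> None:
    n = int(mask.sum())
    noise = rng.integers(-COLOR_NOISE, COLOR_NOISE + 1, size=(n, 3))
    img[mask] = np.clip(np.asarray(color)[None, :] + noise, 0, 255).astype(np.uint8)


def _sample_centers(rng: np.random.Generator, eligible: np.ndarray,
                    pattern: str, n: int, leaf_bbox: tuple[int, int]) -> np.ndarray:
    """Pick ``n`` centers (row, col) among eligible pixels under a pattern."""
    idx_r, idx_c = np.nonzero(eligible)
    if idx_r.size == 0:
        raise PlacementError("no eligible placement pixels left for a lesion")
    x0, x1 = leaf_bbox
    span = max(x1 - x0, 1)
    if pattern == "uniform":
        w = np.ones(idx_r.size)
    elif pattern == "tip_biased":
        w = ((idx_c - x0) / span) ** 3 + 1e-9
    elif pattern == "base_biased":
        w = (1.0 - (idx_c - x0) / span) ** 3 + 1e-9
    elif pattern == "clustered":
        k = rng.integers(1, 4)
        centers = rng.choice(idx_r.size, size=k, replace=False)
        sigma = span / 12.0
        d2 = np.full(idx_r.size, np.inf)
        for ci in centers:
            d2 = np.minimum(
                d2, (idx_r - idx_r[ci]) ** 2 + (idx_c - idx_c[ci]) ** 2
            )
        w = np.exp(-d2 / (2 * sigma**2)) + 1e-12
    else:  # pragma: no cover - guarded by LeafSpec validation
        raise ValueError(pattern)
    w = w / w.sum()
    picks = rng.choice(idx_r.size, size=n, replace=True, p=w)
    return np.stack([idx_r[picks], idx_c[picks]], axis=1)


def _elliptical_lesion(rng: np.random.Generator, area: float,
                       center: tuple[int, int], shape: tuple[int, int]):
    q = rng.uniform(*ELLIPTICAL_AXIS_RATIO)
    a = np.sqrt(area / (np.pi * q))  # semi-major
    b = q * a
    theta = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(center[0], center[1], b, a, rotation=theta, shape=shape)
    return rr, cc


def _irregular_lesion(rng: np.random.Generator, area: float,
                      center: tuple[int, int], shape: tuple[int, int]):
    """Radial-noise-perturbed polygon, anisotropically stretched.

    The stretch drives the Feret diameter up relative to the area, pinning the
    roundness of irregular lesions well below the elliptical band.
    """
    amp = rng.uniform(*IRREGULAR_NOISE_AMPLITUDE)
    stretch = rng.uniform(*IRREGULAR_STRETCH)
    theta = rng.uniform(0, np.pi)
    phis = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    f = np.zeros_like(phis)
    for k in range(3, 8):
        f += rng.normal() * np.cos(k * phis) + rng.normal() * np.sin(k * phis)
    f /= max(np.abs(f).max(), 1e-9)
    radius = 1.0 + amp * f
    # unit-ish blob, stretched along a random axis, scaled to the target area
    x = radius * np.cos(phis) * stretch
    y = radius * np.sin(phis)
    ct, st = np.cos(theta), np.sin(theta)
    xr = x * ct - y * st
    yr = x * st + y * ct
    poly_area = 0.5 * np.abs(np.dot(xr, np.roll(yr, -1)) - np.dot(yr, np.roll(xr, -1)))
    scale = np.sqrt(area / max(poly_area, 1e-9))
    rr, cc = draw_polygon(center[0] + yr * scale, center[1] + xr * scale, shape=shape)
    return rr, cc


def _leaf_labels(spec: LeafSpec) -> list[tuple[str, str, str]]:
    cov = spec.coverage_degree
    if spec.lesion_count == 0:
        return [("lesion_coverage", "none", "none")]
    color_term = (
        "brown_lesions" if spec.lesion_color_class == "brown_necrotic" else "yellow_lesions"
    )
    # The degree of appearance of color/size/shape semantics tracks how much
    # of the leaf expresses them, i.e. the coverage degree.
    return [
        ("lesion_coverage", cov, cov),
        ("lesion_color", color_term, cov),
        ("lesion_size", f"{spec.lesion_size_class}_lesions", cov),
        ("lesion_shape", f"{spec.lesion_shape_class}_lesions", cov),
    ]


def generate_leaf(spec: LeafSpec) -> tuple[LabeledImage, GroundTruth]:
    """Render one leaf image plus exact ground truth.

    Raises
    ------
    PlacementError
        If the requested lesions cannot fit on the blade (total lesion area
        above half the leaf area, or no interior pixel leaves enough margin).
    """
    rng = np.random.default_rng(spec.seed)
    width, height = spec.image_size
    leaf = _leaf_mask(width, height)
    leaf_area = int(leaf.sum())

    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)
    _paint(rng, img, leaf, TISSUE_COLORS[spec.leaf_tissue_class])

    lo, hi = SIZE_CLASS_AREAS[spec.lesion_size_class]
    areas = rng.uniform(lo, hi, size=spec.lesion_count)
    if areas.sum() > 0.5 * leaf_area:
        raise PlacementError(
            f"requested lesion area {areas.sum():.0f} px^2 exceeds packing limit "
            f"({0.5 * leaf_area:.0f} px^2)"
        )

    edt = ndimage.distance_transform_edt(leaf)
    cols = np.nonzero(leaf.any(axis=0))[0]
    bbox = (int(cols.min()), int(cols.max()))

    lesions: list[LesionTruth] = []
    tissue = "necrotic" if spec.lesion_color_class == "brown_necrotic" else "chlorotic"
    color = LESION_COLORS[spec.lesion_color_class]
    for area in areas:
        # keep the whole lesion on the blade: margin ~ its largest radius
        if spec.lesion_shape_class == "elliptical":
            margin = np.sqrt(area / (np.pi * ELLIPTICAL_AXIS_RATIO[0])) + 2
        else:
            margin = np.sqrt(area / np.pi) * (1 + IRREGULAR_NOISE_AMPLITUDE[1]) * np.sqrt(
                IRREGULAR_STRETCH[1]
            ) + 2
        center = _sample_centers(rng, edt > margin, spec.spatial_pattern, 1, bbox)[0]
        if spec.lesion_shape_class == "elliptical":
            rr, cc = _elliptical_lesion(rng, area, tuple(center), leaf.shape)
        else:
            rr, cc = _irregular_lesion(rng, area, tuple(center), leaf.shape)
        keep = leaf[rr, cc]
        rr, cc = rr[keep], cc[keep]
        if rr.size == 0:
            raise PlacementError("lesion rasterized to zero on-leaf pixels")
        lesions.append(LesionTruth(rows=rr, cols=cc, tissue_class=tissue))
        mask = np.zeros(leaf.shape, dtype=bool)
        mask[rr, cc] = True
        _paint(rng, img, mask, color)

    labels = _leaf_labels(spec)
    image = LabeledImage(
        pixels=img,
        image_id=f"leaf_{spec.seed}",
        protocol={"background_color": list(spec.background_color), "kind": "leaf"},
        labels=labels,
    )
    truth = GroundTruth(lesions=lesions, labels=labels, leaf_mask=leaf)
    return image, truth


# ---------------------------------------------------------------------------
# fruit generation
# ---------------------------------------------------------------------------


def _fruit_halfwidth(shape_class: str, v: np.ndarray) -> np.ndarray:
    """Half-width profile of the silhouette at relative height v in [-1, 1]
    (v = -1 bottom/blossom end, v = +1 top/stem end), in units of max width/2."""
    base = np.sqrt(np.clip(1.0 - v**2, 0.0, None))
    if shape_class in ("round", "flat", "long", "ellipsoid"):
        return base
    if shape_class == "rectangular":
        # superellipse |x|^4 + |v|^4 = 1
        return (np.clip(1.0 - np.abs(v) ** 4, 0.0, None)) ** 0.25
    if shape_class == "obovoid":
        return base * (1.0 + 0.28 * v) / 1.28
    if shape_class == "oxheart":
        # broad shoulders, tapered pointed bottom
        return base * (1.0 + 0.45 * v) / 1.45
    if shape_class == "heart":
        prof = base * (1.0 + 0.35 * v) / 1.35
        # shallow indent at the stem end
        prof = prof * (1.0 - 0.25 * np.clip(v - 0.82, 0, None) / 0.18)
        return prof
    raise ValueError(f"unknown fruit shape class {shape_class!r}")


def generate_fruit(spec: FruitSpec) -> tuple[LabeledImage, GroundTruth]:
    """Render a single fruit silhouette from a parametric outline family."""
    rng = np.random.default_rng(spec.seed)
    width, height = spec.image_size
    half_w = FRUIT_SIZE_RADII[spec.size_class] * rng.uniform(0.92, 1.08)
    half_h = half_w * _FRUIT_ASPECT[spec.shape_class]

    v = np.linspace(-1.0, 1.0, 121)
    hw = _fruit_halfwidth(spec.shape_class, v) * half_w
    cy, cx = height / 2.0, width / 2.0
    rows_right = cy - v * half_h
    right = np.stack([rows_right, cx + hw], axis=1)
    left = np.stack([rows_right[::-1], cx - hw[::-1]], axis=1)
    outline = np.concatenate([right, left], axis=0)

    mask = np.zeros((height, width), dtype=bool)
    rr, cc = draw_polygon(outline[:, 0], outline[:, 1], shape=mask.shape)
    mask[rr, cc] = True

    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)
    _paint(rng, img, mask, spec.fill_color)

    labels = [
        ("fruit_shape", f"{spec.shape_class}_shape", "moderate"),
        ("fruit_size", f"{spec.size_class}_size", "moderate"),
    ]
    image = LabeledImage(
        pixels=img,
        image_id=f"fruit_{spec.seed}",
        protocol={"background_color": list(spec.background_color), "kind": "fruit"},
        labels=labels,
    )
    truth = GroundTruth(lesions=[], labels=labels, fruit_outline=outline)
    return image, truth


# ---------------------------------------------------------------------------
# training sets and IO
# ---------------------------------------------------------------------------


def generate_training_set(
    n_per_class: int,
    classes: list[LeafSpec] | list[FruitSpec],
    seed: int,
) -> list[tuple[LabeledImage, GroundTruth]]:
    """Balanced labeled set: ``n_per_class`` images per template.

    Per-image seeds are drawn deterministically from the master seed, so the
    whole set is reproducible bit-for-bit.
    """
    if not classes:
        raise ValueError("empty class template list")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_per_class * len(classes))
    out: list[tuple[LabeledImage, GroundTruth]] = []
    i = 0
    for template in classes:
        gen = generate_leaf if isinstance(template, LeafSpec) else generate_fruit
        for _ in range(n_per_class):
            spec = replace(template, seed=int(seeds[i]))
            img, truth = gen(spec)
            img.image_id = f"{img.image_id}_{i:04d}"
            out.append((img, truth))
            i += 1
    return out


def _rle_encode(mask_flat: np.ndarray) -> list[list[int]]:
    idx = np.nonzero(mask_flat)[0]
    runs: list[list[int]] = []
    if idx.size == 0:
        return runs
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        runs.append([int(idx[s]), int(idx[e] - idx[s] + 1)])
    return runs


def write_image(image: LabeledImage, path) -> None:
    Image.fromarray(image.pixels).save(path, format="PNG")


def write_ground_truth(truth: GroundTruth, shape: tuple[int, int], path) -> None:
    """JSON sidecar: run-length encoded lesion masks plus labels."""
    payload = {
        "shape": list(shape),
        "lesions": [
            {
                "mask_rle": _rle_encode(les.mask(shape).ravel()),
                "class": les.tissue_class,
            }
            for les in truth.lesions
        ],
        "labels": [
            {"semantic_class": c, "term": t, "degree": d} for c, t, d in truth.labels
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def labels_to_csv_rows(image_id: str, truth: GroundTruth) -> list[tuple[str, str, str, str]]:
    return [(image_id, c, t, d) for c, t, d in truth.labels]
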