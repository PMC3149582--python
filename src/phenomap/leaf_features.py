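"""The 452-dimensional leaf feature vector and its constituent descriptors.

A leaf image is summarised by per-region color histograms (RGB and HSV, over
the entire blade, necrotic lesions, chlorotic lesions and non-lesion tissue)
plus per-tissue-class lesion statistics: area ("size") histograms, roundness
histograms, and nearest-neighbour centroid distance histograms.  The fixed
block layout is::

    F001-F048  RGB histogram   entire leaf        48 (16, 16, 16)
    F049-F096  RGB histogram   necrotic lesions   48
    F097-F144  RGB histogram   chlorotic lesions  48
    F145-F192  RGB histogram   non-lesions        48
    F193-F239  HSV histogram   entire leaf        47 (15, 16, 16)
    F240-F286  HSV histogram   necrotic lesions   47
    F287-F333  HSV histogram   non-lesions        47
    F334-F380  HSV histogram   chlorotic lesions  47
    F381-F392  size histogram       necrotic      12
    F393-F404  size histogram       chlorotic     12
    F405-F416  roundness histogram  necrotic      12
    F417-F428  roundness histogram  chlorotic     12
    F429-F440  NN distance histogram necrotic     12
    F441-F452  NN distance histogram chlorotic    12

Color histograms are per-channel normalised; the count histograms are
normalised by their block sum in post-processing (raw counts are retained on
the returned vector).  Roundness is region area over the area of the circle
whose diameter is the region's maximum Feret diameter, so a disk scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import (
    CHLOROTIC,
    NECROTIC,
    NORMAL,
    Lesion,
    LesionSet,
    TissueGates,
    classify_tissue,
    extract_lesions,
    segment_leaf,
)
from .synthetic import BACKGROUND_COLOR, LabeledImage

__all__ = [
    "BinSpec",
    "Block",
    "FeatureVector",
    "LEAF_LAYOUT",
    "N_LEAF_FEATURES",
    "leaf_feature_names",
    "describe_feature",
    "channel_histogram",
    "roundness",
    "size_histogram",
    "roundness_histogram",
    "nn_distance_histogram",
    "spatial_partition_histogram",
    "extract_leaf_features",
    "LeafFeatureExtractor",
]


@dataclass(frozen=True)
class BinSpec:
    """Equi-width binning over [lo, hi); the final bin is closed."""

    n_bins: int
    lo: float = 0.0
    hi: float = 1.0

    def index(self, values: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        idx = np.floor(self.n_bins * (np.asarray(values, float) - self.lo) / span)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)

    def counts(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_bins)
        if len(values):
            np.add.at(out, self.index(values), 1.0)
        return out


# channel bin conventions: 16 bins for R, G, B, S, V; 15 for H (degrees)
_CHANNEL_BINS = {
    "R": BinSpec(16, 0.0, 1.0),
    "G": BinSpec(16, 0.0, 1.0),
    "B": BinSpec(16, 0.0, 1.0),
    "H": BinSpec(15, 0.0, 360.0),
    "S": BinSpec(16, 0.0, 1.0),
    "V": BinSpec(16, 0.0, 1.0),
}

N_COUNT_BINS = 12  # size, roundness and NN-distance histograms


@dataclass(frozen=True)
class Block:
    start: int  # 1-based inclusive
    end: int
    feature_class: str
    region: str
    channels: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _build_leaf_layout() -> list[Block]:
    blocks: list[Block] = []
    pos = 1

    def add(feature_class: str, region: str, channels: tuple[str, ...], length: int):
        nonlocal pos
        blocks.append(Block(pos, pos + length - 1, feature_class, region, channels))
        pos += length

    for region in ("entire", "necrotic", "chlorotic", "non_lesion"):
        add("rgb_histogram", region, ("R", "G", "B"), 48)
    # note the printed block order: non-lesion HSV precedes chlorotic HSV
    for region in ("entire", "necrotic", "non_lesion", "chlorotic"):
        add("hsv_histogram", region, ("H", "S", "V"), 47)
    for fc in ("size_histogram", "roundness_histogram", "nn_distance_histogram"):
        for region in ("necrotic", "chlorotic"):
            add(fc, region, (), N_COUNT_BINS)
    return blocks


LEAF_LAYOUT: list[Block] = _build_leaf_layout()
N_LEAF_FEATURES: int = LEAF_LAYOUT[-1].end
assert N_LEAF_FEATURES == 452


def leaf_feature_names() -> list[str]:
    return [f"F{i:03d}" for i in range(1, N_LEAF_FEATURES + 1)]


def layout_manifest(layout: list[Block] | None = None) -> str:
    """JSON manifest of a block layout (index ranges are 1-based inclusive)."""
    import json

    blocks = layout if layout is not None else LEAF_LAYOUT
    return json.dumps(
        {
            "blocks": [
                {
                    "start": b.start,
                    "end": b.end,
                    "feature_class": b.feature_class,
                    "region": b.region,
                    "channels": list(b.channels),
                }
                for b in blocks
            ]
        },
        indent=1,
    )


def describe_feature(name: str) -> dict:
    """Resolve a zero-padded feature name like ``"F006"`` to its block,
    channel and within-channel bin (1-based)."""
    idx = int(name.lstrip("FfGg"))
    for block in LEAF_LAYOUT:
        if block.start <= idx <= block.end:
            offset = idx - block.start
            desc = {
                "feature": f"F{idx:03d}",
                "feature_class": block.feature_class,
                "region": block.region,
            }
            if block.channels:
                for ch in block.channels:
                    n = _CHANNEL_BINS[ch].n_bins
                    if offset < n:
                        desc["channel"] = ch
                        desc["bin"] = offset + 1
                        break
                    offset -= n
            else:
                desc["bin"] = offset + 1
            return desc
    raise KeyError(name)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    layout: list[Block]
    image_id: str = ""
    raw_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.image_id)


# ---------------------------------------------------------------------------
# individual descriptors
# ---------------------------------------------------------------------------


def channel_histogram(
    pixels: np.ndarray, channel: str, bins: BinSpec | None = None, normalize: bool = True
) -> np.ndarray:
    """Equi-width histogram of one color channel over a pixel set.

    ``pixels`` is an (n, 3) RGB array with values in [0, 1].  Hue is binned in
    degrees on [0, 360); the other channels on [0, 1].
    """
    if channel not in _CHANNEL_BINS:
        raise ValueError(f"unknown channel {channel!r}")
    bins = bins or _CHANNEL_BINS[channel]
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if pixels.shape[0] == 0:
        if normalize:
            raise ValueError("cannot normalize a histogram of an empty pixel set")
        return np.zeros(bins.n_bins)
    if channel in "RGB":
        vals = pixels[:, "RGB".index(channel)]
    else:
        hsv = rgb2hsv(pixels.reshape(-1, 1, 3)).reshape(-1, 3)
        vals = hsv[:, "HSV".index(channel)]
        if channel == "H":
            vals = vals * 360.0
    counts = bins.counts(vals)
    if normalize:
        counts = counts / counts.sum()
    return counts


def roundness(lesion: Lesion) -> float:
    """Area over the area of the circle on the maximum Feret diameter.

    Clipped to 1 to absorb rasterisation overshoot; a single-pixel lesion
    (degenerate diameter) returns 1 by convention.
    """
    d = lesion.max_diameter
    if d <= 1.0:
        return 1.0
    return float(min(lesion.area / (np.pi * (d / 2.0) ** 2), 1.0))


def _class_lesions(lesions: LesionSet | list, tissue_class: str) -> list[Lesion]:
    if isinstance(lesions, LesionSet):
        return lesions.of_class(tissue_class)
    return [l for l in lesions if l.tissue_class == tissue_class]


def size_histogram(lesions, tissue_class: str, bins: BinSpec) -> np.ndarray:
    """Unnormalised count of lesions per area bin (areas in px^2)."""
    areas = np.array([l.area for l in _class_lesions(lesions, tissue_class)])
    return bins.counts(areas)


def roundness_histogram(lesions, tissue_class: str, bins: BinSpec) -> np.ndarray:
    vals = np.array([roundness(l) for l in _class_lesions(lesions, tissue_class)])
    return bins.counts(vals)


def nn_distance_histogram(lesions, tissue_class: str, bins: BinSpec) -> np.ndarray:
    """One nearest-neighbour centroid distance per lesion (n >= 2).

    The total count equals the lesion count, so leaves with more lesions carry
    more histogram mass.  With fewer than two lesions there is no neighbour
    and the histogram is all zeros.
    """
    pts = np.array([l.centroid for l in _class_lesions(lesions, tissue_class)])
    if len(pts) < 2:
        return np.zeros(bins.n_bins)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return bins.counts(d.min(axis=1))


def spatial_partition_histogram(lesions, leaf_mask: np.ndarray, k: int) -> np.ndarray:
    """Lesion counts in ``k`` equal-width slices along the leaf's long axis.

    Partitions run base to tip (ascending coordinate); a centroid exactly on a
    partition boundary goes to the lower-index partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rows_any = np.nonzero(leaf_mask.any(axis=1))[0]
    cols_any = np.nonzero(leaf_mask.any(axis=0))[0]
    horizontal = cols_any.size >= rows_any.size
    lo, hi = (cols_any[0], cols_any[-1]) if horizontal else (rows_any[0], rows_any[-1])
    span = max(hi - lo, 1)
    counts = np.zeros(k)
    items = lesions.lesions if isinstance(lesions, LesionSet) else list(lesions)
    for lesion in items:
        x, y = lesion.centroid
        coord = x if horizontal else y
        t = k * (coord - lo) / span
        idx = int(np.floor(t))
        if idx > 0 and t == idx:  # boundary tie -> lower partition
            idx -= 1
        counts[min(max(idx, 0), k - 1)] += 1
    return counts


# ---------------------------------------------------------------------------
# full 452-feature extraction
# ---------------------------------------------------------------------------


def _region_pixels(pixels01: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return pixels01[mask]


def _color_block(pixels: np.ndarray, channels: tuple[str, ...]) -> np.ndarray:
    parts = []
    for ch in channels:
        parts.append(channel_histogram(pixels, ch, normalize=pixels.shape[0] > 0))
    return np.concatenate(parts)


def extract_leaf_features(
    image: LabeledImage | np.ndarray,
    background_color=BACKGROUND_COLOR,
    tol: float = 40.0,
    gates: TissueGates = TissueGates(),
    min_lesion_area: int = 5,
    size_range_divisor: float = 10.0,
) -> FeatureVector:
    """Run the full leaf pipeline and produce the 452-feature vector.

    Size-histogram bins span ``[0, leaf_area / size_range_divisor]``;
    NN-distance bins span ``[0, leaf long-axis length]``; roundness bins span
    ``[0, 1]``.  Values beyond a range are clamped into the final bin.  Count
    histograms are normalised by their block sum (blocks with no lesions stay
    zero); raw counts are kept on ``FeatureVector.raw_counts``.
    """
    pixels = getattr(image, "pixels", image)
    image_id = getattr(image, "image_id", "")
    leaf = segment_leaf(pixels, background_color, tol)
    tissue = classify_tissue(pixels, leaf, gates)
    lesions = extract_lesions(tissue, min_lesion_area, image_id=image_id)

    pixels01 = pixels.astype(float) / 255.0
    masks = {
        "entire": leaf,
        "necrotic": tissue == NECROTIC,
        "chlorotic": tissue == CHLOROTIC,
        "non_lesion": tissue == NORMAL,
    }

    leaf_area = float(leaf.sum())
    cols_any = np.nonzero(leaf.any(axis=0))[0]
    rows_any = np.nonzero(leaf.any(axis=1))[0]
    long_axis = float(
        max(cols_any[-1] - cols_any[0] + 1, rows_any[-1] - rows_any[0] + 1)
    )
    count_bins = {
        "size_histogram": BinSpec(N_COUNT_BINS, 0.0, leaf_area / size_range_divisor),
        "roundness_histogram": BinSpec(N_COUNT_BINS, 0.0, 1.0),
        "nn_distance_histogram": BinSpec(N_COUNT_BINS, 0.0, long_axis),
    }
    count_fn = {
        "size_histogram": size_histogram,
        "roundness_histogram": roundness_histogram,
        "nn_distance_histogram": nn_distance_histogram,
    }

    values = np.zeros(N_LEAF_FEATURES)
    raw_counts: dict[str, np.ndarray] = {}
    for block in LEAF_LAYOUT:
        sl = slice(block.start - 1, block.end)
        if block.channels:  # color histogram block
            px = _region_pixels(pixels01, masks[block.region])
            values[sl] = _color_block(px, block.channels)
        else:
            counts = count_fn[block.feature_class](
                lesions, block.region, count_bins[block.feature_class]
            )
            raw_counts[f"{block.feature_class}/{block.region}"] = counts
            total = counts.sum()
            values[sl] = counts / total if total > 0 else counts

    return FeatureVector(
        values=values,
        names=leaf_feature_names(),
        layout=LEAF_LAYOUT,
        image_id=image_id,
        raw_counts=raw_counts,
    )


class LeafFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping leaf images to 452-feature rows.

    ``transform`` accepts a sequence of images (``LabeledImage`` or uint8
    arrays) and returns a DataFrame indexed by image id with columns
    ``F001..F452``.
    """

    def __init__(
        self,
        background_color=BACKGROUND_COLOR,
        tol: float = 40.0,
        gates: TissueGates = TissueGates(),
        min_lesion_area: int = 5,
        size_range_divisor: float = 10.0,
    ):
        self.background_color = background_color
        self.tol = tol
        self.gates = gates
        self.min_lesion_area = min_lesion_area
        self.size_range_divisor = size_range_divisor

    def fit(self, X=None, y=None):
        self.n_features_out_ = N_LEAF_FEATURES
        return self

    def transform(self, X) -> pd.DataFrame:
        rows, ids = [], []
        for i, image in enumerate(X):
            fv = extract_leaf_features(
                image,
                background_color=self.background_color,
                tol=self.tol,
                gates=self.gates,
                min_lesion_area=self.min_lesion_area,
                size_range_divisor=self.size_range_divisor,
            )
            rows.append(fv.values)
            ids.append(fv.image_id or f"image_{i:04d}")
        return pd.DataFrame(rows, index=ids, columns=leaf_feature_names())
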