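"""Descriptor oracles and the 452-feature layout contract."""

import numpy as np
import pytest

import phenomap as pm
from phenomap.leaf_features import (
    LEAF_LAYOUT,
    N_LEAF_FEATURES,
    BinSpec,
    channel_histogram,
    describe_feature,
    leaf_feature_names,
    nn_distance_histogram,
    roundness_histogram,
    size_histogram,
    spatial_partition_histogram,
)
from phenomap.segmentation import Lesion, NECROTIC


def _lesion(centroid=(0.0, 0.0), area=10, d=5.0, cls="necrotic"):
    return Lesion(
        rows=np.zeros(1, int), cols=np.zeros(1, int), tissue_class=cls,
        area=area, centroid=centroid, max_diameter=d, perimeter=1.0,
    )


class TestLayout:
    def test_blocks_tile_exactly_452_features(self):
        assert N_LEAF_FEATURES == 452 == 48 * 4 + 47 * 4 + 12 * 6
        pos = 1
        for block in LEAF_LAYOUT:
            assert block.start == pos
            pos = block.end + 1
        assert pos == 453

    @pytest.mark.parametrize(
        "start,feature_class,region",
        [
            (1, "rgb_histogram", "entire"),
            (49, "rgb_histogram", "necrotic"),
            (97, "rgb_histogram", "chlorotic"),
            (145, "rgb_histogram", "non_lesion"),
            (193, "hsv_histogram", "entire"),
            (240, "hsv_histogram", "necrotic"),
            (287, "hsv_histogram", "non_lesion"),
            (334, "hsv_histogram", "chlorotic"),
            (381, "size_histogram", "necrotic"),
            (393, "size_histogram", "chlorotic"),
            (405, "roundness_histogram", "necrotic"),
            (417, "roundness_histogram", "chlorotic"),
            (429, "nn_distance_histogram", "necrotic"),
            (441, "nn_distance_histogram", "chlorotic"),
        ],
    )
    def test_printed_block_boundaries(self, start, feature_class, region):
        block = next(b for b in LEAF_LAYOUT if b.start == start)
        assert (block.feature_class, block.region) == (feature_class, region)

    def test_feature_names_resolve(self):
        names = leaf_feature_names()
        assert names[0] == "F001" and names[-1] == "F452"
        d6 = describe_feature("F006")
        assert d6 == {
            "feature": "F006", "feature_class": "rgb_histogram",
            "region": "entire", "channel": "R", "bin": 6,
        }
        d399 = describe_feature("F399")
        assert d399["feature_class"] == "size_histogram"
        assert d399["region"] == "chlorotic"
        assert d399["bin"] == 7


class TestChannelHistogram:
    def test_uniform_patch_fills_one_bin(self):
        px = np.tile([[0.2, 0.4, 0.6]], (50, 1))
        h = channel_histogram(px, "B")
        assert h[int(16 * 0.6)] == 1.0 and h.sum() == pytest.approx(1.0)

    def test_two_hue_halves_split_between_bins(self):
        # hue 30 deg = pure orange-ish; hue 200 deg = azure-ish
        from skimage.color import hsv2rgb

        hsv = np.zeros((10, 1, 3))
        hsv[:5, 0] = (30 / 360, 1.0, 1.0)
        hsv[5:, 0] = (200 / 360, 1.0, 1.0)
        px = hsv2rgb(hsv).reshape(-1, 3)
        h = channel_histogram(px, "H", bins=BinSpec(10, 0, 360))
        assert h[0] == pytest.approx(0.5)
        assert h[5] == pytest.approx(0.5)

    def test_empty_pixel_set_rules(self):
        empty = np.zeros((0, 3))
        with pytest.raises(ValueError, match="empty"):
            channel_histogram(empty, "R", normalize=True)
        assert channel_histogram(empty, "R", normalize=False).sum() == 0

    def test_normalized_histogram_sums_to_one(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 1, (200, 3))
        for ch in "RGBHSV":
            assert channel_histogram(px, ch).sum() == pytest.approx(1.0, abs=1e-9)


class TestRoundness:
    def test_disk_ellipse_square_oracles(self):
        from skimage.draw import disk, ellipse

        def lesion_from(mask):
            t = np.where(mask, NECROTIC, 0).astype(np.uint8)
            return pm.extract_lesions(t).lesions[0]

        m = np.zeros((120, 120), bool)
        rr, cc = disk((60, 60), 40)
        m[rr, cc] = True
        assert pm.roundness(lesion_from(m)) == pytest.approx(1.0, abs=0.03)

        m = np.zeros((120, 120), bool)
        rr, cc = ellipse(60, 60, 20, 40)
        m[rr, cc] = True
        assert pm.roundness(lesion_from(m)) == pytest.approx(0.5, abs=0.03)

        m = np.zeros((120, 120), bool)
        m[30:90, 30:90] = True
        assert pm.roundness(lesion_from(m)) == pytest.approx(2 / np.pi, abs=0.03)

    def test_single_pixel_lesion_is_round_by_convention(self):
        assert pm.roundness(_lesion(area=1, d=1.0)) == 1.0


class TestCountHistograms:
    def test_size_histogram_counts_lesions_per_area_bin(self):
        bins = BinSpec(12, 0, 120)
        lesions = [_lesion(area=35) for _ in range(7)]  # bin 3 = [30, 40)
        h = size_histogram(lesions, "necrotic", bins)
        assert h[3] == 7 and h.sum() == 7
        assert size_histogram([], "necrotic", bins).sum() == 0

    def test_roundness_histogram_orders_disk_vs_irregular_leaves(self):
        bins = BinSpec(12, 0, 1)
        disks = [_lesion(area=315, d=20.0) for _ in range(6)]  # roundness ~1
        h_disk = roundness_histogram(disks, "necrotic", bins)
        assert h_disk[-2:].sum() == 6  # only the top bins

        spec = pm.LeafSpec(
            seed=8, lesion_count=8, lesion_shape_class="irregular",
            lesion_size_class="medium",
        )
        img, _ = pm.generate_leaf(spec)
        tissue = pm.classify_tissue(
            img.pixels, pm.segment_leaf(img.pixels, spec.background_color)
        )
        h_irr = roundness_histogram(pm.extract_lesions(tissue), "necrotic", bins)
        h_irr = h_irr / h_irr.sum()
        assert h_irr[:4].sum() > (h_disk / h_disk.sum())[:4].sum()

    def test_nn_distance_histogram_oracles(self):
        bins = BinSpec(12, 0, 120)  # width 10
        two = [_lesion(centroid=(0, 0)), _lesion(centroid=(35, 0))]
        h = nn_distance_histogram(two, "necrotic", bins)
        assert h[3] == 2 and h.sum() == 2

        three = [_lesion(centroid=(x, 0)) for x in (0, 45, 90)]
        h3 = nn_distance_histogram(three, "necrotic", bins)
        assert h3[4] == 3

        assert nn_distance_histogram([_lesion()], "necrotic", bins).sum() == 0

    def test_dense_leaf_has_mass_at_shorter_distances_than_sparse(self):
        bins = BinSpec(12, 0, 240)
        dense = [_lesion(centroid=(5 * i, 3 * (i % 3))) for i in range(9)]
        sparse = [_lesion(centroid=(80 * i, 0)) for i in range(9)]
        hd = nn_distance_histogram(dense, "necrotic", bins)
        hs = nn_distance_histogram(sparse, "necrotic", bins)
        idx = np.arange(12)
        assert (hd * idx).sum() / hd.sum() < (hs * idx).sum() / hs.sum()


class TestSpatialPartition:
    def _leaf(self):
        mask = np.zeros((40, 300), bool)
        mask[10:30, 10:290] = True
        return mask

    def test_basal_lesions_land_in_first_partition(self):
        mask = self._leaf()
        lesions = [_lesion(centroid=(30 + i, 20)) for i in range(5)]
        assert spatial_partition_histogram(lesions, mask, 3).tolist() == [5, 0, 0]

    def test_uniform_pattern_is_binomially_balanced(self):
        mask = self._leaf()
        rng = np.random.default_rng(4)
        xs = rng.uniform(10, 290, 400)
        lesions = [_lesion(centroid=(x, 20)) for x in xs]
        counts = spatial_partition_histogram(lesions, mask, 4)
        assert counts.sum() == 400
        sigma = np.sqrt(400 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 100) <= 3 * sigma)

    def test_boundary_centroid_goes_to_lower_partition(self):
        mask = self._leaf()  # long axis spans columns 10..289
        boundary_x = 10 + (289 - 10) / 2  # exact k=2 boundary
        lesions = [_lesion(centroid=(boundary_x, 20))]
        assert spatial_partition_histogram(lesions, mask, 2).tolist() == [1, 0]

    def test_k_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            spatial_partition_histogram([], self._leaf(), 1)


class TestFullVector:
    def test_vector_has_exactly_452_values(self, simple_leaf):
        _, img, _ = simple_leaf
        fv = pm.extract_leaf_features(img)
        assert len(fv) == 452
        assert fv.names == leaf_feature_names()

    def test_lesion_free_leaf_zeroes_lesion_blocks(self):
        img, _ = pm.generate_leaf(pm.LeafSpec(seed=6, lesion_count=0))
        fv = pm.extract_leaf_features(img)
        for block in LEAF_LAYOUT:
            sl = fv.values[block.start - 1 : block.end]
            if block.region in ("necrotic", "chlorotic"):
                assert np.all(sl == 0)
            elif block.feature_class == "rgb_histogram":
                assert sl.sum() == pytest.approx(3.0)  # one per channel

    def test_count_blocks_are_block_normalized_with_raw_counts_kept(self, simple_leaf):
        _, img, _ = simple_leaf
        fv = pm.extract_leaf_features(img)
        for block in LEAF_LAYOUT:
            if block.channels:
                continue
            sl = fv.values[block.start - 1 : block.end]
            raw = fv.raw_counts[f"{block.feature_class}/{block.region}"]
            if raw.sum() > 0:
                assert sl.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(sl, raw / raw.sum())
            else:
                assert np.all(sl == 0)

    def test_hue_centroid_orders_brown_yellow_green(self):
        centroids = {}
        for tissue_class in ("brown", "yellow", "green"):
            img, _ = pm.generate_leaf(
                pm.LeafSpec(seed=2, lesion_count=0, leaf_tissue_class=tissue_class)
            )
            mask = pm.segment_leaf(img.pixels, (150, 150, 160))
            h = channel_histogram(
                img.pixels[mask].astype(float) / 255.0, "H",
                bins=BinSpec(10, 0, 360),
            )
            centroids[tissue_class] = (h * np.arange(10)).sum()
        assert centroids["brown"] < centroids["yellow"] < centroids["green"]

    def test_transformer_returns_feature_frame(self, simple_leaf):
        _, img, _ = simple_leaf
        df = pm.LeafFeatureExtractor().fit().transform([img])
        assert df.shape == (1, 452)
        assert list(df.columns) == leaf_feature_names()
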