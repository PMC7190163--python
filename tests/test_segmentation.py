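import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import h_minima, local_minima
from skimage.segmentation import watershed

from fishcount.filtering import ParameterError
from fishcount.segmentation import (
    LabelMap, SegmentationError, SegmentationParams, correct_segmentation,
    filter_small_regions, load_labelmap, merge_shallow_basins,
    partitions_equal, render_segmentation, save_labelmap, segment_nuclei,
)
from fishcount.synth_fixtures import CellType, FixtureParams, generate_experiment
from fishcount.image_model import max_project, normalize

FOOTPRINT_4CONN = ndimage.generate_binary_structure(2, 1)


def _random_surface(rng, shape=(32, 32), sigma=1.2):
    s = ndimage.gaussian_filter(rng.random(shape), sigma)
    return (s - s.min()) / (s.max() - s.min())


def _base_watershed(surface):
    markers = cc_label(local_minima(surface, connectivity=1), connectivity=1)
    return watershed(surface, markers=markers, connectivity=1)


def _pair_fixture(saddle_depth=1e-5, pairs=2, seed=3):
    """Touching nucleus pairs whose rendered ridge saddle is exactly
    ``saddle_depth`` below the peaks after normalization."""
    p = FixtureParams(
        image_shape=(8, 256, 256), n_nuclei=2 * pairs, touching_pairs=pairs,
        nucleus_radius=(10.0, 13.0), saddle_depth=saddle_depth,
        cell_types=(CellType("GFP", 1.0, {"HES1": 0.0}),),
        noise_sigma=0.0, background=0.0, seed=seed,
    )
    exp, truth = generate_experiment(p)
    proj = max_project(normalize(exp.channels["DAPI"]))
    return proj, truth


class TestMergeShallowBasins:
    def test_zero_depth_is_identity(self):
        rng = np.random.default_rng(0)
        surf = _random_surface(rng)
        base = _base_watershed(surf)
        out = merge_shallow_basins(base, surf, 0.0)
        assert partitions_equal(out.labels, base)

    def test_infinite_depth_merges_each_component(self):
        rng = np.random.default_rng(1)
        surf = _random_surface(rng)
        base = _base_watershed(surf)
        out = merge_shallow_basins(base, surf, np.inf)
        assert out.n_regions == 1  # fully connected domain -> one region

    def test_equals_h_minima_watershed_oracle(self):
        """Depth-threshold basin merging must reproduce the classical
        h-minima-suppressed watershed partition exactly."""
        rng = np.random.default_rng(2)
        for _ in range(12):
            surf = _random_surface(rng)
            base = _base_watershed(surf)
            for h in (1e-6, 1e-5, 1e-4):
                mine = merge_shallow_basins(base, surf, h)
                markers = cc_label(
                    h_minima(surf, h, footprint=FOOTPRINT_4CONN), connectivity=1
                )
                oracle = watershed(surf, markers=markers, connectivity=1)
                assert partitions_equal(mine.labels, oracle)

    def test_result_independent_of_label_numbering(self):
        rng = np.random.default_rng(3)
        surf = _random_surface(rng)
        base = _base_watershed(surf)
        perm = np.concatenate([[0], rng.permutation(base.max()) + 1])
        out_a = merge_shallow_basins(base, surf, 0.01)
        out_b = merge_shallow_basins(perm[base], surf, 0.01)
        assert partitions_equal(out_a.labels, out_b.labels)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SegmentationError):
            merge_shallow_basins(np.ones((4, 4), int), np.zeros((5, 5)), 0.1)


class TestSegmentNuclei:
    def test_two_separated_nuclei(self):
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        img = np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 72) + np.exp(
            -((yy - 70) ** 2 + (xx - 70) ** 2) / 72
        )
        seg = segment_nuclei(img, SegmentationParams(min_size=10))
        assert seg.n_regions == 2

    def test_min_depth_sweep_crosses_constructed_saddle(self):
        proj, truth = _pair_fixture(saddle_depth=1e-5, pairs=2)
        params = lambda d: SegmentationParams(  # noqa: E731
            min_depth=d, min_size=50, smoothing_sigma=0.0
        )
        split = segment_nuclei(proj, params(0.9e-5))
        merged = segment_nuclei(proj, params(1.1e-5))
        assert split.n_regions == 4      # both pairs separated
        assert merged.n_regions == 2     # both pairs collapsed
        assert truth.label_map.n_regions == 4

    def test_recommended_ranges_bracket_transition(self):
        # splitting range (5e-6) keeps pairs apart; the merged result
        # appears above the saddle (5e-5) for a 1e-5 saddle
        proj, _ = _pair_fixture(saddle_depth=1e-5, pairs=1)
        lo = segment_nuclei(
            proj, SegmentationParams(min_depth=5e-6, min_size=50,
                                     smoothing_sigma=0.0)
        )
        hi = segment_nuclei(
            proj, SegmentationParams(min_depth=5e-5, min_size=50,
                                     smoothing_sigma=0.0)
        )
        assert lo.n_regions == 2 and hi.n_regions == 1

    def test_region_count_monotone_in_min_depth(self):
        proj, _ = _pair_fixture(saddle_depth=1e-5, pairs=2)
        counts = [
            segment_nuclei(
                proj, SegmentationParams(min_depth=d, min_size=50,
                                         smoothing_sigma=0.0)
            ).n_regions
            for d in (0.0, 1e-7, 1e-6, 1e-5, 1e-4, 1e-2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_foreground_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            seg = segment_nuclei(
                np.full((16, 16), 0.2),
                SegmentationParams(threshold_method="fixed", fixed_threshold=0.9),
            )
        assert seg.n_regions == 0

    def test_bad_fixed_threshold_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(threshold_method="fixed", fixed_threshold=1.5)

    def test_foreground_partition_property(self, standard_fixture):
        exp, _, _ = standard_fixture
        proj = max_project(normalize(exp.channels["DAPI"]))
        seg = segment_nuclei(proj, SegmentationParams())
        # every pixel has exactly one label; labels compact
        assert seg.labels.min() >= 0
        np.testing.assert_array_equal(np.unique(seg.labels)[1:],
                                      np.arange(1, seg.n_regions + 1))


class TestFilterSmallRegions:
    def _three_region_map(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        lab[0, :5] = 1                      # area 5
        lab[5:10, 0:10] = 2                 # area 50
        lab[15:35, 10:35] = 3               # area 500
        return LabelMap(lab)

    def test_min_size_zero_is_identity(self):
        lm = self._three_region_map()
        out = filter_small_regions(lm, 0)
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_areas_5_50_500_min_size_10_keeps_two(self):
        out = filter_small_regions(self._three_region_map(), 10)
        assert out.n_regions == 2
        # brute-force area scan agrees
        areas = sorted(out.regions()["area"])
        assert areas == [50, 500]

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning):
            out = filter_small_regions(self._three_region_map(), 10_000)
        assert out.n_regions == 0

    def test_monotone_in_min_size(self):
        lm = self._three_region_map()
        counts = [filter_small_regions(lm, s).n_regions for s in (0, 6, 60, 600)]
        assert counts == [3, 2, 1, 0]

    def test_negative_min_size_rejected(self):
        with pytest.raises(ParameterError):
            filter_small_regions(self._three_region_map(), -1)


class TestCorrection:
    def _five_region_map(self):
        lab = np.zeros((30, 30), dtype=np.int32)
        for i in range(5):
            lab[6 * i : 6 * i + 5, 2:28] = i + 1
        return LabelMap(lab)

    def test_merge_reduces_count_and_unifies_pixels(self):
        lm = self._five_region_map()
        out = correct_segmentation(lm, merges=[[3, 4]])
        assert out.n_regions == 4
        merged_mask = (lm.labels == 3) | (lm.labels == 4)
        assert len(np.unique(out.labels[merged_mask])) == 1

    def test_delete_blanks_exactly_listed_regions(self):
        lm = self._five_region_map()
        out = correct_segmentation(lm, deletions=[2])
        assert out.n_regions == 4
        assert (out.labels[lm.labels == 2] == 0).all()
        # other regions' pixel sets untouched
        assert partitions_equal(
            np.where(lm.labels == 2, 0, lm.labels), out.labels
        )

    def test_merge_then_delete_commutes_with_direct_delete(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            surf = ndimage.gaussian_filter(rng.random((24, 24)), 1.0)
            lab = _base_watershed(surf)
            lm = LabelMap(lab)
            if lm.n_regions < 3:
                continue
            merged = correct_segmentation(lm, merges=[[1, 2]])
            a = correct_segmentation(merged, deletions=[1])
            b = correct_segmentation(lm, deletions=[1, 2])
            np.testing.assert_array_equal(a.labels > 0, b.labels > 0)
            assert partitions_equal(a.labels, b.labels)

    def test_unknown_id_lists_valid_ids(self):
        lm = self._five_region_map()
        with pytest.raises(SegmentationError, match=r"\[1, 2, 3, 4, 5\]"):
            correct_segmentation(lm, deletions=[9])

    def test_conflicting_edit_rejected(self):
        lm = self._five_region_map()
        with pytest.raises(SegmentationError, match="merge set and deletions"):
            correct_segmentation(lm, merges=[[1, 2]], deletions=[2])


class TestRenderAndIO:
    def test_labelmap_tiff_round_trip(self, tmp_path):
        lm = TestCorrection()._five_region_map()
        save_labelmap(lm, tmp_path / "l.tif", tmp_path / "l.csv")
        back = load_labelmap(tmp_path / "l.tif")
        np.testing.assert_array_equal(back.labels, lm.labels)

    def test_render_deterministic_and_empty_safe(self, tmp_path):
        lm = TestCorrection()._five_region_map()
        under = np.random.default_rng(0).random(lm.labels.shape)
        a = render_segmentation(lm, under, tmp_path / "a.png")
        b = render_segmentation(lm, under, tmp_path / "b.png")
        assert a.read_bytes() == b.read_bytes()
        empty = LabelMap(np.zeros_like(lm.labels))
        out = render_segmentation(empty, under, tmp_path / "e.png")
        assert out.exists()
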