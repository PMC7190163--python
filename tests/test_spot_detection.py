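import numpy as np
import pandas as pd
import pytest
from skimage.feature import peak_local_max

from fishcount.filtering import FilterParams, ParameterError, bandpass
from fishcount.spot_detection import (
    DetectionParams, categorize_spots, detect_spots, empty_spot_table,
    render_detection_overlay,
)
from fishcount.synth_fixtures import generate_spot_field, match_spots, score_spots
from tests.conftest import standard_detection_params


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(spot_radius=0), dict(min_mass=-1.0), dict(separation=0.5)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            DetectionParams(**kwargs)

    def test_spot_radius_exceeding_volume_rejected(self):
        with pytest.raises(ParameterError):
            detect_spots(np.random.default_rng(0).random((4, 4, 4)),
                         DetectionParams(spot_radius=5))

    def test_default_report_bounds_bracket_min_mass(self):
        p = DetectionParams(min_mass=10.0)
        assert p.interval_bounds == (8.0, 12.0)


class TestDetect:
    def test_twenty_spots_recovered_with_subvoxel_accuracy(self):
        vol, truth = generate_spot_field(
            n_spots=20, shape=(14, 96, 96), peak=0.5, noise_sigma=0.01, seed=2
        )
        filtered = bandpass(vol, FilterParams())
        spots = detect_spots(filtered, standard_detection_params())
        assert len(spots) == 20
        _, _, dist = match_spots(spots, truth, gate=2.0)
        assert len(dist) == 20
        assert dist.mean() < 0.5

    def test_zeros_volume_yields_empty_table_not_error(self):
        spots = detect_spots(np.zeros((8, 32, 32)), DetectionParams())
        assert len(spots) == 0
        assert list(spots.columns) == list(empty_spot_table().columns)

    def test_infinite_min_mass_yields_no_spots(self):
        vol, _ = generate_spot_field(n_spots=10, shape=(12, 64, 64), seed=3)
        filtered = bandpass(vol, FilterParams())
        p = standard_detection_params()
        spots = detect_spots(
            filtered, DetectionParams(p.spot_radius, np.inf, p.separation,
                                      p.percentile_floor)
        )
        assert len(spots) == 0

    def test_mass_gate_monotonicity_and_superset(self):
        vol, _ = generate_spot_field(n_spots=30, shape=(14, 96, 96), seed=4)
        filtered = bandpass(vol, FilterParams())
        base = standard_detection_params()
        prev_keys = None
        prev_count = np.inf
        thresholds = np.linspace(0.0, 3.0 * base.min_mass, 10)
        zero_keys = None
        for t in thresholds:
            spots = detect_spots(
                filtered,
                DetectionParams(base.spot_radius, float(t), base.separation,
                                base.percentile_floor),
            )
            keys = set(map(tuple, np.round(spots[["z", "y", "x"]].values, 6)))
            assert len(spots) <= prev_count
            if zero_keys is None:
                zero_keys = keys
            else:
                assert keys <= zero_keys  # threshold-0 result is a superset
            prev_count = len(spots)
            prev_keys = keys
        assert prev_keys is not None

    def test_close_pair_suppressed_keeping_brighter(self):
        # two resolvable spots 3.5 voxels apart: with separation 4 only
        # the brighter survives; exhaustive greedy suppression oracle agrees
        vol = np.zeros((9, 32, 32))
        zz, yy, xx = np.mgrid[0:9, 0:32, 0:32].astype(float)

        def spot(z0, y0, x0, amp):
            return amp * np.exp(
                -((zz - z0) ** 2) / 2 - ((yy - y0) ** 2) / 2 - ((xx - x0) ** 2) / 2
            )

        vol += spot(4, 15, 14, 0.4) + spot(4, 15, 17.5, 0.7)
        loose = detect_spots(vol, DetectionParams(2, 0.0, 1.0, 95.0))
        assert len(loose) == 2
        tight = detect_spots(vol, DetectionParams(2, 0.0, 4.0, 95.0))
        assert len(tight) == 1
        # oracle: exhaustive pairwise suppression on the loose table
        order = loose.sort_values(["mass"], ascending=False).index
        kept = []
        for i in order:
            pi = loose.loc[i, ["z", "y", "x"]].values.astype(float)
            if all(np.linalg.norm(pi - k) >= 4.0 for k in kept):
                kept.append(pi)
        assert len(kept) == 1
        np.testing.assert_allclose(
            tight[["z", "y", "x"]].values[0], kept[0], atol=1e-9
        )
        assert tight["mass"].iloc[0] == loose["mass"].max()

    def test_pure_function_of_volume(self):
        vol, _ = generate_spot_field(n_spots=15, shape=(12, 64, 64), seed=5)
        filtered = bandpass(vol, FilterParams())
        p = standard_detection_params()
        a = detect_spots(filtered, p)
        b = detect_spots(filtered.copy(), p)
        pd.testing.assert_frame_equal(a, b)

    def test_2d_volume_matches_2d_reference_detector(self):
        """On a z=1 stack detection must behave as a purely 2D detector."""
        rng = np.random.default_rng(6)
        ny = nx = 96
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        img = np.zeros((ny, nx))
        truth = []
        for _ in range(12):
            y0, x0 = rng.uniform(10, ny - 10, 2)
            if any(np.hypot(y0 - t[0], x0 - t[1]) < 12 for t in truth):
                continue
            truth.append((y0, x0))
            img += 0.5 * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * 1.5**2))
        vol = img[None, :, :]
        p = DetectionParams(3, 0.5, 3.0, 99.0)
        spots = detect_spots(vol, p)

        # independent 2D reference: peak finding + window mass + centroid
        floor = np.percentile(img, 99.0)
        cand = peak_local_max(img, min_distance=1, threshold_abs=floor)
        ref = []
        for y, x in cand:
            w = img[max(0, y - 3) : y + 4, max(0, x - 3) : x + 4]
            if w.sum() < 0.5:
                continue
            wy, wx = np.mgrid[max(0, y - 3) : y + 4, max(0, x - 3) : x + 4]
            ref.append(
                ((w * wy).sum() / w.sum(), (w * wx).sum() / w.sum(), w.sum())
            )
        assert len(spots) == len(truth) == len(ref)
        got = spots.sort_values(["y", "x"])[["y", "x"]].values
        ref_arr = np.array(sorted((r[0], r[1]) for r in ref))
        np.testing.assert_allclose(got, ref_arr, atol=0.3)
        assert np.isnan(spots["sigma_z"]).all()

    def test_standard_field_recall_precision(self, spot_field_100):
        vol, truth = spot_field_100
        filtered = bandpass(vol, FilterParams())
        spots = detect_spots(filtered, standard_detection_params())
        m = score_spots(spots, truth, gate=2.0)
        assert m["recall"] >= 0.95 and m["precision"] >= 0.95


class TestCategorize:
    def _table(self, masses):
        df = empty_spot_table()
        rows = pd.DataFrame(
            {
                "channel": "T", "z": 1.0, "y": np.arange(len(masses), dtype=float),
                "x": 1.0, "mass": masses, "peak": 0.1, "sigma_z": 1.0,
                "sigma_y": 1.0, "sigma_x": 1.0, "fallback": False, "region_id": 0,
            }
        )
        return pd.concat([df, rows], ignore_index=True)

    @pytest.mark.parametrize(
        "lower,upper",
        [(0.06, 0.07), (0.23, 0.24)],  # the two advisory interval presets
    )
    def test_bins_partition_spot_set(self, lower, upper):
        masses = np.linspace(0.05, 0.25, 21)
        spots = self._table(masses)
        rep = categorize_spots(spots, lower, upper)
        assert sum(rep.counts) == len(spots)
        assert (rep.below["mass"] < lower).all()
        assert ((rep.within["mass"] >= lower) & (rep.within["mass"] < upper)).all()
        assert (rep.above["mass"] >= upper).all()

    def test_degenerate_equal_bounds(self):
        spots = self._table([0.1, 0.2, 0.3])
        rep = categorize_spots(spots, 0.2, 0.2)
        assert rep.counts == (1, 0, 2)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ParameterError):
            categorize_spots(self._table([0.1]), 0.3, 0.2)


class TestOverlay:
    def test_empty_table_renders_plain_projection(self, tmp_path):
        rep = categorize_spots(empty_spot_table(), 0.1, 0.2)
        out = render_detection_overlay(
            np.random.default_rng(0).random((4, 32, 32)), rep,
            tmp_path / "o.png",
        )
        assert out.exists() and out.stat().st_size > 0

    def test_rerender_is_byte_identical(self, tmp_path):
        vol, _ = generate_spot_field(n_spots=10, shape=(10, 64, 64), seed=8)
        filtered = bandpass(vol, FilterParams())
        spots = detect_spots(filtered, standard_detection_params())
        rep = categorize_spots(spots, 0.8 * spots["mass"].median(),
                               1.2 * spots["mass"].median())
        a = render_detection_overlay(filtered, rep, tmp_path / "a.png")
        b = render_detection_overlay(filtered, rep, tmp_path / "b.png")
        assert a.read_bytes() == b.read_bytes()
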