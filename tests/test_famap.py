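"""FA-map construction: skeletons, distance maps, TS/DS maps, Eq-style update."""

import numpy as np
import pytest
from scipy import ndimage

from ssfa import famap


class TestSkeletonize:
    def test_empty_in_empty_out(self):
        assert not famap.skeletonize(np.zeros((16, 16), bool)).any()

    def test_ribbon_skeleton_is_thin_horizontal_line(self, ribbon):
        m = ribbon(rows=(30, 35), cols=(5, 120))  # width 5
        sk = famap.skeletonize(m)
        rows, cols = np.nonzero(sk)
        assert np.ptp(rows) <= 1                  # collinear up to one-row jog
        per_col = np.bincount(cols, minlength=128)
        assert per_col.max() == 1                 # one pixel wide
        assert sk.sum() >= (120 - 5) - 6          # endpoints retract <= 3 px

    def test_idempotent(self, phantom64):
        sk = famap.skeletonize(phantom64.mask)
        assert np.array_equal(famap.skeletonize(sk), sk)

    def test_skeleton_subset_of_mask(self, phantom64):
        sk = famap.skeletonize(phantom64.mask)
        assert not (sk & ~phantom64.mask).any()


class TestDistanceMap:
    def test_single_pixel_has_distance_one(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        d = famap.distance_map(m)
        assert d.pixels[4, 4] == 1.0
        assert d.dmin == d.dmax == 1.0

    def test_ribbon_dmax_matches_half_width(self, ribbon):
        m = ribbon(rows=(30, 37), cols=(5, 120))  # 7 px wide, half-width 3.5
        d = famap.distance_map(m)
        # brute-force check on the centerline row
        bg = np.argwhere(~m)
        r, c = 33, 60
        brute = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1)).min()
        assert d.pixels[r, c] == pytest.approx(brute)
        assert 3.0 <= d.dmax <= 4.5

    def test_zero_on_background(self, phantom64):
        d = famap.distance_map(phantom64.mask)
        assert (d.pixels[~phantom64.mask] == 0).all()
        assert d.dmax >= d.dmin > 0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            famap.distance_map(np.zeros((8, 8), bool))


class TestThresholdLadder:
    def test_linear_formula(self):
        assert np.allclose(famap.threshold_ladder(1, 11, 10),
                           np.arange(2, 12))

    def test_degenerate_equal_extrema(self):
        assert np.allclose(famap.threshold_ladder(3.0, 3.0, 5), 3.0)

    def test_strictly_increasing(self):
        t = famap.threshold_ladder(1.2, 7.7, 10)
        assert (np.diff(t) > 0).all()

    def test_inverted_extrema_error(self):
        with pytest.raises(ValueError):
            famap.threshold_ladder(5, 4, 10)


class TestTSMap:
    def test_empty_prediction_gives_zeros(self):
        assert not famap.ts_map(np.zeros((32, 32), bool)).any()

    def test_uniform_ribbon_is_constant(self, ribbon):
        m = ribbon(rows=(30, 37), cols=(5, 120))
        ts = famap.ts_map(m, 10)
        vals = np.unique(ts[m])
        assert len(vals) == 1
        assert not ts[~m].any()

    def test_thin_scores_above_thick(self, ribbon):
        thin = ribbon(rows=(10, 13), cols=(5, 120))    # width 3
        thick = ribbon(rows=(30, 41), cols=(5, 120))   # width 11
        ts = famap.ts_map(thin | thick, 10)
        assert ts[thin].mean() > ts[thick].mean()

    def test_thickness_monotonicity_across_widths(self):
        """Mean TS value is non-increasing in branch width (3,5,7,9,11)."""
        widths = [3, 5, 7, 9, 11]
        m = np.zeros((100, 128), bool)
        bands = []
        r = 5
        for w in widths:
            m[r:r + w, 5:120] = True
            bands.append((r, r + w))
            r += w + 10
        ts = famap.ts_map(m, 10)
        means = [ts[a:b, 5:120].mean() for a, b in bands]
        assert all(x >= y - 1e-9 for x, y in zip(means, means[1:]))

    def test_values_quantized_to_levels(self, phantom64):
        L = 10
        ts = famap.ts_map(phantom64.mask, L)
        assert ts.min() >= 0 and ts.max() <= 1
        assert np.allclose(ts * L, np.round(ts * L), atol=1e-6)


class TestDSMap:
    def test_identical_predictions_give_zero(self, phantom64):
        assert not famap.ds_map(phantom64.mask, phantom64.mask).any()

    def test_symmetry(self, ribbon, phantom64):
        p1 = phantom64.mask
        p2 = ribbon(shape=p1.shape, rows=(10, 14), cols=(4, 60))
        assert np.array_equal(famap.ds_map(p1, p2), famap.ds_map(p2, p1))

    def test_deleted_branch_is_covered(self, ribbon):
        thin = ribbon(rows=(10, 13), cols=(5, 120))
        thick = ribbon(rows=(30, 41), cols=(5, 120))
        ds = famap.ds_map(thin | thick, thick)
        assert ds[thin].mean() > 0.9

    def test_dilation_jitter_suppressed(self, phantom64):
        p1 = phantom64.mask
        p2 = ndimage.binary_dilation(p1)
        ds = famap.ds_map(p1, p2)
        assert ds.sum() / p1.size < 0.01

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            famap.ds_map(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestComposeAndUpdate:
    def test_channel_order_and_roundtrip(self, ribbon):
        ts1 = famap.ts_map(ribbon(), 10)
        ts2 = 0.5 * ts1
        ds = np.zeros_like(ts1)
        fa = famap.compose_fa_map(ts1, ts2, ds)
        a, b, c = famap.split_fa_map(fa)
        assert np.array_equal(a, ts1) and np.array_equal(b, ts2)
        assert np.array_equal(c, ds)

    def test_out_of_range_rejected(self):
        z = np.zeros((8, 8), np.float32)
        with pytest.raises(ValueError):
            famap.compose_fa_map(z + 1.5, z, z)

    @pytest.mark.parametrize("k,expect", [(0.0, "a0"), (1.0, "hat"), (0.5, "mid")])
    def test_update_endpoints_and_midpoint(self, k, expect):
        a0 = np.zeros((3, 8, 8), np.float32)
        hat = np.ones((3, 8, 8), np.float32)
        st = famap.FAState(a0, k)
        out = famap.update_fa_map(st, hat)
        target = {"a0": a0, "hat": hat, "mid": np.full_like(a0, 0.5)}[expect]
        assert np.array_equal(out, target)

    def test_update_is_not_recursive(self):
        """After many updates the state is still (1-k)A0 + k*(last A_hat)."""
        rng = np.random.default_rng(0)
        a0 = rng.random((3, 8, 8)).astype(np.float32)
        st = famap.FAState(a0, 0.3)
        hat = None
        for _ in range(5):
            hat = rng.random((3, 8, 8)).astype(np.float32)
            famap.update_fa_map(st, hat)
        assert np.allclose(st.current, 0.7 * a0 + 0.3 * hat)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            famap.FAState(np.zeros((3, 4, 4)), 1.5)


class TestInitFAMaps:
    class _FakePredictor:
        def __init__(self, mask, trained=True):
            self.mask = mask
            self.trained = trained

        def predict_mask(self, image, threshold=0.5):
            return self.mask

    def test_ts_channels_identical_ds_zero(self, phantom64):
        pred = self._FakePredictor(phantom64.mask)
        (a0,) = famap.init_fa_maps(pred, [phantom64.image])
        assert np.array_equal(a0[0], a0[1])
        assert not a0[2].any()

    def test_empty_prediction_gives_zero_map(self, phantom64):
        pred = self._FakePredictor(np.zeros_like(phantom64.mask))
        (a0,) = famap.init_fa_maps(pred, [phantom64.image])
        assert not a0.any()

    def test_untrained_predictor_rejected(self, phantom64):
        pred = self._FakePredictor(phantom64.mask, trained=False)
        with pytest.raises(ValueError):
            famap.init_fa_maps(pred, [phantom64.image])
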