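import numpy as np
import pytest
from scipy import stats

from intensify3d import (
    BackgroundMask,
    ImageStack,
    NormalizationConfig,
    compute_background_mask,
    normalize_plane,
    normalize_stack_xy,
    propagate_mbi,
    remove_signal,
)
from intensify3d.tissue_detector import TissueMask
from intensify3d.xy_normalizer import _plane_rng


def cfg_for(mbi=60.0, sfs=11, **kw):
    return NormalizationConfig(mbi=mbi, sfs=sfs, **kw)


class TestPropagateMbi:
    def test_identical_planes_share_the_reference_mbi(self, rng, all_tissue):
        plane = rng.integers(0, 200, size=(30, 30)).astype(np.uint16)
        stack = ImageStack(planes=[plane, plane.copy()], bit_depth=16)
        masks = [all_tissue(plane.shape)] * 2
        mbi, q_star = propagate_mbi(stack, masks, cfg_for(mbi=100.0))
        assert mbi[0] == 100.0
        # identical distributions: the propagated value interpolates the
        # same order statistics, so it matches the reference's own quantile
        ref_vals = plane.astype(float).ravel()
        assert mbi[1] == pytest.approx(np.quantile(ref_vals, q_star))

    def test_scaled_plane_gets_scaled_mbi(self, rng, all_tissue):
        a = rng.uniform(0, 100, size=(100, 100))
        stack = ImageStack(planes=[a, 2.0 * a], bit_depth=16)
        masks = [all_tissue(a.shape)] * 2
        cfg = cfg_for(mbi=10.0)
        mbi, q_star = propagate_mbi(stack, masks, cfg)
        # oracle: direct quantile computation + scaling equivariance
        assert mbi[1] == pytest.approx(2.0 * np.quantile(a, q_star), rel=1e-12)
        assert mbi[1] == pytest.approx(2.0 * cfg.mbi, rel=2e-3)

    def test_mbi_above_all_pixels_gives_rank_one_and_plane_maxima(self, rng, all_tissue):
        a = rng.uniform(0, 100, size=(20, 20))
        b = rng.uniform(0, 50, size=(20, 20))
        stack = ImageStack(planes=[a, b], bit_depth=16)
        mbi, q_star = propagate_mbi(stack, [all_tissue(a.shape)] * 2, cfg_for(mbi=500.0))
        assert q_star == 1.0
        assert mbi[1] == pytest.approx(b.max())

    def test_plane_without_tissue_is_flagged_skip(self, rng, all_tissue):
        a = rng.uniform(10, 100, size=(20, 20))
        stack = ImageStack(planes=[a, a.copy()], bit_depth=16)
        masks = [all_tissue(a.shape), TissueMask(np.zeros(a.shape, bool))]
        mbi, _ = propagate_mbi(stack, masks, cfg_for(mbi=50.0))
        assert np.isnan(mbi[1]) and np.isfinite(mbi[0])

    def test_mbi_below_all_reference_pixels_raises(self, rng, all_tissue):
        a = rng.uniform(100, 200, size=(20, 20))
        stack = ImageStack(planes=[a], bit_depth=16)
        with pytest.raises(ValueError, match="MBI below"):
            propagate_mbi(stack, [all_tissue(a.shape)], cfg_for(mbi=5.0))


class TestRemoveSignal:
    def test_plane_without_signal_is_unchanged(self, all_tissue):
        plane = np.full((10, 10), 8.0)
        out, n = remove_signal(plane, 10.0, all_tissue(plane.shape), _plane_rng(0, 0))
        assert n == 0 and np.array_equal(out, plane)

    def test_single_donor_value_replaces_the_signal_pixel(self, all_tissue):
        plane = np.full((10, 10), 5.0)
        plane[3, 4] = 100.0
        out, n = remove_signal(plane, 10.0, all_tissue(plane.shape), _plane_rng(0, 0))
        assert n == 1 and out[3, 4] == 5.0
        assert out.max() <= 10.0

    def test_replacements_follow_the_donor_distribution(self, rng, all_tissue):
        # background drawn from a known discrete law, 10% supra-MBI signal
        support = np.array([2.0, 4.0, 6.0, 8.0])
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        n = 100_000
        vals = rng.choice(support, size=n, p=probs)
        signal_idx = rng.choice(n, size=n // 10, replace=False)
        vals[signal_idx] = 50.0
        plane = vals.reshape(250, 400)
        out, replaced = remove_signal(plane, 10.0, all_tissue(plane.shape), _plane_rng(1, 0))
        assert replaced == n // 10
        donors = plane[plane <= 10.0]
        expected_freq = np.array([(donors == v).mean() for v in support])
        new_vals = out.ravel()[signal_idx]
        observed = np.array([(new_vals == v).sum() for v in support])
        _, p = stats.chisquare(observed, expected_freq * len(new_vals))
        assert p > 0.01

    def test_error_when_no_donors(self, all_tissue):
        plane = np.full((5, 5), 100.0)
        with pytest.raises(ValueError, match="MBI below all tissue"):
            remove_signal(plane, 10.0, all_tissue(plane.shape), _plane_rng(0, 0))

    def test_local_recentring_preserves_a_gradient(self, rng, all_tissue):
        # a bright blob on a strong ramp: local in-fill must keep the local
        # level instead of pulling it toward the plane-wide mean
        h, w = 60, 200
        ramp = np.linspace(100, 1000, w)[None, :] * np.ones((h, 1))
        plane = ramp + rng.normal(0, 5, size=(h, w))
        plane[20:40, 170:190] = 5000.0
        out, _ = remove_signal(
            plane, 1100.0, all_tissue(plane.shape), _plane_rng(0, 0), local_window=31
        )
        filled = out[20:40, 170:190]
        local_truth = ramp[20:40, 170:190]
        assert abs(filled.mean() - local_truth.mean()) < 0.05 * local_truth.mean()


class TestBackgroundMask:
    def test_constant_plane_reproduced(self, all_tissue):
        plane = np.full((40, 40), 77.0)
        bg = compute_background_mask(plane, all_tissue(plane.shape), cfg_for(sfs=11))
        assert np.allclose(bg.grid, 77.0)
        assert not bg.floor_applied

    def test_linear_ramp_reproduced_to_the_boundary(self):
        yy, xx = np.mgrid[0:50, 0:80].astype(float)
        ramp = 5.0 + 2.0 * xx + 0.5 * yy
        bg = compute_background_mask(ramp, TissueMask(np.ones(ramp.shape, bool)), cfg_for(sfs=15))
        assert np.max(np.abs(bg.grid - ramp) / ramp) < 1e-6

    def test_matches_per_window_least_squares_fit(self, rng):
        # independent oracle: direct polynomial fit in each sliding window
        from scipy.signal import savgol_filter

        y = np.cumsum(rng.normal(0, 1, size=60))
        window, order = 11, 3
        filtered = savgol_filter(y, window, order, mode="interp")
        half = window // 2
        x = np.arange(window, dtype=float)
        for i in range(half, 60 - half):
            coeffs = np.polyfit(x, y[i - half : i + half + 1], order)
            assert filtered[i] == pytest.approx(np.polyval(coeffs, half), abs=1e-8)

    def test_floor_applied_to_dark_plane(self, all_tissue):
        plane = np.zeros((30, 30))
        bg = compute_background_mask(plane, all_tissue(plane.shape), cfg_for(sfs=11))
        assert bg.floor_applied and np.all(bg.grid == 1.0)

    def test_sfs_too_large_raises(self, all_tissue):
        plane = np.zeros((10, 10))
        with pytest.raises(ValueError, match="SFS too large"):
            compute_background_mask(plane, all_tissue(plane.shape), cfg_for(sfs=21))

    def test_medium_filled_with_tissue_median(self):
        # non-tissue corner must not drag the mask down
        plane = np.full((40, 40), 200.0)
        plane[:10, :10] = 0.0
        tissue = np.ones((40, 40), bool)
        tissue[:10, :10] = False
        bg = compute_background_mask(plane, TissueMask(tissue), cfg_for(sfs=11))
        assert np.allclose(bg.grid, 200.0)


class TestNormalizePlane:
    def test_pure_background_maps_to_mask_median(self, rng, all_tissue):
        m = rng.uniform(50, 150, size=(20, 20))
        out, scale = normalize_plane(m, BackgroundMask(m, False), all_tissue(m.shape))
        assert scale == pytest.approx(np.median(m))
        assert np.allclose(out, scale)

    def test_doubled_pixel_maps_to_twice_the_median(self, all_tissue):
        m = np.full((5, 5), 10.0)
        plane = m.copy()
        plane[2, 2] = 20.0
        out, scale = normalize_plane(plane, BackgroundMask(m, False), all_tissue(m.shape))
        assert out[2, 2] == pytest.approx(2 * scale)
        assert out[0, 0] == pytest.approx(scale)

    def test_no_tissue_passes_through(self):
        plane = np.arange(25, dtype=float).reshape(5, 5)
        mask = BackgroundMask(np.full((5, 5), 3.0), False)
        out, scale = normalize_plane(plane, mask, TissueMask(np.zeros((5, 5), bool)))
        assert np.array_equal(out, plane) and scale == 1.0

    def test_signal_to_background_ratio_preserved_under_flat_mask(self, all_tissue):
        # two-level image, flat mask: the ratio s/b is exactly conserved
        plane = np.full((10, 10), 40.0)
        plane[5, 5] = 360.0
        out, _ = normalize_plane(plane, BackgroundMask(np.full((10, 10), 8.0), False), all_tissue(plane.shape))
        assert out[5, 5] / out[0, 0] == pytest.approx(360.0 / 40.0)


class TestNormalizeStackXY:
    def test_flat_stack_is_identity(self, flat_stack):
        cfg = cfg_for(mbi=60.0, sfs=11)
        corrected, records, profiles, masks = normalize_stack_xy(flat_stack, cfg)
        for plane in corrected:
            assert np.allclose(plane, 50.0)
        assert all(r.n_signal_pixels_replaced == 0 for r in records)

    def test_plane_order_does_not_change_results(self, rng):
        planes = [rng.integers(0, 400, size=(24, 24)).astype(np.uint16) for _ in range(4)]
        stack = ImageStack(planes=planes, bit_depth=16)
        cfg = cfg_for(mbi=300.0, sfs=9, seed=3)
        fwd, *_ = normalize_stack_xy(stack, cfg)
        rev, *_ = normalize_stack_xy(stack, cfg, plane_order=[3, 2, 1, 0])
        for a, b in zip(fwd, rev):
            assert np.array_equal(a, b)

    def test_seed_determinism(self, rng):
        planes = [rng.integers(0, 400, size=(24, 24)).astype(np.uint16) for _ in range(3)]
        stack = ImageStack(planes=planes, bit_depth=16)
        cfg = cfg_for(mbi=300.0, sfs=9, seed=11)
        a, *_ = normalize_stack_xy(stack, cfg)
        b, *_ = normalize_stack_xy(stack, cfg)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_mask_positivity_invariant(self, rng, all_tissue):
        plane = rng.uniform(0, 3, size=(30, 30))
        bg = compute_background_mask(plane, all_tissue(plane.shape), cfg_for(sfs=11, mask_floor=1.0))
        assert bg.grid.min() >= 1.0
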