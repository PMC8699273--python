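"""The four SSIM-family metrics and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy.ndimage import correlate, gaussian_filter

from dotiqa.metrics import (SSIMConfig, compute_metric, downsample2,
                            gaussian_window, issim_components, missim_s,
                            ms_issim_s, ms_ssim, mssim, similarity_grid_map,
                            ssim_components, window_stats)

CFG = SSIMConfig()


def random_pair(rng, side=32, sigma=20.0):
    x = rng.integers(0, 256, size=(side, side)).astype(float)
    y = np.clip(x + rng.normal(0, sigma, x.shape), 0, 255).round()
    return x, y


def ndimage_mssim(x, y, cfg=CFG):
    """Independent sliding-window SSIM via ndimage correlation filters."""
    w = gaussian_window(cfg.window_size, cfg.window_sigma)

    def filt(img):
        return correlate(img, w, mode="constant")

    half = cfg.window_size // 2
    crop = (slice(half, -half), slice(half, -half))
    mu_x = filt(x)[crop]
    mu_y = filt(y)[crop]
    exx = filt(x * x)[crop] - mu_x ** 2
    eyy = filt(y * y)[crop] - mu_y ** 2
    exy = filt(x * y)[crop] - mu_x * mu_y
    c1, c2 = cfg.c1, cfg.c2
    num = (2 * mu_x * mu_y + c1) * (2 * exy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (exx + eyy + c2)
    return float(np.mean(num / den))


class TestGaussianWindow:
    def test_unit_sum(self):
        assert abs(gaussian_window(9, 1.5).sum() - 1.0) < 1e-12

    def test_rotation_symmetry_and_centre_max(self):
        w = gaussian_window(9, 1.5)
        np.testing.assert_allclose(w, np.rot90(w), atol=1e-15)
        np.testing.assert_allclose(w, w.T, atol=1e-15)
        assert w[4, 4] == w.max()

    def test_even_or_tiny_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_window(8, 1.5)
        with pytest.raises(ValueError):
            gaussian_window(1, 1.5)


class TestWindowStats:
    def test_constant_window_all_sigmas_zero(self):
        w = gaussian_window(9, 1.5)
        s = window_stats(np.full((9, 9), 7.0), np.full((9, 9), 7.0), w)
        assert s.sigma_x == pytest.approx(0.0, abs=1e-12)
        assert s.sigma_y == pytest.approx(0.0, abs=1e-12)
        assert s.sigma_xy == pytest.approx(0.0, abs=1e-12)
        assert s.lambda_x == pytest.approx(0.0, abs=1e-12)
        assert s.sigma_x_minus == pytest.approx(0.0, abs=1e-12)
        assert s.sigma_x_plus == pytest.approx(0.0, abs=1e-12)

    def test_identical_windows_cov_equals_var(self, rng):
        w = gaussian_window(9, 1.5)
        x = rng.normal(size=(9, 9))
        s = window_stats(x, x, w)
        assert s.sigma_xy == pytest.approx(s.sigma_x ** 2, rel=1e-12)

    def test_matches_bruteforce_loops(self, rng):
        """Weighted moments vs explicit python double loop."""
        w = gaussian_window(9, 1.5)
        x = rng.normal(5, 2, size=(9, 9))
        y = rng.normal(5, 2, size=(9, 9))
        s = window_stats(x, y, w)
        mu_x = sum(w[i, j] * x[i, j] for i in range(9) for j in range(9))
        var_x = sum(w[i, j] * (x[i, j] - mu_x) ** 2
                    for i in range(9) for j in range(9))
        mu_y = sum(w[i, j] * y[i, j] for i in range(9) for j in range(9))
        cov = sum(w[i, j] * (x[i, j] - mu_x) * (y[i, j] - mu_y)
                  for i in range(9) for j in range(9))
        assert s.mu_x == pytest.approx(mu_x, abs=1e-12)
        assert s.sigma_x == pytest.approx(np.sqrt(var_x), abs=1e-12)
        assert s.sigma_xy == pytest.approx(cov, abs=1e-12)
        # split sigma over the strictly-below-mean subset, renormalized
        wm = sum(w[i, j] for i in range(9) for j in range(9)
                 if x[i, j] < mu_x)
        var_minus = sum(w[i, j] * (x[i, j] - mu_x) ** 2
                        for i in range(9) for j in range(9)
                        if x[i, j] < mu_x) / wm
        assert s.sigma_x_minus == pytest.approx(np.sqrt(var_minus),
                                                abs=1e-12)

    def test_cauchy_schwarz(self, rng):
        w = gaussian_window(9, 1.5)
        for _ in range(20):
            x = rng.normal(size=(9, 9))
            y = rng.normal(size=(9, 9))
            s = window_stats(x, y, w)
            assert abs(s.sigma_xy) <= s.sigma_x * s.sigma_y + 1e-12


class TestComponents:
    def test_equal_means_unit_luminance(self, rng):
        w = gaussian_window(9, 1.5)
        x = rng.normal(100, 10, size=(9, 9))
        mu = float((w * x).sum())
        y = 2 * mu - x            # reflected: same weighted mean as x
        l, _, _ = ssim_components(window_stats(x, y, w), CFG)
        assert l == pytest.approx(1.0, abs=1e-12)

    def test_equal_sigmas_unit_contrast(self, rng):
        w = gaussian_window(9, 1.5)
        x = rng.normal(100, 10, size=(9, 9))
        y = 200.0 - x             # same spread, different mean
        _, c, _ = ssim_components(window_stats(x, y, w), CFG)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_product_equals_single_formula(self, rng):
        """l*c*s collapses to the classic one-line SSIM with C3 = C2/2."""
        w = gaussian_window(9, 1.5)
        for _ in range(20):
            x = rng.normal(100, 30, size=(9, 9))
            y = rng.normal(100, 30, size=(9, 9))
            s = window_stats(x, y, w)
            l, c, strut = ssim_components(s, CFG)
            single = ((2 * s.mu_x * s.mu_y + CFG.c1)
                      * (2 * s.sigma_xy + CFG.c2)) / (
                (s.mu_x ** 2 + s.mu_y ** 2 + CFG.c1)
                * (s.sigma_x ** 2 + s.sigma_y ** 2 + CFG.c2))
            assert l * c * strut == pytest.approx(single, abs=1e-12)

    def test_issim_identity_windows(self, rng):
        w = gaussian_window(9, 1.5)
        x = rng.normal(size=(9, 9))
        s_tilde, h = issim_components(window_stats(x, x, w), CFG)
        assert s_tilde == pytest.approx(1.0, abs=1e-12)
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_issim_shift_invariant_sharpness(self, rng):
        """A constant intensity shift leaves the mean-removed window, hence
        the sharpness term, unchanged."""
        w = gaussian_window(9, 1.5)
        x = rng.normal(100, 20, size=(9, 9))
        _, h = issim_components(window_stats(x, x + 25.0, w), CFG)
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_issim_matches_direct_formula(self, rng):
        w = gaussian_window(9, 1.5)
        x = rng.normal(100, 30, size=(9, 9))
        y = rng.normal(100, 30, size=(9, 9))
        s = window_stats(x, y, w)
        s_tilde, h = issim_components(s, CFG)
        c2 = CFG.c2
        expected = ((2 * s.sigma_x_minus * s.sigma_y_minus + c2)
                    * (2 * s.sigma_x_plus * s.sigma_y_plus + c2)) / (
            (s.sigma_x_minus ** 2 + s.sigma_y_minus ** 2 + c2)
            * (s.sigma_x_plus ** 2 + s.sigma_y_plus ** 2 + c2))
        assert s_tilde == pytest.approx(expected, abs=1e-12)


class TestMSSIM:
    def test_identity_is_exactly_one(self, rng):
        x, _ = random_pair(rng)
        assert mssim(x, x).score == 1.0

    def test_matches_ndimage_reference(self, rng):
        for _ in range(5):
            x, y = random_pair(rng, side=32)
            assert mssim(x, y).score == pytest.approx(ndimage_mssim(x, y),
                                                      abs=1e-7)

    def test_matches_scikit_image_with_matched_window(self, rng):
        """Cross-library check: our sliding window at size 11 reproduces
        scikit-image's gaussian-weighted SSIM (truncated at radius 5)."""
        from skimage.metrics import structural_similarity
        x, y = random_pair(rng, side=64)
        ref = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=255)
        ours = mssim(x, y, SSIMConfig(window_size=11)).score
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_inverted_image_scores_below_one(self, rng):
        x, _ = random_pair(rng)
        assert mssim(x, 255.0 - x).score < 1.0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            mssim(np.zeros((5, 5)), np.zeros((5, 5)))

    def test_map_mean_is_score(self, rng):
        x, y = random_pair(rng)
        m = mssim(x, y)
        assert m.score == pytest.approx(float(m.map.mean()), abs=1e-15)
        assert np.all(m.map <= 1.0 + 1e-12) and np.all(m.map >= -1.0 - 1e-12)


class TestDownsample2:
    def test_constant_preserved_at_half_size(self):
        out = downsample2(np.full((128, 128), 37.0))
        assert out.shape == (64, 64)
        np.testing.assert_allclose(out, 37.0)

    def test_checkerboard_flattens_to_midvalue(self):
        board = np.indices((16, 16)).sum(axis=0) % 2 * 255.0
        np.testing.assert_allclose(downsample2(board), 127.5)

    def test_odd_side_rejected(self):
        with pytest.raises(ValueError):
            downsample2(np.zeros((15, 15)))


def unrolled_ms_ssim(x, y, cfg=CFG):
    """Explicitly unrolled 5-scale loop using the single-scale machinery."""
    from dotiqa.metrics import _component_maps
    terms = []
    for k in range(cfg.n_scales):
        maps = _component_maps(x, y, cfg, split=False)
        terms.append((maps["c"].mean(), maps["s"].mean()))
        if k < cfg.n_scales - 1:
            x, y = downsample2(x), downsample2(y)
    lbar = _component_maps(x, y, cfg, split=False)["l"].mean()
    score = lbar ** cfg.scale_weights[4]
    for k, (c, s) in enumerate(terms):
        score *= (c * s) ** cfg.scale_weights[k]
    return score


def unrolled_ms_issim_s(x, y, cfg=CFG):
    from dotiqa.metrics import _component_maps
    terms, hbars = [], []
    for k in range(cfg.n_scales):
        maps = _component_maps(x, y, cfg, split=True)
        terms.append((maps["c"].mean(), maps["s"].mean()))
        hbars.append(maps["h"].mean())
        if k < cfg.n_scales - 1:
            x, y = downsample2(x), downsample2(y)
    lbar = _component_maps(x, y, cfg, split=True)["l"].mean()
    score = lbar ** cfg.scale_weights[4]
    for k, (c, s) in enumerate(terms):
        score *= (c * s) ** cfg.scale_weights[k]
    return np.mean(hbars) * score


class TestMultiscale:
    def test_identity_is_one(self, rng):
        x, _ = random_pair(rng, side=160)
        assert ms_ssim(x, x) == 1.0
        assert ms_issim_s(x, x) == 1.0

    def test_printed_weights_sum(self):
        assert sum(CFG.scale_weights) == pytest.approx(1.0001, abs=1e-12)

    def test_ms_ssim_matches_unrolled_loop(self, rng):
        x, y = random_pair(rng, side=160)
        assert ms_ssim(x, y) == pytest.approx(unrolled_ms_ssim(x, y),
                                              abs=1e-10)

    def test_ms_issim_s_matches_unrolled_loop(self, rng):
        x, y = random_pair(rng, side=160)
        assert ms_issim_s(x, y) == pytest.approx(unrolled_ms_issim_s(x, y),
                                                 abs=1e-10)

    def test_sum_prefactor_variant(self, rng):
        x, y = random_pair(rng, side=160)
        mean_v = ms_issim_s(x, y, SSIMConfig(ms_prefactor="mean"))
        sum_v = ms_issim_s(x, y, SSIMConfig(ms_prefactor="sum"))
        assert sum_v == pytest.approx(5 * mean_v, rel=1e-12)

    def test_too_small_image_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            ms_ssim(np.zeros((128, 128)), np.zeros((128, 128)))


def test_blur_penalized_harder_by_sharpness_metric(rng):
    """Low-pass filtering is the failure mode the sharpness term targets:
    the sharpness-aware score must fall below plain mean SSIM."""
    x, _ = random_pair(rng, side=64)
    y = gaussian_filter(x, 2.0)
    assert missim_s(x, y).score < mssim(x, y).score


def test_missim_s_matches_per_window_loop(rng):
    """Sliding missim_s equals an explicit window-by-window evaluation."""
    w = gaussian_window(9, 1.5)
    x, y = random_pair(rng, side=16)
    got = missim_s(x, y)
    for idx in [(0, 0), (3, 5), (7, 7)]:
        i, j = idx
        xs = x[i:i + 9, j:j + 9]
        ys = y[i:i + 9, j:j + 9]
        stats = window_stats(xs, ys, w)
        l, c, _ = ssim_components(stats, CFG)
        s_tilde, h = issim_components(stats, CFG)
        assert got.map[i, j] == pytest.approx(l * c * s_tilde * h, abs=1e-12)


def test_all_metrics_symmetric(rng):
    x, y = random_pair(rng, side=160)
    for name in ("mssim", "ms_ssim", "missim_s", "ms_issim_s"):
        a = compute_metric(name, x, y)
        b = compute_metric(name, y, x)
        assert a == pytest.approx(b, abs=1e-12)


def test_degradation_monotonicity(rng):
    """All four scores fall as additive noise grows (10-seed average)."""
    x, _ = random_pair(rng, side=160, sigma=0.0)
    sigmas = [4.0, 16.0, 64.0]
    means = {name: [] for name in ("mssim", "ms_ssim", "missim_s",
                                   "ms_issim_s")}
    for sigma in sigmas:
        scores = {name: [] for name in means}
        for seed in range(10):
            noise_rng = np.random.default_rng(seed)
            y = np.clip(x + noise_rng.normal(0, sigma, x.shape), 0,
                        255).round()
            for name in means:
                scores[name].append(compute_metric(name, x, y))
        for name in means:
            means[name].append(np.mean(scores[name]))
    for name, seq in means.items():
        assert seq[0] > seq[1] > seq[2], name


def test_similarity_grid_map_consistency(rng):
    x, _ = random_pair(rng, side=32)
    batch = [x.copy(), np.clip(x + 30, 0, 255), 255.0 - x]
    grid = similarity_grid_map(x, batch, "mssim", grid_shape=(1, 3))
    assert grid.shape == (1, 3)
    assert grid[0, 0] == 1.0
    for k, img in enumerate(batch):
        assert grid[0, k] == compute_metric("mssim", x, img)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st_hyp.integers(min_value=0, max_value=10_000))
def test_mssim_bounded_above_by_one(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 256, size=(12, 12)).astype(float)
    y = rng.integers(0, 256, size=(12, 12)).astype(float)
    assert mssim(x, y).score <= 1.0 + 1e-12
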