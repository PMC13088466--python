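"""Otsu thresholding, root masking, grid partitioning, segment extraction."""

import numpy as np
import pytest

from rootspec import (
    InvalidInputError,
    SceneConfig,
    SpectralCube,
    build_optics,
    calibrate,
    coverage_percent,
    grow_architecture,
    mean_segment_spectrum,
    otsu_threshold,
    partition_grid,
    render_scene,
    root_mask_from_cube,
    trim_bands,
)
from rootspec.errors import SegmentationError
from rootspec.segmentation import extract_segments, segments_to_frame


def otsu_bruteforce(values: np.ndarray) -> tuple[float, float]:
    """Exhaustive search over the 255 interior bin edges of a 256-bin
    histogram, recomputing class statistics from the raw values."""
    x = np.asarray(values, dtype=float).ravel()
    edges = np.linspace(x.min(), x.max(), 257)
    best_t, best_v = None, -1.0
    for t in edges[1:-1]:
        lo = x[x < t]
        hi = x[x >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / x.size
        v = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-15:  # strictly better: ties keep the lowest edge
            best_v, best_t = v, t
    return best_t, best_v


def _between_class_variance(x, t):
    lo, hi = x[x < t], x[x >= t]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / x.size
    return w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self, rng):
        x = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        t = otsu_threshold(x)
        assert 0.2 < t <= 0.8

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError, match="constant"):
            otsu_threshold(np.full(100, 0.5))

    def test_equals_bruteforce_on_gaussian_mixture(self):
        """Stated two-Gaussian mixture: exhaustive search is the oracle."""
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.normal(0.25, 0.05, 600), rng.normal(0.7, 0.08, 400)]
        )
        t = otsu_threshold(x)
        t_oracle, v_oracle = otsu_bruteforce(x)
        assert _between_class_variance(x, t) == pytest.approx(v_oracle, rel=1e-10)
        assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_equals_bruteforce_on_100_random_instances(self):
        """Property: implementation matches the exhaustive oracle on every
        random instance (mixtures with random means, weights, spreads)."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n1 = int(rng.integers(20, 200))
            n2 = int(rng.integers(20, 200))
            x = np.concatenate([
                rng.normal(rng.uniform(0, 0.4), rng.uniform(0.02, 0.15), n1),
                rng.normal(rng.uniform(0.5, 1.0), rng.uniform(0.02, 0.15), n2),
            ])
            t = otsu_threshold(x)
            _, v_oracle = otsu_bruteforce(x)
            assert _between_class_variance(x, t) == pytest.approx(v_oracle, rel=1e-9)

    def test_agrees_with_skimage_to_a_bin(self):
        """Cross-check against an independent implementation (bin quantum)."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.3, 0.05, 500), rng.normal(0.75, 0.05, 500)])
        quantum = (x.max() - x.min()) / 256
        assert abs(otsu_threshold(x) - threshold_otsu(x, nbins=256)) <= 2 * quantum


class TestRootMask:
    def test_recovers_truth_mask_on_noiseless_scene(self):
        cfg = SceneConfig(
            image_size_px=(256, 256), field_cm=(12.5, 12.5), n_plants=2,
            noise_sd=0.0, scatter_gain_sd=0.0, scatter_offset_sd=0.0,
        )
        optics = build_optics(cfg.wavelengths_nm)
        from rootspec import grow_scene

        arch, _ = grow_scene(cfg, [0.8, 0.5], seed=13)
        raw = render_scene(arch, optics, cfg, seed=13)
        cube = trim_bands(calibrate(raw))
        mask = root_mask_from_cube(cube)
        agreement = (mask.mask == raw.truth_mask).mean()
        assert agreement >= 0.99

    def test_all_background_scene_reports_no_roots(self):
        cfg = SceneConfig(
            image_size_px=(64, 64), field_cm=(3.125, 3.125), n_plants=1,
            n_bands=30, noise_sd=0.0, scatter_gain_sd=0.0, scatter_offset_sd=0.0,
        )
        optics = build_optics(cfg.wavelengths_nm)
        raw = render_scene(grow_architecture(cfg, 0.0, seed=1), optics, cfg, seed=1)
        cube = calibrate(raw)
        with pytest.raises(SegmentationError, match="no roots"):
            root_mask_from_cube(cube)

    def test_mask_within_dilated_truth(self, small_scene):
        """Detected roots stay inside a small dilation of the true support."""
        from scipy.ndimage import binary_dilation

        raw, cube = small_scene
        mask = root_mask_from_cube(cube)
        dilated = binary_dilation(raw.truth_mask, iterations=2)
        assert np.all(dilated[mask.mask])


class TestPartitionGrid:
    def _cube(self, h=512, w=512):
        wl = np.linspace(450, 950, 10)
        return SpectralCube(np.zeros((h, w, 10), dtype=np.float32), wl, 25.0 / 512)

    def test_default_cell_size_matches_geometry(self):
        """5 x 2.5 cm at 20.48 px/cm rounds to 102 x 51 px."""
        grid = partition_grid(self._cube())
        assert grid.seg_height_px == 51 and grid.seg_width_px == 102
        assert grid.n_rows == 10 and grid.n_cols == 5

    def test_cell_counts_match_integer_division(self):
        cube = self._cube(500, 490)
        grid = partition_grid(cube)
        assert grid.n_rows == 500 // 51 and grid.n_cols == 490 // 102

    def test_origin_too_deep_yields_empty_grid_error(self):
        with pytest.raises(SegmentationError, match="empty grid"):
            partition_grid(self._cube(), origin=(500, 0))

    def test_cells_disjoint_and_in_bounds(self):
        grid = partition_grid(self._cube())
        seen = np.zeros((512, 512), dtype=int)
        for _, _, (r0, c0, r1, c1) in grid.cells():
            assert 0 <= r0 < r1 <= 512 and 0 <= c0 < c1 <= 512
            seen[r0:r1, c0:c1] += 1
        assert seen.max() == 1  # pairwise disjoint


class TestCoverage:
    def test_extremes(self):
        assert coverage_percent(np.ones((10, 10), bool), (0, 0, 10, 10)) == 100.0
        assert coverage_percent(np.zeros((10, 10), bool), (0, 0, 10, 10)) == 0.0

    def test_checkerboard_is_half(self):
        mask = np.indices((102, 51)).sum(axis=0) % 2 == 0
        cov = coverage_percent(mask, (0, 0, 102, 51))
        assert cov == pytest.approx(50.0, abs=100.0 / (102 * 51))

    def test_transpose_invariance(self, rng):
        mask = rng.random((40, 60)) > 0.6
        b = (5, 10, 25, 50)
        bt = (b[1], b[0], b[3], b[2])
        assert coverage_percent(mask, b) == coverage_percent(mask.T, bt)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(InvalidInputError):
            coverage_percent(np.ones((5, 5), bool), (0, 0, 6, 5))


class TestMeanSpectrum:
    def _cube(self, refl):
        wl = np.linspace(450, 950, refl.shape[2])
        return SpectralCube(refl, wl, 0.05)

    def test_uniform_spectrum_reproduced_exactly(self):
        s = np.array([0.1, 0.4, 0.7])
        cube = self._cube(np.tile(s, (6, 6, 1)))
        spec, fb = mean_segment_spectrum(cube, np.ones((6, 6), bool), (0, 0, 6, 6))
        np.testing.assert_allclose(spec, s, rtol=0, atol=1e-14)
        assert not fb

    def test_two_root_pixels_average(self):
        refl = np.zeros((2, 2, 3))
        s1, s2 = np.array([0.2, 0.4, 0.6]), np.array([0.4, 0.8, 1.0])
        refl[0, 0], refl[1, 1] = s1, s2
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[1, 1] = True
        spec, _ = mean_segment_spectrum(self._cube(refl), mask, (0, 0, 2, 2))
        np.testing.assert_allclose(spec, (s1 + s2) / 2)

    def test_matches_explicit_loop_oracle(self, rng):
        refl = rng.random((12, 14, 5))
        mask = rng.random((12, 14)) > 0.5
        bounds = (2, 3, 10, 12)
        spec, _ = mean_segment_spectrum(self._cube(refl), mask, bounds)
        acc, n = np.zeros(5), 0
        for i in range(bounds[0], bounds[2]):
            for j in range(bounds[1], bounds[3]):
                if mask[i, j]:
                    acc += refl[i, j]
                    n += 1
        np.testing.assert_allclose(spec, acc / n, atol=1e-12)

    def test_empty_segment_falls_back_with_flag(self):
        cube = self._cube(np.full((4, 4, 3), 0.3))
        spec, fb = mean_segment_spectrum(cube, np.zeros((4, 4), bool), (0, 0, 4, 4))
        assert fb
        np.testing.assert_allclose(spec, 0.3)

    def test_area_mean_blends_root_and_background(self):
        refl = np.zeros((2, 2, 1))
        refl[0, 0, 0] = 1.0  # one bright pixel among four
        spec, fb = mean_segment_spectrum(
            self._cube(np.tile(refl, (1, 1, 3))), np.zeros((2, 2), bool),
            (0, 0, 2, 2), pixels="all",
        )
        assert not fb
        np.testing.assert_allclose(spec, 0.25)


class TestExtractSegments:
    def test_frame_has_band_columns_and_truth(self, small_scene, small_config):
        raw, cube = small_scene
        grid = partition_grid(cube)
        mask = root_mask_from_cube(cube)
        from rootspec import truth_segment_weights

        truth = truth_segment_weights(raw.truth_density, grid)
        weights = {
            (int(r.grid_row), int(r.grid_col)): float(r.dry_weight_g)
            for r in truth.itertuples()
        }
        records = extract_segments(cube, mask, grid, truth_weights=weights)
        assert len(records) == grid.n_rows * grid.n_cols
        frame = segments_to_frame(records, cube.wavelengths_nm)
        wl_cols = [c for c in frame.columns if c.startswith("wl_")]
        assert len(wl_cols) == cube.wavelengths_nm.size
        assert frame["coverage_pct"].between(0, 100).all()
        # truth weights attached where the grid has them
        assert frame["dry_weight_g"].notna().all()
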