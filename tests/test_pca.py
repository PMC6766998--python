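"""Pixel-wise PCA, score images, and loading-based wavelength selection."""

import numpy as np
import pytest

import seedspectra as ss
from seedspectra.pca import _local_extrema
from seedspectra.spectra import SpectraTable


def table_from(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return SpectraTable(matrix=matrix,
                        wavelengths=np.linspace(942, 1646, matrix.shape[1]),
                        labels=np.zeros(matrix.shape[0], dtype=int))


def eig_oracle(X, n_components):
    """Brute-force PCA oracle: dense eigendecomposition of the sample
    covariance matrix, sorted by descending eigenvalue, with the same sign
    convention (largest-magnitude entry positive)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    frac = evals / evals.sum()
    return evecs[:, :n_components], frac[:n_components]


class TestFitPCA:
    def test_one_dimensional_data_explains_everything(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        direction = np.array([3.0, 4.0, 0.0]) / 5.0
        X = np.outer(t, direction)
        pca = ss.fit_pca(table_from(X), n_components=2)
        assert pca.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 6))
        pca = ss.fit_pca(table_from(X), n_components=6)
        loadings_o, frac_o = eig_oracle(X, 6)
        np.testing.assert_allclose(pca.loadings, loadings_o, atol=1e-8)
        np.testing.assert_allclose(pca.explained_fraction, frac_o, atol=1e-8)

    def test_duplicating_rows_changes_nothing(self):
        rng = np.random.default_rng(2)
        X = rng.random((15, 5))
        a = ss.fit_pca(table_from(X), n_components=4)
        b = ss.fit_pca(table_from(np.vstack([X, X])), n_components=4)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-9)
        np.testing.assert_allclose(a.explained_fraction, b.explained_fraction,
                                   atol=1e-9)

    def test_loadings_are_orthonormal(self):
        rng = np.random.default_rng(3)
        pca = ss.fit_pca(table_from(rng.random((30, 10))), n_components=8)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(4)
        pca = ss.fit_pca(table_from(rng.random((50, 12))), n_components=10)
        assert np.all(np.diff(pca.explained_fraction) <= 1e-12)

    def test_reconstruction_residual_matches_unexplained_variance(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 15))
        pca = ss.fit_pca(table_from(X), n_components=5)
        Xc = X - pca.mean_spectrum
        residual = Xc - pca.scores @ pca.loadings.T
        total_ss = (Xc ** 2).sum()
        expected = (1.0 - pca.explained_fraction.sum()) * total_ss
        assert np.linalg.norm(residual) ** 2 == pytest.approx(
            expected, rel=1e-6)

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        pca = ss.fit_pca(table_from(rng.random((25, 8))), n_components=6)
        for j in range(6):
            assert pca.loadings[np.argmax(np.abs(pca.loadings[:, j])), j] > 0

    def test_subsample_threshold_equal_to_n_rows_is_exact(self):
        rng = np.random.default_rng(7)
        X = rng.random((40, 6))
        full = ss.fit_pca(table_from(X), n_components=4, max_pixels=10**6)
        same = ss.fit_pca(table_from(X), n_components=4, max_pixels=40)
        np.testing.assert_array_equal(full.loadings, same.loadings)
        np.testing.assert_array_equal(full.scores, same.scores)

    def test_scores_computed_for_all_rows_under_subsampling(self):
        rng = np.random.default_rng(8)
        X = rng.random((500, 6))
        pca = ss.fit_pca(table_from(X), n_components=3, max_pixels=100,
                         rng_seed=0)
        assert pca.scores.shape == (500, 3)

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError):
            ss.fit_pca(table_from(np.ones((1, 5))), n_components=1)


class TestScoreImage:
    def make_scene_and_mask(self, profiles, classes):
        spec = ss.SceneSpec(image_shape=(80, 80), seeds_per_image=len(classes),
                            noise_sd_additive=0.005,
                            noise_sd_multiplicative=0.0, rng_seed=13)
        rs = ss.render_scene(spec, profiles, classes)
        scene = ss.correct_reflectance(rs.raw, rs.references)
        return rs, scene

    def test_classes_separate_along_pc1_with_projection_oracle(self):
        profiles = ss.make_variety_profiles(2, 200, 15, 0.08, rng_seed=3)
        rs, scene = self.make_scene_and_mask(profiles, [0, 1])
        mask = ss.SeedMask(rs.mask)
        table = ss.extract_pixel_spectra(scene, mask, list(rs.seed_classes))
        pca = ss.fit_pca(table, n_components=3)
        # projection oracle: mean PC1 score per class from direct projection
        proj = (table.matrix - pca.mean_spectrum) @ pca.loadings[:, 0]
        mean_a = proj[table.labels == 0].mean()
        mean_b = proj[table.labels == 1].mean()
        assert abs(mean_a - mean_b) > 0
        np.testing.assert_allclose(pca.scores[:, 0], proj, atol=1e-10)

    def test_constant_foreground_scores_are_zero(self):
        cube = np.full((20, 20, 6), 0.5)
        scene = ss.HyperspectralScene(cube, np.linspace(1000, 1500, 6),
                                      calibrated=True)
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1
        mask = ss.SeedMask(labels)
        table = ss.extract_pixel_spectra(scene, mask, [0])
        pca = ss.fit_pca(table, n_components=2)
        assert np.abs(pca.scores).max() <= 1e-12

    def test_rendering_is_deterministic(self):
        profiles = ss.make_variety_profiles(2, 200, 15, 0.08, rng_seed=3)
        rs, scene = self.make_scene_and_mask(profiles, [0, 1])
        mask = ss.SeedMask(rs.mask)
        table = ss.extract_pixel_spectra(scene, mask, list(rs.seed_classes))
        pca = ss.fit_pca(table, n_components=2)
        img1, pct1 = ss.score_image(pca, scene, mask, pc_index=0)
        img2, pct2 = ss.score_image(pca, scene, mask, pc_index=0)
        assert img1.tobytes() == img2.tobytes()
        assert pct1 == pct2
        assert img1.dtype == np.uint8 and img1.shape == (80, 80, 3)

    def test_empty_mask_raises(self):
        cube = np.full((8, 8, 4), 0.5)
        scene = ss.HyperspectralScene(cube, np.linspace(1000, 1400, 4),
                                      calibrated=True)
        table = SpectraTable(matrix=np.random.default_rng(0).random((10, 4)),
                             wavelengths=np.linspace(1000, 1400, 4),
                             labels=np.zeros(10, dtype=int))
        pca = ss.fit_pca(table, n_components=2)
        with pytest.raises(ValueError):
            ss.score_image(pca, scene, ss.SeedMask(np.zeros((8, 8), int)), 0)


def extremum_scan_oracle(values):
    """Exhaustive neighbor comparison for strict local maxima."""
    n = len(values)
    out = []
    for i in range(n):
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < n - 1 else -np.inf
        if values[i] > left and values[i] > right:
            out.append(i)
    return out


class TestWavelengthSelection:
    def make_pca_with_loadings(self, loadings, wavelengths=None):
        loadings = np.asarray(loadings, dtype=float)
        if wavelengths is None:
            wavelengths = np.linspace(942, 1646, loadings.shape[0])
        n_bands, n_pcs = loadings.shape
        return ss.PCAResult(
            mean_spectrum=np.zeros(n_bands),
            loadings=loadings,
            scores=np.zeros((2, n_pcs)),
            explained_fraction=np.linspace(0.5, 0.1, n_pcs),
            wavelengths=np.asarray(wavelengths),
        )

    def test_single_spike_selects_exactly_that_wavelength(self):
        loadings = np.zeros((50, 1))
        loadings[17, 0] = 0.9
        pca = self.make_pca_with_loadings(loadings)
        sel = ss.select_effective_wavelengths(pca, n_pcs=1, theta=0.5)
        assert sel.band_indices.tolist() == [17]
        assert sel.wavelengths[0] == pytest.approx(pca.wavelengths[17])
        assert sel.source_pcs[17] == [0]

    def test_tiny_theta_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(9)
        loadings = rng.normal(size=(80, 1))
        pca = self.make_pca_with_loadings(loadings)
        sel = ss.select_effective_wavelengths(pca, n_pcs=1, theta=1e-9)
        oracle = extremum_scan_oracle(np.abs(loadings[:, 0]))
        assert sel.band_indices.tolist() == oracle

    def test_union_over_pcs_records_sources(self):
        loadings = np.zeros((30, 2))
        loadings[5, 0] = 1.0
        loadings[5, 1] = 1.0
        loadings[20, 1] = 0.9
        pca = self.make_pca_with_loadings(loadings)
        sel = ss.select_effective_wavelengths(pca, n_pcs=2, theta=0.5)
        assert sel.band_indices.tolist() == [5, 20]
        assert sel.source_pcs[5] == [0, 1]
        assert sel.source_pcs[20] == [1]

    def test_selection_is_scale_equivariant(self, strong_table):
        a = ss.select_effective_wavelengths(
            ss.fit_pca(strong_table, n_components=10))
        scaled = strong_table.with_matrix(strong_table.matrix * 7.5)
        b = ss.select_effective_wavelengths(
            ss.fit_pca(scaled, n_components=10))
        assert a.band_indices.tolist() == b.band_indices.tolist()

    def test_invalid_theta_raises(self, strong_table):
        pca = ss.fit_pca(strong_table, n_components=3)
        for theta in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                ss.select_effective_wavelengths(pca, n_pcs=3, theta=theta)

    def test_planted_band_recovery_single_run(self):
        """Planted discriminative bands dominate the loading extrema when
        the deviation is large against noise."""
        profiles = ss.make_variety_profiles(7, 200, 10, 0.05, rng_seed=17)
        table = ss.make_labeled_spectra(profiles, 150, 0.01, rng_seed=17)
        pca = ss.fit_pca(table, n_components=10)
        sel = ss.select_effective_wavelengths(pca, n_pcs=10, theta=0.5)
        planted = set().union(*(p.discriminative_bands for p in profiles))
        recovered = len(planted & set(sel.band_indices.tolist())) / len(planted)
        assert recovered >= 0.8

    def test_interior_extrema_line_up_with_wavelengths(self):
        rng = np.random.default_rng(10)
        loadings = rng.normal(size=(40, 3))
        pca = self.make_pca_with_loadings(loadings)
        sel = ss.select_effective_wavelengths(pca, n_pcs=3, theta=0.3)
        np.testing.assert_array_equal(sel.wavelengths,
                                      pca.wavelengths[sel.band_indices])
        assert np.all(np.diff(sel.wavelengths) > 0)


def test_local_extrema_edge_cases():
    assert _local_extrema(np.array([1.0])).tolist() == [0]
    assert _local_extrema(np.array([2.0, 1.0])).tolist() == [0]
    assert _local_extrema(np.array([1.0, 2.0])).tolist() == [1]
    assert _local_extrema(np.array([1.0, 1.0])).tolist() == []
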