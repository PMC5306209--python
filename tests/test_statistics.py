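"""PCA atlas, mode selection and discriminant shape modes."""

import numpy as np
import pytest

from atriashape import make_sphere_template, mesh_to_vector, vector_to_mesh
from atriashape.statistics import (
    build_ilda,
    build_olda,
    build_pca,
    fisher_lda,
    group_mean_shape,
    mode_marker_correlation,
    node_reconstruction_error,
    reconstruct,
    select_num_modes,
    synthesize_extreme_shapes,
)


class TestPCA:
    def test_two_subjects_single_difference_mode(self, rng):
        a = rng.normal(size=120)
        b = rng.normal(size=120)
        pca = build_pca([a, b])
        assert pca.n_modes == 1
        diff = (b - a) / np.linalg.norm(b - a)
        assert abs(abs(pca.modes[0] @ diff) - 1) < 1e-10

    def test_cohort_of_144_gives_143_modes(self, rng):
        X = rng.normal(size=(144, 1608))
        pca = build_pca(X)
        assert pca.n_modes == 143
        assert pca.explained_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(pca.explained_fraction) <= 1e-12)

    def test_modes_orthonormal(self, rng):
        pca = build_pca(rng.normal(size=(30, 100)))
        G = pca.modes @ pca.modes.T
        np.testing.assert_allclose(G, np.eye(pca.n_modes), atol=1e-8)

    def test_full_reconstruction_exact(self, rng):
        X = rng.normal(size=(15, 80))
        pca = build_pca(X)
        for i in range(15):
            np.testing.assert_allclose(
                reconstruct(pca, i, pca.n_modes), X[i], atol=1e-8
            )

    def test_zero_modes_gives_mean(self, rng):
        X = rng.normal(size=(10, 50))
        pca = build_pca(X)
        np.testing.assert_allclose(reconstruct(pca, 3, 0), X.mean(axis=0))

    def test_matches_sklearn_pca(self, rng):
        """Independent cross-check against scikit-learn's PCA."""
        from sklearn.decomposition import PCA as SkPCA

        X = rng.normal(size=(25, 40)) * np.linspace(3, 0.5, 40)
        ours = build_pca(X)
        ref = SkPCA().fit(X)
        np.testing.assert_allclose(
            ours.explained_fraction[:10],
            ref.explained_variance_ratio_[:10], atol=1e-10
        )
        for k in range(5):
            assert abs(ours.modes[k] @ ref.components_[k]) == pytest.approx(1.0, abs=1e-8)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            build_pca(rng.normal(size=(1, 10)))


class TestReconstructionError:
    def test_identical_meshes_zero(self, template):
        assert node_reconstruction_error(template, template) == 0.0

    def test_uniform_shift_one_mm(self, template):
        shifted = template.transformed(translation=(0, 0, 1.0))
        assert node_reconstruction_error(template, shifted) == pytest.approx(1.0)

    def test_gaussian_perturbation_matches_chi3_mean(self, template, rng):
        # E||N(0, s^2 I_3)|| = s * 2 * sqrt(2/pi)
        sigma = 0.7
        other = template.copy()
        other.positions = other.positions + rng.normal(0, sigma, (134, 3))
        expected = sigma * 2 * np.sqrt(2 / np.pi)
        err = node_reconstruction_error(template, other)
        assert err == pytest.approx(expected, rel=0.15)

    def test_full_dof_residual_non_increasing_in_k(self, template, rng):
        """Orthogonality: the residual norm shrinks with every added mode."""
        base = mesh_to_vector(template)
        X = np.array([base + rng.normal(0, 1.0, base.size) for _ in range(12)])
        pca = build_pca(X)
        for i in range(len(X)):
            errs = [
                np.linalg.norm(X[i] - reconstruct(pca, i, k))
                for k in range(0, pca.n_modes + 1)
            ]
            assert all(b <= a + 1e-10 for a, b in zip(errs, errs[1:]))

    def test_cohort_mean_node_error_non_increasing(self, small_cohort):
        """On a structured cohort the position-only error is also monotone."""
        from atriashape.statistics import meshes_to_vectors, _vector_node_error

        X = meshes_to_vectors(small_cohort.meshes)
        pca = build_pca(X)
        means = []
        for k in range(1, 13):
            means.append(np.mean([
                _vector_node_error(X[i], reconstruct(pca, i, k))
                for i in range(len(X))
            ]))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))


class TestModeSelection:
    def test_planted_rank_three_recovered(self, template, rng):
        base = mesh_to_vector(template)
        d = base.size
        dirs = np.linalg.qr(rng.normal(size=(d, 3)))[0].T
        sds = np.array([120.0, 72.0, 48.0])
        X = np.array([
            base
            + (rng.normal(0, 1, 3) * sds) @ dirs
            + rng.normal(0, 0.003, d)
            for _ in range(40)
        ])
        pca = build_pca(X)
        assert select_num_modes(pca, X, threshold=1.0) == 3

    def test_loose_threshold_gives_one_mode(self, template, rng):
        base = mesh_to_vector(template)
        X = np.array([base + rng.normal(0, 0.5, base.size) for _ in range(10)])
        pca = build_pca(X)
        assert select_num_modes(pca, X, threshold=1e6) == 1

    def test_unreachable_threshold_warns(self, template, rng):
        base = mesh_to_vector(template)
        X = np.array([base + rng.normal(0, 5.0, base.size) for _ in range(5)])
        pca = build_pca(X)
        with pytest.warns(UserWarning):
            k = select_num_modes(pca, X, threshold=1e-15)
        assert k == pca.n_modes


class TestFisherLDA:
    def test_recovers_separation_axis(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 0.5).astype(int)
        X[y == 1, 0] += 3.0
        w, _ = fisher_lda(X, y)
        angle = np.degrees(np.arccos(abs(w[0])))
        assert angle < 5.0

    def test_matches_closed_form_oracle(self, rng):
        # w proportional to Sigma^-1 (mu1 - mu0) for shared covariance
        n = 4000
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        X = rng.multivariate_normal(np.zeros(3), cov, size=n)
        y = (rng.random(n) < 0.5).astype(int)
        delta = np.array([1.0, -0.5, 2.0])
        X[y == 1] += delta
        w, _ = fisher_lda(X, y)
        oracle = np.linalg.solve(cov, delta)
        oracle /= np.linalg.norm(oracle)
        assert abs(w @ oracle) > 0.99

    def test_beats_random_direction_search(self, rng):
        """No random direction achieves a better Fisher ratio."""
        n, d = 50, 3
        X = rng.normal(size=(n, d))
        y = (np.arange(n) % 2).astype(int)
        X[y == 1, 1] += 1.5
        w, _ = fisher_lda(X, y)

        def fisher_ratio(v):
            s = X @ v
            s0, s1 = s[y == 0], s[y == 1]
            between = (s1.mean() - s0.mean()) ** 2
            within = s0.var(ddof=1) * (len(s0) - 1) + s1.var(ddof=1) * (len(s1) - 1)
            return between / within

        best = fisher_ratio(w)
        dirs = rng.normal(size=(10_000, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        rand_best = max(fisher_ratio(v) for v in dirs)
        assert rand_best <= best + 1e-6

    def test_1d_reduces_to_sign(self, rng):
        x = rng.normal(size=40)
        y = (x + rng.normal(0, 0.1, 40) > 0).astype(int)
        w, s = fisher_lda(x[:, None], y)
        assert abs(abs(w[0]) - 1) < 1e-12
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_direction_matches_sklearn_lda(self, rng):
        """Independent cross-check: scikit-learn's LDA coef_ is parallel."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(80, 4))
        y = (rng.random(80) < 0.5).astype(int)
        X[y == 1] += [1.0, 0.3, -0.5, 0.0]
        w, _ = fisher_lda(X, y)
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).coef_[0]
        cos = abs(w @ ref) / np.linalg.norm(ref)
        assert cos > 0.999

    def test_identical_means_warns(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            fisher_lda(X, y)


def _planted_pca(rng, n=120, d=60, k=6, signal_modes=(0, 2), delta=1.8):
    """PCAModel + labels where only `signal_modes` separate the classes.

    Returns (pca, labels, expected_shape_direction): the population Fisher
    direction mapped to shape space (within-class covariance is diagonal
    in the planted basis, so it is the planted signal combination).
    """
    y = (rng.random(n) < 0.5).astype(int)
    scales = np.linspace(5, 1, k)
    scores = rng.normal(size=(n, k)) * scales
    w_star = np.zeros(k)
    for m in signal_modes:
        scores[y == 1, m] += delta * scales[m] / 2
        w_star[m] = (delta * scales[m] / 2) / scales[m] ** 2
    dirs = np.linalg.qr(rng.normal(size=(d, k)))[0].T
    X = scores @ dirs + rng.normal(0, 0.01, (n, d))
    expected = w_star @ dirs
    nrm = np.linalg.norm(expected)
    if nrm > 0:
        expected = expected / nrm
    return build_pca(X), y, expected


class TestDiscriminantModes:
    def test_ilda_recovers_planted_direction(self, rng):
        pca, y, expected = _planted_pca(rng, n=400, signal_modes=(1,), delta=3.0)
        mode = build_ilda(pca, y, k_selected=6)
        cos = abs(mode.direction_shape @ expected) / np.linalg.norm(mode.direction_shape)
        assert cos > 0.85

    def test_ilda_null_labels_chance_auc(self, rng):
        from atriashape.classify import loo_cv

        pca, _, _ = _planted_pca(rng, signal_modes=(), delta=0.0)
        y = (rng.random(pca.n_subjects) < 0.5).astype(int)
        cv = loo_cv(pca.scores[:, :6], y)
        assert 0.35 < cv.loo_auc < 0.65

    def test_olda_subset_counts(self, rng):
        pca, y, _ = _planted_pca(rng, n=40, k=8)
        mode = build_olda(pca, y, k_selected=8, min_subset=2)
        assert len(mode.search_log) == 247
        mode1 = build_olda(pca, y, k_selected=8, min_subset=1)
        assert len(mode1.search_log) == 255

    def test_olda_winner_maximises_logged_auc(self, rng):
        pca, y, _ = _planted_pca(rng, n=60, k=5)
        mode = build_olda(pca, y, k_selected=5)
        best_logged = max(e["loo_auc"] for e in mode.search_log)
        winner = next(
            e for e in mode.search_log if tuple(e["subset"]) == tuple(mode.subspace_ids)
        )
        assert winner["loo_auc"] == best_logged

    def test_olda_recovers_planted_modes(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            pca, y, _ = _planted_pca(rng, n=150, signal_modes=(0, 2), delta=2.2)
            mode = build_olda(pca, y, k_selected=6)
            hits += {0, 2} <= set(mode.subspace_ids)
        assert hits >= 4  # planted pair found in >= 90% nominally; allow one miss

    def test_extreme_shapes_mirror_about_mean(self, rng):
        pca, y, _ = _planted_pca(rng)
        mode = build_ilda(pca, y, 6)
        hi, lo = synthesize_extreme_shapes(pca, mode, n_sd=2)
        np.testing.assert_allclose(pca.mean_shape - lo, hi - pca.mean_shape, atol=1e-9)
        zero_hi, zero_lo = synthesize_extreme_shapes(pca, mode, n_sd=0)
        np.testing.assert_allclose(zero_hi, pca.mean_shape)
        np.testing.assert_allclose(zero_lo, pca.mean_shape)

    def test_extreme_shape_projects_to_n_sd(self, rng):
        pca, y, _ = _planted_pca(rng)
        mode = build_ilda(pca, y, 6)
        hi, _ = synthesize_extreme_shapes(pca, mode, n_sd=2)
        # project back onto the discriminant direction in PCA space
        coords = (hi - pca.mean_shape) @ pca.modes[:6].T
        proj = coords @ mode.direction_pca
        sd = mode.subject_scores.std(ddof=0)
        assert proj == pytest.approx(2 * sd, rel=1e-6)


class TestGroupMeansAndCorrelation:
    def test_group_mean_trivials(self, rng):
        X = rng.normal(size=(6, 20))
        y = np.array([0, 0, 1, 1, 1, 0])
        np.testing.assert_allclose(
            group_mean_shape(X, y, 1), X[y == 1].mean(axis=0)
        )
        grand = X.mean(axis=0)
        weighted = (3 * group_mean_shape(X, y, 0) + 3 * group_mean_shape(X, y, 1)) / 6
        np.testing.assert_allclose(grand, weighted)
        with pytest.raises(ValueError):
            group_mean_shape(X, y, 7)

    def test_marker_equal_to_mode_score(self, rng):
        pca = build_pca(rng.normal(size=(50, 30)))
        rho = mode_marker_correlation(pca, pca.scores[:, 0])
        assert abs(rho[0]) == pytest.approx(1.0, abs=1e-10)

    def test_independent_marker_low_correlation(self, rng):
        pca = build_pca(rng.normal(size=(144, 60)))
        rho = mode_marker_correlation(pca, rng.normal(size=144))
        assert np.abs(rho).max() < 0.35

    def test_zero_variance_marker_rejected(self, rng):
        pca = build_pca(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError):
            mode_marker_correlation(pca, np.ones(10))
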