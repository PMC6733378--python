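import numpy as np
import pytest

import hipshape as hs
from conftest import random_similarity
from hipshape.shape_model import project_population


def _aligned(coords):
    """Wrap raw coordinate vectors as aligned shapes for model building."""
    return [hs.AlignedShape(f"s{i}", np.asarray(c, float), 0.0)
            for i, c in enumerate(coords)]


class TestBuildSsm:
    def test_single_axis_variation_gives_one_mode(self):
        mean = np.arange(8.0)
        e = np.zeros(8)
        e[3] = 1.0
        shapes = _aligned([mean + 0.5 * e, mean - 0.5 * e,
                           mean + 0.25 * e, mean - 0.25 * e])
        model = hs.build_ssm(shapes)
        assert model.n_modes == 1
        assert model.variance_fraction[0] == pytest.approx(1.0)
        assert abs(model.eigenvectors[0] @ e) == pytest.approx(1.0)

    def test_model_invariants(self, fitted_model):
        _, _, model = fitted_model
        G = model.eigenvectors @ model.eigenvectors.T
        assert np.allclose(G, np.eye(model.n_modes), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= 0)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(model.score_sds ** 2, model.eigenvalues,
                           rtol=1e-6)

    def test_deterministic_sign_convention(self, fitted_model):
        _, _, model = fitted_model
        for vec in model.eigenvectors:
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_matches_sklearn_pca(self, fitted_model):
        """Cross-check eigenvalues/components against an independent PCA."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        _, aligned, model = fitted_model
        X = np.vstack([a.coords for a in aligned])
        pca = sklearn.PCA(n_components=10).fit(X)
        assert np.allclose(pca.explained_variance_,
                           model.eigenvalues[:10], rtol=1e-8)
        for comp, vec in zip(pca.components_, model.eigenvectors[:10]):
            assert abs(comp @ vec) == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_rejected(self):
        shapes = _aligned([np.arange(6.0)] * 4)
        with pytest.raises(ValueError, match="variance"):
            hs.build_ssm(shapes)

    def test_needs_two_shapes(self):
        with pytest.raises(ValueError):
            hs.build_ssm(_aligned([np.arange(6.0)]))


class TestScores:
    def test_training_scores_standardized(self, fitted_model):
        _, aligned, model = fitted_model
        S = np.vstack([s.scores for s in hs.score_training(model, aligned)])
        assert np.abs(S.mean(axis=0)).max() < 1e-8
        assert np.abs(S.std(axis=0, ddof=1) - 1.0).max() < 1e-8

    def test_mean_shape_scores_zero(self, fitted_model):
        _, _, model = fitted_model
        (s,) = hs.score_training(
            model, _aligned([model.mean]))
        assert np.allclose(s.scores, 0.0, atol=1e-10)

    def test_constructed_two_sd_shape(self, fitted_model):
        _, _, model = fitted_model
        shape = model.mean + 2.0 * model.score_sds[0] * model.eigenvectors[0]
        (s,) = hs.score_training(model, _aligned([shape]))
        assert s.scores[0] == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(s.scores[1:], 0.0, atol=1e-8)

    def test_dimension_mismatch_rejected(self, fitted_model):
        _, _, model = fitted_model
        with pytest.raises(ValueError, match="dimension"):
            hs.score_training(model, _aligned([np.zeros(10)]))


class TestProject:
    def test_reproduces_training_scores(self, fitted_model):
        _, aligned, model = fitted_model
        training = hs.score_training(model, aligned)
        for a, t in zip(aligned[:100], training[:100]):
            p = hs.project(model, hs.LandmarkConfiguration(a.image_id,
                                                           a.points))
            assert np.allclose(p.scores, t.scores, atol=1e-8)

    def test_similarity_invariance_of_scores(self, fitted_model, rng):
        _, aligned, model = fitted_model
        base = aligned[0].points
        ref = hs.project(model, hs.LandmarkConfiguration("x", base)).scores
        for _ in range(8):
            moved = random_similarity(rng, base)
            got = hs.project(model, hs.LandmarkConfiguration("x", moved))
            assert np.allclose(got.scores, ref, atol=1e-8)

    def test_shifted_population_displaces_first_mode_mean(
            self, template58, ground_truth, fitted_model):
        """An external population offset along mode 1 projects to a
        displaced mode-1 mean while other mode means stay near zero."""
        template, base = template58
        _, _, model = fitted_model
        model = hs.truncate(model, 3)
        spec = hs.SyntheticPopulationSpec(
            n_images=200, marking_noise_sd=0.1, seed=55, template=template)
        # same generative modes, but score distribution shifted by +1.5 SD
        # on mode 1 only
        shift = 1.5 * ground_truth.true_mode_sds[0] \
            * ground_truth.true_modes[0].reshape(58, 2)
        configs, _ = hs.simulate_population(ground_truth, spec)

        def score_means(offset):
            reduced = [hs.apply_template_exclusions(
                hs.LandmarkConfiguration(c.image_id, c.points + offset),
                template) for c in configs]
            S = np.vstack([s.scores
                           for s in project_population(model, reduced)])
            return S.mean(axis=0)

        delta = score_means(shift) - score_means(0.0)
        assert abs(delta[0]) > 1.0
        assert np.abs(delta[1:]).max() < 0.35

    def test_homogeneous_population_has_small_sds(
            self, template58, ground_truth, fitted_model):
        """A narrow single-scanner-like population projects with SDs < 1."""
        template, _ = template58
        _, _, model = fitted_model
        model = hs.truncate(model, 3)
        spec = hs.SyntheticPopulationSpec(
            n_images=150, marking_noise_sd=0.05, seed=77, template=template)
        gt_narrow = hs.GroundTruthModel(
            ground_truth.base_shape, ground_truth.true_modes,
            0.3 * ground_truth.true_mode_sds)
        configs, _ = hs.simulate_population(gt_narrow, spec)
        reduced = [hs.apply_template_exclusions(c, template)
                   for c in configs]
        S = np.vstack([s.scores
                       for s in project_population(model, reduced)])
        assert np.all(S.std(axis=0, ddof=1) < 1.0)

    def test_wrong_point_count_rejected(self, fitted_model):
        _, _, model = fitted_model
        with pytest.raises(ValueError, match="points"):
            hs.project(model, np.zeros((10, 2)) + np.arange(10)[:, None])


class TestReconstruct:
    def test_zero_sd_gives_mean(self, fitted_model):
        _, _, model = fitted_model
        assert np.allclose(hs.reconstruct(model, 0, 0.0),
                           model.mean.reshape(-1, 2))

    def test_plus_minus_reflection_about_mean(self, fitted_model):
        _, _, model = fitted_model
        plus = hs.reconstruct(model, 1, 2.0)
        minus = hs.reconstruct(model, 1, -2.0)
        assert np.allclose((plus + minus) / 2.0, model.mean.reshape(-1, 2),
                           atol=1e-12)

    def test_score_training_round_trip_is_exact(self, fitted_model):
        """Scoring a reconstruction without re-normalization is the exact
        linear inverse: score k on mode m, zero elsewhere."""
        _, _, model = fitted_model
        for m in range(3):
            recon = hs.reconstruct(model, m, 2.0).reshape(-1)
            (s,) = hs.score_training(
                model, [hs.AlignedShape("r", recon, 0.0)])
            expected = np.zeros(model.n_modes)
            expected[m] = 2.0
            assert np.allclose(s.scores, expected, atol=1e-8)

    def test_project_round_trip_on_leading_modes(self, fitted_model):
        """Projecting a reconstruction recovers its scores up to the
        curvature of unit-size shape space (the reconstruction does not
        sit exactly on the unit sphere), so the tolerance is loose."""
        _, _, model = fitted_model
        lead = hs.truncate(model, 3)
        for m in range(3):
            scores = hs.project(lead, hs.reconstruct(lead, m, 2.0)).scores
            expected = np.zeros(3)
            expected[m] = 2.0
            assert np.allclose(scores, expected, atol=0.01)

    def test_out_of_range_mode_rejected(self, fitted_model):
        _, _, model = fitted_model
        with pytest.raises(IndexError):
            hs.reconstruct(model, model.n_modes, 1.0)


class TestVarianceAndTruncation:
    def test_variance_explained_bounds(self, fitted_model):
        _, _, model = fitted_model
        assert hs.variance_explained(model, 0) == 0.0
        assert hs.variance_explained(model, model.n_modes) \
            == pytest.approx(1.0, abs=1e-8)
        cum = [hs.variance_explained(model, m)
               for m in range(model.n_modes + 1)]
        assert np.all(np.diff(cum) >= 0)

    def test_truncate_to_full_is_identity(self, fitted_model):
        _, _, model = fitted_model
        same = hs.truncate(model, model.n_modes)
        assert np.array_equal(same.eigenvectors, model.eigenvectors)

    def test_truncated_model_projects_ten_scores(self, fitted_model):
        _, aligned, model = fitted_model
        ten = hs.truncate(model, 10)
        p = hs.project(ten, hs.LandmarkConfiguration("x",
                                                     aligned[0].points))
        assert p.scores.shape == (10,)
        for m in range(1, 11):
            assert hs.variance_explained(ten, m) == pytest.approx(
                hs.variance_explained(model, m))

    def test_invalid_truncation_rejected(self, fitted_model):
        _, _, model = fitted_model
        with pytest.raises(ValueError):
            hs.truncate(model, 0)


class TestCompleteness:
    def test_full_basis_reconstructs_training_shapes(self, fitted_model):
        """With every positive-eigenvalue mode kept, each training shape
        is exactly mean + sum of its scored mode displacements."""
        _, aligned, _ = fitted_model
        model = hs.build_ssm(aligned, eig_rtol=0.0)
        scores = hs.score_training(model, aligned)
        for s, a in zip(scores[:50], aligned[:50]):
            recon = model.mean \
                + (s.scores * model.score_sds) @ model.eigenvectors
            assert np.abs(recon - a.coords).max() < 1e-8
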