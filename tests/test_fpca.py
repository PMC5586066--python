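"""Functional PCA: recovery, projection, modes of variation, dominant angles."""

import numpy as np
import pytest

from mammospat.errors import (
    DegenerateDataError,
    IncompatibleGridError,
    InsufficientDataError,
)
from mammospat.fpca import dominant_angles, fit_fpca, mode_of_variation, project
from mammospat.phantom import generate_curves


def orthonormal_basis(g=180):
    grid = np.arange(g) * (360.0 / g)
    phi1 = np.cos(np.radians(grid))
    phi2 = np.sin(2 * np.radians(grid))
    phi1 /= np.linalg.norm(phi1)
    phi2 /= np.linalg.norm(phi2)
    return grid, phi1, phi2


@pytest.fixture(scope="module")
def noise_free_sample():
    grid, phi1, phi2 = orthonormal_basis()
    mu = 3.0 + np.sin(np.radians(grid))
    sample = generate_curves(80, grid, mu, [phi1, phi2], [4.0, 1.0], noise_sd=0.0, seed=0)
    return grid, mu, phi1, phi2, sample


class TestFitRecovery:
    def test_eigenfunction_recovery_noise_free(self):
        # single-component fixture: the centred curves span exactly phi_1,
        # so the leading empirical eigenfunction recovers it up to sign
        grid, phi1, _ = orthonormal_basis()
        mu = 3.0 + np.sin(np.radians(grid))
        sample = generate_curves(40, grid, mu, [phi1], [4.0], noise_sd=0.0, seed=0)
        model = fit_fpca(sample.curves, grid)
        err1 = min(
            np.max(np.abs(model.eigenfunctions[0] - phi1)),
            np.max(np.abs(model.eigenfunctions[0] + phi1)),
        )
        assert err1 < 1e-8
        assert np.max(np.abs(model.mean_fn - sample.curves.mean(axis=0))) < 1e-12

    def test_two_component_span_recovery_noise_free(self, noise_free_sample):
        # with two components the empirical basis is a rotation within the
        # true span; the span itself is recovered exactly
        grid, mu, phi1, phi2, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid, variance_threshold=1.0)
        span = model.eigenfunctions[:2]
        for phi in (phi1, phi2):
            resid = phi - span.T @ (span @ phi)
            assert np.max(np.abs(resid)) < 1e-8

    def test_eigenvalues_within_20pct_at_n500(self):
        grid, phi1, phi2 = orthonormal_basis(90)
        sample = generate_curves(
            500, grid, np.zeros(90), [phi1, phi2], [4.0, 1.0], noise_sd=0.05, seed=1
        )
        model = fit_fpca(sample.curves, grid)
        assert abs(model.eigenvalues[0] - 4.0) / 4.0 < 0.2
        assert abs(model.eigenvalues[1] - 1.0) / 1.0 < 0.2

    def test_eigenvalue_ordering_and_orthonormality(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        gram = model.eigenfunctions[: model.K] @ model.eigenfunctions[: model.K].T
        assert np.allclose(gram, np.eye(model.K), atol=1e-8)

    def test_variance_threshold_rule(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        cum = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
        assert cum[model.K - 1] >= model.variance_threshold
        assert model.K == 1 or cum[model.K - 2] < model.variance_threshold

    def test_threshold_one_keeps_all_nonzero_components(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid, variance_threshold=1.0)
        assert model.K == model.eigenvalues.size

    def test_standardised_scores_zero_mean_unit_variance(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(model.scores.var(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_eigenvalues_match_explicit_covariance(self):
        rng = np.random.default_rng(5)
        curves = rng.random((12, 30))
        model = fit_fpca(curves, variance_threshold=1.0)
        cov = np.cov(curves, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = model.eigenvalues.size
        assert np.allclose(model.eigenvalues, expected[:k], atol=1e-10)

    def test_reconstruction_residual_bounded(self):
        rng = np.random.default_rng(6)
        curves = rng.random((40, 60))
        model = fit_fpca(curves, variance_threshold=0.85)
        raw = (curves - model.mean_fn) @ model.eigenfunctions[: model.K].T
        recon = model.mean_fn + raw @ model.eigenfunctions[: model.K]
        resid_var = np.mean(np.sum((curves - recon) ** 2, axis=1))
        total_var = np.trace(np.cov(curves, rowvar=False, ddof=1))
        assert resid_var <= (1 - 0.85) * total_var * (40 / 39) + 1e-9

    def test_constant_shift_family_gives_flat_first_component(self):
        rng = np.random.default_rng(7)
        base = np.sin(np.radians(np.arange(72) * 5.0))
        curves = base[None, :] + rng.normal(0, 2.0, size=(50, 1))
        model = fit_fpca(curves)
        phi = model.eigenfunctions[0]
        assert np.max(np.abs(phi - phi.mean())) < 1e-8

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_fpca(np.zeros((1, 10)))
        with pytest.raises(DegenerateDataError):
            fit_fpca(np.ones((5, 10)))


class TestProject:
    def test_training_scores_reproduced(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        again = project(model, sample.curves)
        assert np.allclose(again, model.scores, atol=1e-10)

    def test_mean_curve_projects_to_zero(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        raw = project(model, model.mean_fn[None, :], standardise=False)
        assert np.allclose(raw, 0.0, atol=1e-10)

    def test_unit_component_curve_scores_sqrt_lambda(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        curve = model.mean_fn + np.sqrt(model.eigenvalues[0]) * model.eigenfunctions[0]
        raw = project(model, curve[None, :], standardise=False)[0]
        assert raw[0] == pytest.approx(np.sqrt(model.eigenvalues[0]))
        assert np.allclose(raw[1:], 0.0, atol=1e-10)

    def test_grid_mismatch_rejected(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        with pytest.raises(IncompatibleGridError):
            project(model, np.zeros((2, 17)))


class TestModesOfVariation:
    def test_alpha_zero_is_mean(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        mov = mode_of_variation(model, 1, 0.0)
        assert np.array_equal(mov.plus, model.mean_fn)
        assert np.array_equal(mov.minus, model.mean_fn)

    def test_plus_minus_reflect_about_mean(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        mov = mode_of_variation(model, 1, 1.0)
        assert np.allclose(mov.plus + mov.minus, 2 * model.mean_fn, atol=1e-12)

    def test_direct_formula_at_alpha_two(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        mov = mode_of_variation(model, 1, 2.0)
        expected = model.mean_fn + 2.0 * np.sqrt(model.eigenvalues[0]) * model.eigenfunctions[0]
        assert np.allclose(mov.plus, expected, atol=1e-12)

    def test_out_of_range_component(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        with pytest.raises(IndexError):
            mode_of_variation(model, model.K + 1, 1.0)


class TestDominantAngles:
    @staticmethod
    def _model_with_phi(phi):
        """Wrap a hand-built eigenfunction in a minimal model."""
        from mammospat.fpca import FPCModel

        g = phi.size
        return FPCModel(
            grid=np.arange(g) * (360.0 / g),
            mean_fn=np.zeros(g),
            eigenfunctions=phi[None, :] / np.linalg.norm(phi),
            eigenvalues=np.array([1.0]),
            K=1,
            variance_threshold=0.85,
            scores=np.zeros((2, 1)),
            score_mean=np.zeros(1),
            score_sd=np.ones(1),
        )

    def test_pure_cosine_single_peak(self):
        grid = np.arange(180) * 2.0
        phi = np.cos(np.radians(grid - 100.0))
        model = self._model_with_phi(phi)
        angles = dominant_angles(model, 1, top_m=1)
        # |cos| peaks at 100 and 280; the single largest local max is returned
        assert angles[0][0] in (100.0, 280.0)

    def test_three_bump_fixture(self):
        grid = np.arange(180) * 2.0
        phi = np.zeros(180)
        for centre, sign, height in ((54, 1, 1.0), (152, -1, 0.8), (268, 1, 0.9)):
            phi += sign * height * np.exp(-0.5 * ((grid - centre) / 8.0) ** 2)
        model = self._model_with_phi(phi)
        got = dominant_angles(model, 1, top_m=3)
        assert sorted(a for a, _ in got) == [54.0, 152.0, 268.0]
        signs = {a: s for a, s in got}
        assert signs[54.0] == 1 and signs[152.0] == -1 and signs[268.0] == 1

    def test_angles_are_grid_members(self, noise_free_sample):
        grid, *_, sample = noise_free_sample
        model = fit_fpca(sample.curves, grid)
        for a, _ in dominant_angles(model, 1, top_m=3):
            assert a in grid
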