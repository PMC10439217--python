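"""SEM core: model algebra, DWLS estimation, fit indices, smoothing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsemkit.covariance import GeneticCovariance
from gsemkit.sem import (
    FREE,
    ModelSpec,
    count_free_parameters,
    fit_dwls,
    free_parameter_names,
    implied_sigma,
    model_df,
    smooth_to_pd,
)
from gsemkit.simulate import fixture_gc, make_sv_fixture
from gsemkit.vech import vech


def one_factor_spec(n_items=3, name="F1"):
    items = [f"x{i}" for i in range(n_items)]
    return ModelSpec(
        name=f"one_factor_{n_items}",
        items=items,
        factors=["F"],
        loadings={(it, "F"): FREE for it in items},
    )


class TestModelAlgebra:
    def test_free_parameter_count(self):
        spec = one_factor_spec(4)
        assert count_free_parameters(spec) == 8
        assert model_df(spec) == 2

    def test_saturated_model_has_zero_df(self):
        # 3 items, 3 loadings + 3 residuals + ... a 3-item one-factor model is
        # exactly saturated: 6 free parameters = 6 unique moments
        spec = one_factor_spec(3)
        assert model_df(spec) == 0

    def test_under_identified_raises(self):
        items = ["x0", "x1"]
        spec = ModelSpec(
            name="u", items=items, factors=["F", "G"],
            loadings={(it, f): FREE for it in items for f in ("F", "G")},
            factor_cov={("G", "F"): FREE},
        )
        with pytest.raises(ValueError, match="under-identified"):
            model_df(spec)

    def test_free_factor_variance_rejected(self):
        with pytest.raises(ValueError, match="fixed"):
            ModelSpec(
                name="bad", items=["x0"], factors=["F"],
                loadings={("x0", "F"): FREE}, factor_cov={("F", "F"): FREE},
            )

    def test_item_without_loading_rejected(self):
        with pytest.raises(ValueError, match="load on no factor"):
            ModelSpec(name="bad", items=["x0", "x1"], factors=["F"],
                      loadings={("x0", "F"): FREE})


class TestImpliedSigma:
    def test_zero_loadings_give_diagonal(self):
        spec = one_factor_spec(3)
        theta = np.array([0, 0, 0, 0.5, 0.6, 0.7])
        np.testing.assert_allclose(implied_sigma(spec, theta), np.diag([0.5, 0.6, 0.7]))

    def test_one_factor_closed_form(self):
        spec = one_factor_spec(3)
        lam = np.array([0.3, 0.5, 0.7])
        th = np.array([0.2, 0.3, 0.4])
        sigma = implied_sigma(spec, np.concatenate([lam, th]))
        for i in range(3):
            for j in range(3):
                expected = lam[i] * lam[j] + (th[i] if i == j else 0.0)
                assert sigma[i, j] == pytest.approx(expected)

    def test_matches_direct_matrix_product(self):
        # two correlated factors, fixed and free values mixed
        items = ["a", "b", "c"]
        spec = ModelSpec(
            name="m", items=items, factors=["F", "G"],
            loadings={("a", "F"): FREE, ("b", "F"): 0.4, ("b", "G"): FREE, ("c", "G"): FREE},
            factor_cov={("G", "F"): FREE},
        )
        rng = np.random.default_rng(0)
        theta = rng.uniform(0.1, 0.8, count_free_parameters(spec))
        names = free_parameter_names(spec)
        vals = dict(zip(names, theta))
        Lam = np.array([
            [vals[("lambda", "a", "F")], 0.0],
            [0.4, vals[("lambda", "b", "G")]],
            [0.0, vals[("lambda", "c", "G")]],
        ])
        Psi = np.array([[1.0, vals[("psi", "G", "F")]], [vals[("psi", "G", "F")], 1.0]])
        Th = np.diag([vals[("theta", it)] for it in items])
        np.testing.assert_allclose(implied_sigma(spec, theta), Lam @ Psi @ Lam.T + Th)


class TestSmoothToPD:
    def test_pd_input_unchanged(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        out, change = smooth_to_pd(S, 1e-8)
        np.testing.assert_allclose(out, S)
        assert change == 0.0

    def test_negative_eigenvalue_clipped_to_epsilon(self):
        # eigen oracle: construct a matrix with one -0.01 eigenvalue
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        vals = np.array([1.0, 0.5, 0.2, -0.01])
        S = Q @ np.diag(vals) @ Q.T
        S = (S + S.T) / 2
        eps = 1e-6
        out, change = smooth_to_pd(S, eps)
        got = np.linalg.eigvalsh(out)
        assert got.min() == pytest.approx(eps, rel=1e-6)
        expected = Q @ np.diag(np.clip(vals, eps, None)) @ Q.T
        np.testing.assert_allclose(out, (expected + expected.T) / 2, atol=1e-10)
        assert change > 0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 5))
        out, _ = smooth_to_pd((A + A.T) / 2, 1e-8)
        np.testing.assert_allclose(out, out.T)


def _toy_theta():
    # 3-item one-factor truth with distinct loadings
    return np.array([0.6, 0.7, 0.5, 0.3, 0.25, 0.4])


class TestFitDWLS:
    def test_noise_free_recovery_is_exact(self):
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.0, seed=0)
        fit = fit_dwls(spec, gc)
        assert fit.chisq < 1e-6
        np.testing.assert_allclose(fit.estimates, theta, atol=1e-6)
        assert fit.converged

    def test_matches_independent_brute_force_minimizer(self):
        """DWLS solution vs Nelder-Mead multistart of the same discrepancy."""
        from scipy.optimize import minimize

        spec = one_factor_spec(3)
        theta = _toy_theta()
        gc = fixture_gc(spec, theta, noise_scale=0.05, seed=9)
        fit = fit_dwls(spec, gc)

        s = vech(gc.S)
        w = 1.0 / np.diag(gc.V)

        def F(th):
            e = s - vech(implied_sigma(spec, th))
            return e @ (w * e)

        best = None
        rng = np.random.default_rng(0)
        for _ in range(8):
            x0 = theta * rng.uniform(0.5, 1.5, theta.size)
            res = minimize(F, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        np.testing.assert_allclose(np.abs(fit.estimates), np.abs(best.x), atol=1e-4)
        assert fit.F_min == pytest.approx(best.fun, abs=1e-6)

    def test_refit_from_solution_is_fixed_point(self):
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.02, seed=17)
        fit1 = fit_dwls(spec, gc)
        fit2 = fit_dwls(spec, gc, x0=fit1.estimates)
        np.testing.assert_allclose(fit2.estimates, fit1.estimates, atol=1e-10)

    def test_aic_identity_exact(self):
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.05, seed=23)
        fit = fit_dwls(spec, gc)
        assert fit.AIC == fit.chisq + 2 * fit.q

    def test_zero_v_diagonal_names_moment(self):
        spec = one_factor_spec(3)
        gc = fixture_gc(spec, _toy_theta(), noise_scale=0.02, seed=2)
        V = gc.V.copy()
        V[1, 1] = 0.0
        bad = GeneticCovariance(trait_names=gc.trait_names, S=gc.S, V=V)
        with pytest.raises(ValueError, match="x1.*x0"):
            fit_dwls(spec, bad)

    def test_perfect_fit_indices(self):
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.0, seed=0)
        fit = fit_dwls(spec, gc)
        assert fit.CFI == pytest.approx(1.0)
        assert fit.SRMR == pytest.approx(0.0, abs=1e-8)

    def test_standardized_identity_orthogonal_factors(self):
        # squared standardized loading + standardized residual variance = 1
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.03, seed=5)
        fit = fit_dwls(spec, gc)
        var = np.diag(fit.implied)
        for i, it in enumerate(spec.items):
            lam_std = fit.standardized_loadings[(it, "F")]
            th = fit.estimate(("theta", it))
            assert lam_std**2 + th / var[i] == pytest.approx(1.0, abs=1e-10)

    def test_standardized_equals_raw_on_correlation_input(self):
        # noise-free fixture from a truth whose implied variances are 1
        spec = one_factor_spec(3)
        lam = np.array([0.6, 0.7, 0.5])
        theta = np.concatenate([lam, 1 - lam**2])
        gc = fixture_gc(spec, theta, noise_scale=0.0, seed=0)
        fit = fit_dwls(spec, gc)
        for i, it in enumerate(spec.items):
            assert fit.standardized_loadings[(it, "F")] == pytest.approx(lam[i], abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        spec = one_factor_spec(4)
        theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
        gc = fixture_gc(spec, theta, noise_scale=0.02, seed=8)
        # start the optimizer in the mirrored basin
        fit = fit_dwls(spec, gc, x0=np.concatenate([-theta[:4], theta[4:]]))
        std = [fit.standardized_loadings[(it, "F")] for it in spec.items]
        assert std[int(np.argmax(np.abs(std)))] > 0


class TestCalibration:
    def test_sandwich_ses_and_unbiasedness(self, bifactor_spec, bifactor_theta):
        """200 fixture draws from the bifactor truth: estimates unbiased and
        sandwich SEs within 15% of the empirical spread."""
        n_rep = 200
        ests = np.empty((n_rep, bifactor_theta.size))
        ses = np.empty_like(ests)
        pvals = np.empty(n_rep)
        for r in range(n_rep):
            gc = fixture_gc(bifactor_spec, bifactor_theta, noise_scale=0.01, seed=1000 + r)
            fit = fit_dwls(bifactor_spec, gc, compute_indices=False)
            ests[r] = fit.estimates
            ses[r] = fit.se
            pvals[r] = fit.p_value
        bias = ests.mean(axis=0) - bifactor_theta
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(bias) < 4 * mc_se)
        ratio = ses.mean(axis=0) / ests.std(axis=0, ddof=1)
        assert np.all(np.abs(ratio - 1) < 0.15)
        # chi-square p-values approximately uniform (mean 1/2 within MC error)
        assert abs(pvals.mean() - 0.5) < 4 * np.sqrt(1 / 12 / n_rep)


def test_make_sv_fixture_v_is_psd():
    spec = one_factor_spec(4)
    theta = np.array([0.6, 0.7, 0.5, 0.4, 0.3, 0.25, 0.4, 0.35])
    for seed in range(5):
        _, V = make_sv_fixture(spec, theta, noise_scale=0.02, seed=seed)
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > 0
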