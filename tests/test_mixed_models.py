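import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from simgrowth import (
    GrowthParams,
    OutcomeParams,
    TrajectoryData,
    alpha_from_omega,
    bivariate_loglik,
    blup_residuals,
    draw_age_schedule,
    estimates_from_residuals,
    fit_bivariate_lmm,
    fit_univariate_lmm,
    inflate_residuals,
    second_stage,
    simulate_trajectories,
    univariate_loglik,
)
from simgrowth.mixed_models import (
    LmmFit,
    ResidualSet,
    _chol_from_theta,
    _kernel_args,
    _make_stats,
    _nll_bivariate,
    _nll_univariate,
    _theta_from_cov,
)
from simgrowth import _kernels

OMEGA3 = np.array([[6.0, 0.2, 3.0], [0.2, 0.3, 0.5], [3.0, 0.5, 102.0]])


def _brute_loglik_uni(data, beta, omega, sigma):
    ll = 0.0
    for j in range(data.n_individuals):
        Z = np.column_stack([np.ones(data.n_occasions), data.ages[j]])
        V = Z @ omega @ Z.T + sigma**2 * np.eye(data.n_occasions)
        ll += multivariate_normal.logpdf(data.heights[j], Z @ beta, V)
    return ll


def _brute_loglik_biv(data, beta, omega3, sigma):
    ll = 0.0
    I = data.n_occasions
    for j in range(data.n_individuals):
        Z = np.column_stack([np.ones(I), data.ages[j]])
        Zt = np.zeros((I + 1, 3))
        Zt[:I, :2] = Z
        Zt[I, 2] = 1.0
        V = Zt @ omega3 @ Zt.T + np.diag([sigma**2] * I + [0.0])
        mu = np.append(Z @ beta[:2], beta[2])
        y = np.append(data.heights[j], data.outcome[j])
        ll += multivariate_normal.logpdf(y, mu, V, allow_singular=True)
    return ll


class TestLikelihood:
    def test_univariate_matches_dense_gaussian(self, data_small):
        beta = np.array([49.5, 9.2])
        ours = univariate_loglik(data_small, beta, OMEGA3[:2, :2], 1.8)
        brute = _brute_loglik_uni(data_small, beta, OMEGA3[:2, :2], 1.8)
        assert ours == pytest.approx(brute, abs=1e-8)

    def test_bivariate_matches_dense_gaussian(self, data_small):
        beta = np.array([49.5, 9.2, 119.0])
        ours = bivariate_loglik(data_small, beta, OMEGA3, 1.8)
        brute = _brute_loglik_biv(data_small, beta, OMEGA3, 1.8)
        assert ours == pytest.approx(brute, abs=1e-8)

    def test_bivariate_factorises_when_outcome_independent(self, data_small):
        # zero cross-covariances: joint loglik = growth loglik + iid
        # Gaussian loglik of the outcome around its mean
        omega3 = OMEGA3.copy()
        omega3[2, :2] = omega3[:2, 2] = 0.0
        beta = np.array([49.5, 9.2, 119.0])
        joint = bivariate_loglik(data_small, beta, omega3, 1.8)
        heights = univariate_loglik(data_small, beta[:2], omega3[:2, :2], 1.8)
        sd = np.sqrt(omega3[2, 2])
        outcome = np.sum(
            -0.5 * np.log(2 * np.pi * sd**2)
            - 0.5 * (data_small.outcome - beta[2]) ** 2 / sd**2
        )
        assert joint == pytest.approx(heights + outcome, abs=1e-8)

    @pytest.mark.parametrize("kind", ["univariate", "bivariate"])
    def test_compiled_kernel_agrees_with_reference(self, kind, data_small):
        with_bp = kind == "bivariate"
        dim = 3 if with_bp else 2
        rng = np.random.default_rng(12)
        w = rng.integers(0, 3, data_small.n_individuals).astype(float)
        stats = _make_stats(data_small, weights=w, with_bp=with_bp)
        args = _kernel_args(stats, with_bp)
        theta = _theta_from_cov(OMEGA3[:dim, :dim], 1.8, dim)
        theta += rng.normal(0, 0.05, theta.size)
        kernel = _kernels.biv_nll_grad if with_bp else _kernels.uni_nll_grad
        reference = _nll_bivariate if with_bp else _nll_univariate
        nll_k, grad_k, _, _ = kernel(theta, *args, True)
        nll_r, grad_r = reference(theta, stats, True)
        assert nll_k == pytest.approx(nll_r, rel=1e-10)
        np.testing.assert_allclose(grad_k, grad_r, rtol=1e-7, atol=1e-9)

    def test_gradient_matches_finite_differences(self, data_small):
        stats = _make_stats(data_small, with_bp=True)
        args = _kernel_args(stats, True)
        theta = _theta_from_cov(OMEGA3, 1.8, 3)
        _, grad, _, _ = _kernels.biv_nll_grad(theta, *args, True)
        for i in range(theta.size):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            fp = _kernels.biv_nll_grad(theta + e, *args, False)[0]
            fm = _kernels.biv_nll_grad(theta - e, *args, False)[0]
            assert grad[i] == pytest.approx((fp - fm) / 2e-6, rel=5e-4, abs=1e-4)

    def test_weighted_equals_expanded(self, data_small):
        rng = np.random.default_rng(3)
        w = np.bincount(
            rng.integers(0, data_small.n_individuals, data_small.n_individuals),
            minlength=data_small.n_individuals,
        ).astype(float)
        idx = np.repeat(np.arange(data_small.n_individuals), w.astype(int))
        expanded = TrajectoryData(
            ages=data_small.ages[idx],
            heights=data_small.heights[idx],
            outcome=data_small.outcome[idx],
        )
        beta = np.array([49.5, 9.2, 119.0])
        assert bivariate_loglik(data_small, beta, OMEGA3, 1.8, weights=w) == (
            pytest.approx(bivariate_loglik(expanded, beta, OMEGA3, 1.8), rel=1e-12)
        )
        fw = fit_bivariate_lmm(data_small, weights=w)
        fe = fit_bivariate_lmm(expanded)
        assert fw.loglik == pytest.approx(fe.loglik, abs=1e-5)
        np.testing.assert_allclose(fw.fixed, fe.fixed, atol=1e-5)


class TestUnivariateFit:
    def test_against_statsmodels_mixedlm(self, data_small):
        fit = fit_univariate_lmm(data_small)
        J, I = data_small.ages.shape
        frame = pd.DataFrame(
            {
                "height": data_small.heights.ravel(),
                "age": data_small.ages.ravel(),
                "id": np.repeat(np.arange(J), I),
            }
        )
        model = sm.MixedLM.from_formula(
            "height ~ age", groups="id", re_formula="~age", data=frame
        )
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
        # same likelihood function: evaluate ours at their estimates
        ours_at_sm = univariate_loglik(
            data_small, res.fe_params.to_numpy(), res.cov_re.to_numpy(),
            np.sqrt(res.scale),
        )
        assert ours_at_sm == pytest.approx(res.llf, abs=1e-6)
        # both optimisers find the same maximum
        assert fit.loglik == pytest.approx(res.llf, abs=1e-4)
        np.testing.assert_allclose(fit.fixed, res.fe_params.to_numpy(), atol=1e-3)
        np.testing.assert_allclose(
            fit.fixed_se, res.bse_fe.to_numpy(), rtol=1e-2
        )

    def test_gls_fixed_effects_closed_form(self, data_small):
        # with variance parameters held at the fit, the profiled fixed
        # effects must equal the dense-matrix GLS estimator
        fit = fit_univariate_lmm(data_small)
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        for j in range(data_small.n_individuals):
            Z = np.column_stack([np.ones(5), data_small.ages[j]])
            V = Z @ fit.omega @ Z.T + fit.sigma_eh**2 * np.eye(5)
            Vi = np.linalg.inv(V)
            XtVX += Z.T @ Vi @ Z
            XtVy += Z.T @ Vi @ data_small.heights[j]
        np.testing.assert_allclose(fit.fixed, np.linalg.solve(XtVX, XtVy), atol=1e-8)
        np.testing.assert_allclose(
            fit.fixed_se, np.sqrt(np.diag(np.linalg.inv(XtVX))), rtol=1e-7
        )

    def test_noiseless_degenerate_limit(self, noiseless_data):
        fit = fit_univariate_lmm(noiseless_data)
        u = np.stack([noiseless_data.true_u0, noiseless_data.true_u1], axis=1)
        np.testing.assert_allclose(fit.fixed, [50.0, 9.0] + u.mean(axis=0), atol=0.02)
        np.testing.assert_allclose(fit.omega, np.cov(u.T, bias=True), atol=0.05)
        assert fit.sigma_eh < 0.01

    def test_parameter_recovery_over_replicates(self):
        sched = draw_age_schedule(n_individuals=400, seed=21)
        g, o = GrowthParams(), OutcomeParams()
        omegas = []
        for seed in range(100):
            data = simulate_trajectories(sched, g, o, seed=3000 + seed)
            omegas.append(fit_univariate_lmm(data).omega)
        omegas = np.asarray(omegas)
        mean = omegas.mean(axis=0)
        se = omegas.std(axis=0, ddof=1) / np.sqrt(len(omegas))
        assert np.all(np.abs(mean - g.omega) < 3.5 * se + 1e-3)


class TestBivariateFit:
    def test_independent_outcome_gives_zero_cross_covariances(self, schedule_small):
        growth = GrowthParams()
        outcome = OutcomeParams(alpha3=0.0, alpha4=0.0)
        data = simulate_trajectories(schedule_small, growth, outcome, seed=31)
        fit = fit_bivariate_lmm(data)
        # SE of a covariance ~ sqrt(var1*var2/J)
        J = data.n_individuals
        se0 = np.sqrt(growth.sigma_u0**2 * outcome.sigma_ebp**2 / J)
        se1 = np.sqrt(growth.sigma_u1**2 * outcome.sigma_ebp**2 / J)
        assert abs(fit.omega[0, 2]) < 4 * se0
        assert abs(fit.omega[1, 2]) < 4 * se1

    def test_moment_transform_recovers_conditional_effects(self, data_large):
        fit = fit_bivariate_lmm(data_large)
        a1, a3, a4 = alpha_from_omega(fit.omega)
        assert a3 == pytest.approx(0.5, abs=0.45)
        assert a4 == pytest.approx(2.0, abs=2.2)
        assert a1 == pytest.approx(0.54, abs=0.45)

    def test_embeds_univariate_fit(self, data_small):
        # growth block of the joint fit stays near the univariate fit
        uni = fit_univariate_lmm(data_small)
        biv = fit_bivariate_lmm(data_small)
        np.testing.assert_allclose(biv.fixed[:2], uni.fixed, atol=0.05)
        np.testing.assert_allclose(biv.omega[:2, :2], uni.omega, atol=0.3)


class TestBlups:
    def test_closed_form_equals_dense_joint_gls(self):
        sched = draw_age_schedule(n_individuals=15, seed=41)
        data = simulate_trajectories(sched, GrowthParams(), OutcomeParams(), seed=42)
        for kind in ("univariate", "bivariate"):
            if kind == "univariate":
                fit = fit_univariate_lmm(data)
            else:
                fit = fit_bivariate_lmm(data)
            res = blup_residuals(fit, data)
            for j in range(data.n_individuals):
                Z = np.column_stack([np.ones(5), data.ages[j]])
                if kind == "univariate":
                    V = Z @ fit.omega @ Z.T + fit.sigma_eh**2 * np.eye(5)
                    r = data.heights[j] - Z @ fit.fixed
                    expected = fit.omega @ Z.T @ np.linalg.solve(V, r)
                else:
                    Zt = np.zeros((6, 3))
                    Zt[:5, :2] = Z
                    Zt[5, 2] = 1.0
                    V = Zt @ fit.omega @ Zt.T + np.diag([fit.sigma_eh**2] * 5 + [0.0])
                    r = np.append(
                        data.heights[j] - Z @ fit.fixed[:2],
                        data.outcome[j] - fit.fixed[2],
                    )
                    expected = fit.omega @ Zt.T @ np.linalg.solve(V, r)
                np.testing.assert_allclose(res.u_hat[j], expected, atol=1e-8)

    def test_full_shrinkage_limit_zero_residuals(self, data_small):
        fit = LmmFit(
            kind="univariate", fixed=np.array([50.0, 9.0]),
            fixed_se=np.zeros(2), omega=np.zeros((2, 2)), sigma_eh=2.0,
            loglik=0.0, converged=True, n_iter=0,
        )
        res = blup_residuals(fit, data_small)
        assert np.all(res.u_hat == 0.0)

    def test_no_shrinkage_limit_approaches_ols(self, noiseless_data):
        from simgrowth import ols_summaries

        fit = fit_univariate_lmm(noiseless_data)
        res = blup_residuals(fit, noiseless_data)
        ols = ols_summaries(noiseless_data)
        np.testing.assert_allclose(
            fit.fixed[0] + res.u_hat[:, 0], ols.b_hat, atol=1e-4
        )
        np.testing.assert_allclose(
            fit.fixed[1] + res.u_hat[:, 1], ols.g_hat, atol=1e-4
        )

    def test_shrinkage_inequality(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = blup_residuals(fit, data_small)
        assert res.u_hat[:, 0].var() < fit.omega[0, 0]
        assert res.u_hat[:, 1].var() < fit.omega[1, 1]


class TestInflation:
    def _residuals(self, u):
        return ResidualSet(u_hat=u, inflated=False, reference_cov=np.cov(u.T, bias=True))

    def test_hand_cholesky_case(self):
        # sample cov diag(4,1) -> target diag(1,1): u* = (u0/2, u1)
        rng = np.random.default_rng(5)
        u = rng.standard_normal((500, 2))
        u -= u.mean(axis=0)
        # whiten then scale to make the sample covariance exactly diag(4,1)
        L = np.linalg.cholesky(np.cov(u.T, bias=True))
        u = u @ np.linalg.inv(L).T @ np.diag([2.0, 1.0])
        res = self._residuals(u)
        out = inflate_residuals(res, np.eye(2))
        np.testing.assert_allclose(out.u_hat[:, 0], 0.5 * u[:, 0], atol=1e-10)
        np.testing.assert_allclose(out.u_hat[:, 1], u[:, 1], atol=1e-10)

    def test_already_calibrated_is_identity(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = blup_residuals(fit, data_small)
        u = res.u_hat
        S = np.cov((u - u.mean(axis=0)).T, bias=True)
        out = inflate_residuals(res, S)
        np.testing.assert_allclose(out.u_hat, u, atol=1e-10)

    def test_postcondition_sample_covariance_exact(self, data_small):
        fit = fit_bivariate_lmm(data_small)
        res = blup_residuals(fit, data_small)
        out = inflate_residuals(res, fit.omega)
        uc = out.u_hat - out.u_hat.mean(axis=0)
        S = uc.T @ uc / uc.shape[0]
        np.testing.assert_allclose(S, fit.omega, rtol=1e-10, atol=1e-12)

    def test_first_component_is_positive_rescaling(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = blup_residuals(fit, data_small)
        out = inflate_residuals(res, fit.omega)
        centred_in = res.u_hat[:, 0] - res.u_hat[:, 0].mean()
        centred_out = out.u_hat[:, 0] - out.u_hat[:, 0].mean()
        ratio = centred_out / centred_in
        assert np.allclose(ratio, ratio[0]) and ratio[0] > 0

    def test_upper_orientation_mixes_first_component(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = blup_residuals(fit, data_small)
        out = inflate_residuals(res, fit.omega, orientation="upper")
        uc = out.u_hat - out.u_hat.mean(axis=0)
        S = uc.T @ uc / uc.shape[0]
        np.testing.assert_allclose(S, fit.omega, rtol=1e-10, atol=1e-12)
        centred_in = res.u_hat[:, 0] - res.u_hat[:, 0].mean()
        centred_out = uc[:, 0]
        ratio = centred_out / centred_in
        assert not np.allclose(ratio, ratio[0])  # genuine linear combination

    def test_double_inflation_rejected(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = inflate_residuals(blup_residuals(fit, data_small), fit.omega)
        with pytest.raises(ValueError, match="already"):
            inflate_residuals(res, fit.omega)

    def test_singular_sample_covariance_rejected(self):
        u = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        res = self._residuals(u)
        with pytest.raises(np.linalg.LinAlgError, match="calibrate"):
            inflate_residuals(res, np.eye(2))


class TestEstimatesAndMoments:
    def test_zero_residuals_give_population_means(self, data_small):
        fit = fit_univariate_lmm(data_small)
        res = ResidualSet(
            u_hat=np.zeros((data_small.n_individuals, 2)),
            inflated=False, reference_cov=fit.omega,
        )
        est = estimates_from_residuals(fit, res)
        assert np.all(est.b_hat == fit.fixed[0])
        assert np.all(est.g_hat == fit.fixed[1])
        assert est.method == "mlm_shrunken"

    def test_joint_two_stage_equals_moment_estimator(self, data_small):
        # the second-stage regression on simultaneously re-inflated
        # residuals reproduces the moment transform of omega exactly
        fit = fit_bivariate_lmm(data_small)
        res = inflate_residuals(blup_residuals(fit, data_small), fit.omega)
        est = estimates_from_residuals(fit, res)
        assoc = second_stage(est, est.bp_hat)
        a1, a3, a4 = alpha_from_omega(fit.omega)
        assert assoc["alpha1"].estimate == pytest.approx(a1, abs=1e-8)
        assert assoc["alpha3"].estimate == pytest.approx(a3, abs=1e-8)
        assert assoc["alpha4"].estimate == pytest.approx(a4, abs=1e-8)

    def test_bivariate_bp_hat_tracks_observed_outcome(self, data_large):
        fit = fit_bivariate_lmm(data_large)
        res = inflate_residuals(blup_residuals(fit, data_large), fit.omega)
        est = estimates_from_residuals(fit, res)
        assert est.method == "bvm_inflated"
        assert np.corrcoef(est.bp_hat, data_large.outcome)[0, 1] > 0.9

    def test_alpha_from_omega_analytic_construction(self):
        # omega built from the true generating parameters returns the
        # exact alpha values: alpha1 = 0.5 + 2.0*(0.1*0.5/2.5) = 0.54
        g, o = GrowthParams(), OutcomeParams()
        om2 = g.omega
        avec = np.array([o.alpha3, o.alpha4])
        omega3 = np.zeros((3, 3))
        omega3[:2, :2] = om2
        omega3[:2, 2] = omega3[2, :2] = om2 @ avec
        omega3[2, 2] = avec @ om2 @ avec + o.sigma_ebp**2
        a1, a3, a4 = alpha_from_omega(omega3)
        assert a1 == pytest.approx(0.54, abs=1e-12)
        assert a3 == pytest.approx(0.5, abs=1e-12)
        assert a4 == pytest.approx(2.0, abs=1e-12)

    def test_alpha_from_omega_edge_cases(self):
        zero_cross = np.diag([6.25, 0.25, 100.0])
        assert alpha_from_omega(zero_cross) == (0.0, 0.0, 0.0)
        diag_growth = zero_cross.copy()
        diag_growth[0, 2] = diag_growth[2, 0] = 2.0
        diag_growth[1, 2] = diag_growth[2, 1] = 0.1
        a1, a3, a4 = alpha_from_omega(diag_growth)
        assert a3 == pytest.approx(2.0 / 6.25)
        assert a4 == pytest.approx(0.1 / 0.25)
        assert a1 == pytest.approx(2.0 / 6.25)
        singular = np.zeros((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            alpha_from_omega(singular)
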