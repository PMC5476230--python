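"""Latent growth curve SEM for the joint growth-outcome model.

The measurement model loads each height on two latent factors — birth
length ``B`` (loadings 1) and growth rate ``G`` (loadings equal to the
measurement age) — and the structural model regresses the distal outcome
directly on the latent factors:

    H_ij = B_j + t_ij * G_j + e1_ij
    BP_j = alpha2 + alpha3 * B_j + alpha4 * G_j + e2_j      (conditional)
    BP_j = alpha0 + alpha1 * B_j + e2_j                     (unconditional)

Because the structural coefficients are free parameters, their standard
errors propagate the first-stage uncertainty in full — the property the
two-stage pipelines lack.  Fits maximise the implied multivariate-
Gaussian marginal likelihood directly (no separate SEM engine).

Time-score (loadings) modes
---------------------------
``individual_ages`` (default)
    ``t_ij`` are each individual's observed ages.  The model is then an
    exact reparameterisation of the bivariate joint LMM: the maximised
    likelihoods coincide and the structural estimates equal the moment
    transform of the joint random-effect covariance.  Fitting reuses the
    compiled joint-likelihood kernel; standard errors come from the
    profile-likelihood Hessian plus the delta method.
``birth_at_zero``
    As above, except the birth indicator is anchored at exactly t=0, as
    an analyst treating "birth length" as measured at birth would do;
    the small residual age jitter at birth is then ignored by the model.
``fixed_mean_ages``
    Conventional fixed time scores at the occasion mean ages with a
    single measurement-residual variance.  With individually jittered
    measurement ages this specification is badly misspecified (the
    growth-rate x age-jitter term acts as large, heteroscedastic
    occasion noise) and is retained only as a contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .mixed_models import (
    _chol_from_theta,
    _kernel_args,
    _make_stats,
    _theta_from_cov,
    fit_bivariate_lmm,
)
from .simulate import TrajectoryData
from .trajectory_summaries import ols_summaries

__all__ = ["SemFit", "fit_sem_conditional", "fit_sem_unconditional", "alpha1_from_sem"]

_LOG2PI = np.log(2.0 * np.pi)
_MODES = ("individual_ages", "birth_at_zero", "fixed_mean_ages")


@dataclass(frozen=True)
class SemFit:
    """Fitted SEM.  Conditional fits carry (alpha2, alpha3, alpha4);
    unconditional fits carry (alpha0, alpha1)."""

    structural: str  # "conditional" | "unconditional"
    loadings_mode: str
    coef: dict
    se: dict
    latent_means: np.ndarray  # (muB, muG)
    latent_cov: np.ndarray  # 2x2
    sigma_e1: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def alpha3(self) -> float:
        return self.coef["alpha3"]

    @property
    def alpha4(self) -> float:
        return self.coef["alpha4"]

    @property
    def alpha1(self) -> float:
        return self.coef["alpha1"]

    def summary_dict(self) -> dict:
        return {
            "structural": self.structural,
            "loadings_mode": self.loadings_mode,
            "coef": dict(self.coef),
            "se": dict(self.se),
            "latent_means": self.latent_means.tolist(),
            "latent_cov": self.latent_cov.tolist(),
            "sigma_e1": self.sigma_e1,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


# ---------------------------------------------------------------------------
# numerical helpers

def _num_hessian(f, x, rel_step=1e-3):
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _num_jacobian(f, x, step=1e-6):
    f0 = np.atleast_1d(f(x))
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = step
        J[:, i] = (np.atleast_1d(f(x + e)) - np.atleast_1d(f(x - e))) / (2 * step)
    return J


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _model_data(data: TrajectoryData, mode: str) -> TrajectoryData:
    if mode == "individual_ages":
        return data
    ages = data.ages.copy()
    ages[:, 0] = 0.0
    return TrajectoryData(ages=ages, heights=data.heights, outcome=data.outcome)


# ---------------------------------------------------------------------------
# kernel-based modes (individual_ages / birth_at_zero)

def _alpha_map(theta):
    """(alpha3, alpha4) from the joint-covariance log-Cholesky params."""
    L = _chol_from_theta(theta, 3)
    om = L @ L.T
    a = np.linalg.solve(om[:2, :2], om[:2, 2])
    return a


def _cond_kernel_fit(data: TrajectoryData, mode: str) -> SemFit:
    mdata = _model_data(data, mode)
    fit = fit_bivariate_lmm(mdata)
    psi = fit.omega[:2, :2]
    cvec = fit.omega[:2, 2]
    a = np.linalg.solve(psi, cvec)
    sig_e2_sq = fit.omega[2, 2] - cvec @ a
    mu = fit.fixed[:2]
    alpha2 = fit.fixed[2] - a @ mu

    stats = _make_stats(mdata, with_bp=True)
    args = _kernel_args(stats, True)
    theta = _theta_from_cov(fit.omega, fit.sigma_eh, 3)

    def nll(th):
        return _kernels.biv_nll_grad(th, *args, False)[0]

    H = _num_hessian(nll, theta)
    cov_theta = _safe_inv(H)
    Ja = _num_jacobian(_alpha_map, theta)  # 2 x 7
    cov_a = Ja @ cov_theta @ Ja.T
    se3, se4 = np.sqrt(np.clip(np.diag(cov_a), 0.0, None))
    # alpha2 = beta2 - a'beta_h; mean and covariance parameters are
    # asymptotically orthogonal in Gaussian models, so the two variance
    # contributions add.
    _, _, beta, M = _kernels.biv_nll_grad(theta, *args, False)
    gb = np.array([-a[0], -a[1], 1.0])
    gt = -Ja.T @ mu  # d alpha2 / d theta through a(theta)
    var2 = gb @ _safe_inv(M) @ gb + gt @ cov_theta @ gt
    return SemFit(
        structural="conditional",
        loadings_mode=mode,
        coef={"alpha2": float(alpha2), "alpha3": float(a[0]), "alpha4": float(a[1])},
        se={"alpha2": float(np.sqrt(max(var2, 0.0))),
            "alpha3": float(se3), "alpha4": float(se4)},
        latent_means=mu.copy(),
        latent_cov=psi.copy(),
        sigma_e1=fit.sigma_eh,
        sigma_e2=float(np.sqrt(max(sig_e2_sq, 0.0))),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )


def _alpha1_map(theta):
    """Marginal birth-length coefficient from the joint-covariance params."""
    L = _chol_from_theta(theta, 3)
    om = L @ L.T
    return np.array([om[0, 2] / om[0, 0]])


def _uncond_kernel_fit(data: TrajectoryData, mode: str) -> SemFit:
    """Unconditional structural model ``BP = alpha0 + alpha1 B + e2``.

    The growth factor stays in the measurement model and the outcome
    residual is free to covary with it, so the model is a saturated
    reparameterisation of the joint fit: ``alpha1`` is the marginal
    regression coefficient ``omega_0BP / omega_00``, identical to the
    ``alpha3 + alpha4 psi01/psi00`` transform of the conditional fit.
    Its SE propagates the full first-stage uncertainty via the
    profile-likelihood Hessian and the delta method.
    """
    mdata = _model_data(data, mode)
    fit = fit_bivariate_lmm(mdata)
    psi = fit.omega[:2, :2]
    alpha1 = fit.omega[0, 2] / fit.omega[0, 0]
    sig_e2_sq = fit.omega[2, 2] - fit.omega[0, 2] ** 2 / fit.omega[0, 0]
    stats = _make_stats(mdata, with_bp=True)
    args = _kernel_args(stats, True)
    theta = _theta_from_cov(fit.omega, fit.sigma_eh, 3)

    def nll(th):
        return _kernels.biv_nll_grad(th, *args, False)[0]

    H = _num_hessian(nll, theta)
    cov_theta = _safe_inv(H)
    Ja = _num_jacobian(_alpha1_map, theta)  # 1 x 7
    se1 = float(np.sqrt(max((Ja @ cov_theta @ Ja.T)[0, 0], 0.0)))
    mu = fit.fixed[:2]
    alpha0 = fit.fixed[2] - alpha1 * mu[0]
    _, _, _, M = _kernels.biv_nll_grad(theta, *args, False)
    gb = np.array([-alpha1, 0.0, 1.0])
    gt = -mu[0] * Ja[0]
    var0 = gb @ _safe_inv(M) @ gb + gt @ cov_theta @ gt
    return SemFit(
        structural="unconditional",
        loadings_mode=mode,
        coef={"alpha0": float(alpha0), "alpha1": float(alpha1)},
        se={"alpha0": float(np.sqrt(max(var0, 0.0))), "alpha1": se1},
        latent_means=mu.copy(),
        latent_cov=psi.copy(),
        sigma_e1=fit.sigma_eh,
        sigma_e2=float(np.sqrt(max(sig_e2_sq, 0.0))),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )


# ---------------------------------------------------------------------------
# fixed mean-age loadings (moment-based contrast mode)

def _unpack_fixed(theta, conditional):
    mu = theta[:2]
    if conditional:
        coefs = {"alpha2": theta[2], "alpha3": theta[3], "alpha4": theta[4]}
        a = np.array([theta[3], theta[4]])
        k = 5
    else:
        coefs = {"alpha0": theta[2], "alpha1": theta[3]}
        a = np.array([theta[3], 0.0])
        k = 4
    l00 = np.exp(theta[k]); l10 = theta[k + 1]; l11 = np.exp(theta[k + 2])
    psi = np.array([[l00 * l00, l00 * l10],
                    [l00 * l10, l10 * l10 + l11 * l11]])
    sig_e1 = np.exp(theta[k + 3])
    sig_e2 = np.exp(theta[k + 4])
    return mu, coefs, a, psi, sig_e1, sig_e2


def _nll_fixed(theta, lam, xbar, S, J, conditional):
    mu, coefs, a, psi, sig_e1, sig_e2 = _unpack_fixed(theta, conditional)
    intercept = coefs["alpha2"] if conditional else coefs["alpha0"]
    I = lam.shape[0]
    lam_psi = lam @ psi
    sigma = np.empty((I + 1, I + 1))
    sigma[:I, :I] = lam_psi @ lam.T
    sigma[:I, :I][np.diag_indices(I)] += sig_e1**2
    sigma[:I, I] = sigma[I, :I] = lam_psi @ a
    sigma[I, I] = a @ psi @ a + sig_e2**2
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    d = xbar - np.append(lam @ mu, intercept + a @ mu)
    sol = np.linalg.solve(sigma, np.column_stack([S, d]))
    return 0.5 * J * ((I + 1) * _LOG2PI + logdet + np.trace(sol[:, :-1]) + d @ sol[:, -1])


def _start_values_fixed(data: TrajectoryData, conditional: bool):
    est = ols_summaries(data)
    b, g, bp = est.b_hat, est.g_hat, data.outcome
    x, y = data.ages, data.heights
    n = x.shape[1]
    rss = ((y - b[:, None] - g[:, None] * x) ** 2).sum(axis=1)
    sig_e1 = max(np.sqrt(rss.mean() / (n - 2)), 0.2)
    U = np.stack([b, g], axis=1)
    mu = U.mean(axis=0)
    psi = np.cov(U.T)
    psi[0, 0] = max(psi[0, 0] * 0.8, 0.2)
    psi[1, 1] = max(psi[1, 1] * 0.5, 0.01)
    cols = [np.ones(b.size), b] + ([g] if conditional else [])
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, bp, rcond=None)
    sig_e2 = max((bp - X @ coef).std(), 1.0)
    L = np.linalg.cholesky(psi)
    theta = [mu[0], mu[1]] + list(coef)
    theta += [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
              np.log(sig_e1), np.log(sig_e2)]
    return np.asarray(theta)


def _fit_fixed(data, conditional, mean_ages):
    ages = np.asarray(mean_ages, dtype=float) if mean_ages is not None \
        else data.ages.mean(axis=0)
    lam = np.column_stack([np.ones(ages.size), ages])
    stacked = np.column_stack([data.heights, data.outcome])
    xbar = stacked.mean(axis=0)
    S = np.cov(stacked.T, bias=True)
    J = data.n_individuals

    def nll(theta):
        return _nll_fixed(theta, lam, xbar, S, J, conditional)

    theta0 = _start_values_fixed(data, conditional)
    res = minimize(nll, theta0, method="L-BFGS-B",
                   options={"maxiter": 800, "ftol": 1e-12})
    H = _num_hessian(nll, res.x)
    cov = _safe_inv(H)
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    mu, coefs, a, psi, sig_e1, sig_e2 = _unpack_fixed(res.x, conditional)
    names = list(coefs)
    se = {nm: float(s) for nm, s in zip(names, se_vec[2:2 + len(names)])}
    return SemFit(
        structural="conditional" if conditional else "unconditional",
        loadings_mode="fixed_mean_ages",
        coef={k: float(v) for k, v in coefs.items()},
        se=se,
        latent_means=mu.copy(),
        latent_cov=psi,
        sigma_e1=float(sig_e1),
        sigma_e2=float(sig_e2),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# public API

def fit_sem_conditional(
    data: TrajectoryData,
    loadings_mode: str = "individual_ages",
    mean_ages=None,
) -> SemFit:
    """Fit the SEM with the conditional structural model (alpha3, alpha4).

    ``mean_ages`` fixes the growth-rate loadings in ``fixed_mean_ages``
    mode (default: empirical per-occasion mean ages).
    """
    if loadings_mode not in _MODES:
        raise ValueError(f"unknown loadings_mode: {loadings_mode!r}")
    if loadings_mode == "fixed_mean_ages":
        return _fit_fixed(data, True, mean_ages)
    return _cond_kernel_fit(data, loadings_mode)


def fit_sem_unconditional(
    data: TrajectoryData,
    loadings_mode: str = "individual_ages",
    mean_ages=None,
) -> SemFit:
    """Fit the SEM relating the outcome to birth length only (alpha1)."""
    if loadings_mode not in _MODES:
        raise ValueError(f"unknown loadings_mode: {loadings_mode!r}")
    if loadings_mode == "fixed_mean_ages":
        return _fit_fixed(data, False, mean_ages)
    return _uncond_kernel_fit(data, loadings_mode)


def alpha1_from_sem(fit: SemFit) -> float:
    """Unconditional birth-length association implied by a conditional fit,
    ``alpha1 = alpha3 + alpha4 * psi01 / psi00``; the refit is the
    SE-bearing route."""
    if fit.structural != "conditional":
        raise ValueError("requires a conditional fit")
    psi = fit.latent_cov
    if psi[0, 0] <= 0:
        raise ZeroDivisionError("zero birth-length variance")
    return float(fit.coef["alpha3"] + fit.coef["alpha4"] * psi[0, 1] / psi[0, 0])
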