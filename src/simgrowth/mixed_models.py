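"""Maximum-likelihood mixed models for growth and the joint growth-outcome model.

Two models are fitted by direct maximisation of the marginal Gaussian
likelihood:

* **Univariate LMM** — random intercept / random slope model for the
  repeated heights; per-individual covariance ``Z_j Omega Z_j' + s2 I``.
* **Bivariate (joint) LMM** — the same growth model plus a single-level
  equation for the distal outcome whose individual deviation ``u2j`` is
  correlated with the growth random effects; ``Omega`` becomes 3x3 and the
  outcome row carries no occasion-level residual (its variance lives
  entirely inside ``Omega``).

Implementation notes
--------------------
Likelihoods are profiled over the fixed effects (GLS) and evaluated with
the Woodbury identity on per-individual 2x2 blocks, so one evaluation is a
handful of vectorised operations over individuals; the bivariate outcome
row enters through its scalar Schur complement.  Optimisation is L-BFGS-B
over a log-Cholesky parameterisation of ``Omega`` plus ``log sigma_eh``,
with analytic gradients.  All sums over individuals accept frequency
weights, which is what makes non-parametric (cluster) bootstrap refits
cheap: a resample is just a new weight vector over the original
individuals.

Individual random-effect predictions are BLUPs ("shrunken residuals"),
``u_j = Omega Z_j' V_j^{-1} (y_j - X_j beta)``; their sample covariance
understates ``Omega``, and :func:`inflate_residuals` applies the
Cholesky-based linear re-calibration that restores it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .simulate import TrajectoryData
from .trajectory_summaries import IndividualEstimates, ols_summaries

__all__ = [
    "LmmFit",
    "ResidualSet",
    "fit_univariate_lmm",
    "fit_bivariate_lmm",
    "blup_residuals",
    "inflate_residuals",
    "estimates_from_residuals",
    "alpha_from_omega",
    "univariate_loglik",
    "bivariate_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LmmFit:
    """A converged (or flagged) maximum-likelihood fit."""

    kind: str  # "univariate" | "bivariate"
    fixed: np.ndarray
    fixed_se: np.ndarray
    omega: np.ndarray
    sigma_eh: float
    loglik: float
    converged: bool
    n_iter: int

    def summary_dict(self) -> dict:
        return {
            "kind": self.kind,
            "fixed": self.fixed.tolist(),
            "fixed_se": self.fixed_se.tolist(),
            "omega": self.omega.tolist(),
            "sigma_eh": self.sigma_eh,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass(frozen=True)
class ResidualSet:
    """Per-individual random-effect predictions (2 or 3 components)."""

    u_hat: np.ndarray  # (J, k)
    inflated: bool
    reference_cov: np.ndarray  # (k, k)


# ---------------------------------------------------------------------------
# sufficient statistics and small-matrix helpers

@dataclass(frozen=True)
class _Stats:
    G: np.ndarray  # (J, 2, 2) = Z_j' Z_j
    Zy: np.ndarray  # (J, 2) = Z_j' h_j
    yy: np.ndarray  # (J,) = h_j' h_j
    bp: np.ndarray | None  # (J,) outcome, bivariate only
    w: np.ndarray  # (J,) frequency weights
    n_occ: int


def _make_stats(data: TrajectoryData, weights=None, with_bp=False) -> _Stats:
    x, y = data.ages, data.heights
    J, I = x.shape
    G = np.empty((J, 2, 2))
    G[:, 0, 0] = I
    G[:, 0, 1] = G[:, 1, 0] = x.sum(axis=1)
    G[:, 1, 1] = (x * x).sum(axis=1)
    Zy = np.stack([y.sum(axis=1), (x * y).sum(axis=1)], axis=1)
    yy = (y * y).sum(axis=1)
    w = np.ones(J) if weights is None else np.asarray(weights, dtype=float)
    return _Stats(G=G, Zy=Zy, yy=yy, bp=data.outcome if with_bp else None,
                  w=w, n_occ=I)


def _inv2(M):
    """Batched 2x2 inverse; M is (..., 2, 2)."""
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    out = np.empty_like(M)
    out[..., 0, 0] = M[..., 1, 1]
    out[..., 1, 1] = M[..., 0, 0]
    out[..., 0, 1] = -M[..., 0, 1]
    out[..., 1, 0] = -M[..., 1, 0]
    return out / det[..., None, None], det


def _chol_from_theta(theta, dim):
    """Lower Cholesky factor with log-parameterised diagonal."""
    L = np.zeros((dim, dim))
    idx = 0
    for i in range(dim):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L


def _theta_from_cov(omega, sigma_eh, dim):
    omega = np.asarray(omega, dtype=float)
    # nudge to PD before factorising
    evals, evecs = np.linalg.eigh(omega)
    floor = max(1e-6, 1e-8 * max(evals.max(), 1.0))
    omega = (evecs * np.clip(evals, floor, None)) @ evecs.T
    L = np.linalg.cholesky(omega)
    theta = []
    for i in range(dim):
        for j in range(i + 1):
            theta.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
    theta.append(np.log(max(sigma_eh, 1e-4)))
    return np.asarray(theta)


def _grad_omega_to_theta(S, L, dim):
    """Chain rule d loglik/d Omega (symmetric S) -> log-Cholesky params."""
    dL = 2.0 * S @ L
    g = []
    for i in range(dim):
        for j in range(i + 1):
            g.append(dL[i, j] * L[i, i] if i == j else dL[i, j])
    return g


def _core(stats: _Stats, omega2, sig2):
    """Woodbury pieces shared by every likelihood evaluation.

    Returns per-individual A_j = Z'V^-1 Z, t_j = Z'V^-1 h, y'V^-1 y,
    log|V_h|, and the posterior 2x2 Sp_j used by the gradient.
    """
    G, Zy, yy, I = stats.G, stats.Zy, stats.yy, stats.n_occ
    o_inv, o_det = _inv2(omega2[None])
    o_inv = o_inv[0]
    if o_det[0] <= 0:
        return None
    B = o_inv[None] + G / sig2
    Sp, _ = _inv2(B)
    GSp = np.einsum("jab,jbc->jac", G, Sp)
    A = (G - np.einsum("jab,jbc->jac", GSp, G) / sig2) / sig2
    t = (Zy - np.einsum("jab,jb->ja", GSp, Zy) / sig2) / sig2
    SpZy = np.einsum("jab,jb->ja", Sp, Zy)
    yVy = yy / sig2 - np.einsum("ja,ja->j", Zy, SpZy) / sig2**2
    # |V_h| = sig2^I * |I2 + omega2 G / sig2|
    M = np.eye(2)[None] + np.einsum("ab,jbc->jac", omega2, G) / sig2
    detM = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(detM <= 0):
        return None
    logdet = I * np.log(sig2) + np.log(detM)
    return A, t, yVy, logdet, Sp, GSp


def _nll_univariate(theta, stats: _Stats, want_grad: bool):
    L = _chol_from_theta(theta, 2)
    omega2 = L @ L.T
    sig2 = np.exp(2.0 * theta[-1])
    core = _core(stats, omega2, sig2)
    if core is None:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    A, t, yVy, logdet, Sp, GSp = core
    w = stats.w
    # profiled GLS fixed effects
    M2 = np.einsum("j,jab->ab", w, A)
    rhs = np.einsum("j,ja->a", w, t)
    beta = np.linalg.solve(M2, rhs)
    Q = float(w @ (yVy - 2.0 * (t @ beta)
                   + np.einsum("a,jab,b->j", beta, A, beta)))
    ntot = w.sum() * stats.n_occ
    ll = -0.5 * (ntot * _LOG2PI + float(w @ logdet) + Q)
    if not want_grad:
        return -ll, beta, M2
    a = t - np.einsum("jab,b->ja", A, beta)  # Z'V^-1 r
    S = 0.5 * (np.einsum("j,ja,jb->ab", w, a, a)
               - np.einsum("j,jab->ab", w, A))
    g_sig2 = _dldsig2_heights(stats, beta, Sp, GSp, sig2, w)
    grad = np.array(_grad_omega_to_theta(S, L, 2) + [g_sig2 * 2.0 * sig2])
    return -ll, -grad


def _dldsig2_heights(stats, beta_h, Sp, GSp, sig2, w, extra=None):
    """d loglik / d sig2 restricted to the height rows.

    ``extra``, when given (bivariate), is the tuple (c, m_over_s2, cKc)
    adding the outcome row's contribution through the Schur complement.
    """
    G, Zy, yy, I = stats.G, stats.Zy, stats.yy, stats.n_occ
    q = Zy - np.einsum("jab,b->ja", G, beta_h)  # Z' r_h
    Spq = np.einsum("jab,jb->ja", Sp, q)
    GSpq = np.einsum("jab,jb->ja", GSp, q)
    rr = yy - 2.0 * (Zy @ beta_h) + np.einsum("a,jab,b->j", beta_h, G, beta_h)
    rP2r = (rr - 2.0 * np.einsum("ja,ja->j", q, Spq) / sig2
            + np.einsum("ja,ja->j", GSpq, Spq) / sig2**2) / sig2**2
    trP = (I - np.einsum("jaa->j", np.einsum("jab,jbc->jac", Sp, G)) / sig2) / sig2
    if extra is None:
        return 0.5 * float(w @ (rP2r - trP))
    c, m_over_s2, s2 = extra
    # Z'P^2 Z = (G - 2 G Sp G / s + G Sp G Sp G / s^2) / s^2   (s = sig2)
    GSpG = np.einsum("jab,jbc->jac", GSp, G)
    K = (G - 2.0 * GSpG / sig2
         + np.einsum("jab,jbc->jac", GSp, GSpG) / sig2**2) / sig2**2
    # Z'P^2 r = (q - 2 G Sp q / s + G Sp G Sp q / s^2) / s^2
    ZP2r = (q - 2.0 * GSpq / sig2
            + np.einsum("jab,jb->ja", GSp, GSpq) / sig2**2) / sig2**2
    cKc = np.einsum("a,jab,b->j", c, K, c)
    cZP2r = ZP2r @ c
    norm_h = rP2r - 2.0 * m_over_s2 * cZP2r + m_over_s2**2 * cKc
    tr_hh = trP + cKc / s2
    return 0.5 * float(w @ (norm_h - tr_hh))


def _nll_bivariate(theta, stats: _Stats, want_grad: bool):
    L = _chol_from_theta(theta, 3)
    omega3 = L @ L.T
    sig2 = np.exp(2.0 * theta[-1])
    omega2 = omega3[:2, :2]
    c = omega3[:2, 2]
    s2bp = omega3[2, 2]
    core = _core(stats, omega2, sig2)
    if core is None:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    A, t, yVy, logdet, Sp, GSp = core
    w, bp = stats.w, stats.bp
    Ac = np.einsum("jab,b->ja", A, c)  # (J, 2)
    s2 = s2bp - Ac @ c  # (J,) Schur complement of the outcome row
    if np.any(s2 <= 0):
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    ytil = bp - t @ c
    # profiled GLS over (beta0, beta1, beta2); xtil = (-A_j c, 1)
    M3 = np.zeros((3, 3))
    M3[:2, :2] = np.einsum("j,jab->ab", w, A)
    ws2 = w / s2
    M3[:2, :2] += np.einsum("j,ja,jb->ab", ws2, Ac, Ac)
    M3[:2, 2] = M3[2, :2] = -np.einsum("j,ja->a", ws2, Ac)
    M3[2, 2] = ws2.sum()
    rhs = np.zeros(3)
    rhs[:2] = np.einsum("j,ja->a", w, t) - np.einsum("j,ja->a", ws2 * ytil, Ac)
    rhs[2] = ws2 @ ytil
    beta = np.linalg.solve(M3, rhs)
    beta_h = beta[:2]
    m = ytil + Ac @ beta_h - beta[2]
    Q = float(w @ (yVy - 2.0 * (t @ beta_h)
                   + np.einsum("a,jab,b->j", beta_h, A, beta_h))
              + ws2 @ (m * m))
    ntot = w.sum() * (stats.n_occ + 1)
    ll = -0.5 * (ntot * _LOG2PI + float(w @ logdet)
                 + float(w @ np.log(s2)) + Q)
    if not want_grad:
        return -ll, beta, M3
    a = t - np.einsum("jab,b->ja", A, beta_h)
    m_over_s2 = m / s2
    # Gtil_j = Ztil' V^-1 rtil, Atil_j = Ztil' V^-1 Ztil (3-dim blocks)
    Gt = np.empty((len(m), 3))
    Gt[:, :2] = a - Ac * m_over_s2[:, None]
    Gt[:, 2] = m_over_s2
    S = np.zeros((3, 3))
    S[:2, :2] = (np.einsum("j,ja,jb->ab", w, Gt[:, :2], Gt[:, :2])
                 - np.einsum("j,jab->ab", w, A)
                 - np.einsum("j,ja,jb->ab", ws2, Ac, Ac))
    S[:2, 2] = S[2, :2] = (np.einsum("j,ja->a", w * m_over_s2, Gt[:, :2])
                           + np.einsum("j,ja->a", ws2, Ac))
    S[2, 2] = w @ (m_over_s2**2) - ws2.sum()
    S *= 0.5
    g_sig2 = _dldsig2_heights(stats, beta_h, Sp, GSp, sig2, w,
                              extra=(c, m_over_s2, s2))
    grad = np.array(_grad_omega_to_theta(S, L, 3) + [g_sig2 * 2.0 * sig2])
    return -ll, -grad


# ---------------------------------------------------------------------------
# public likelihood evaluations (fixed parameters; used by oracles/tests)

def univariate_loglik(data, fixed, omega, sigma_eh, weights=None) -> float:
    """Marginal Gaussian log-likelihood of the growth model at given params."""
    stats = _make_stats(data, weights)
    core = _core(stats, np.asarray(omega, dtype=float), sigma_eh**2)
    if core is None:
        return -np.inf
    A, t, yVy, logdet, _, _ = core
    beta = np.asarray(fixed, dtype=float)
    w = stats.w
    Q = float(w @ (yVy - 2.0 * (t @ beta)
                   + np.einsum("a,jab,b->j", beta, A, beta)))
    ntot = w.sum() * stats.n_occ
    return -0.5 * (ntot * _LOG2PI + float(w @ logdet) + Q)


def bivariate_loglik(data, fixed, omega3, sigma_eh, weights=None) -> float:
    """Joint growth-outcome log-likelihood at given parameters."""
    stats = _make_stats(data, weights, with_bp=True)
    omega3 = np.asarray(omega3, dtype=float)
    sig2 = sigma_eh**2
    core = _core(stats, omega3[:2, :2], sig2)
    if core is None:
        return -np.inf
    A, t, yVy, logdet, _, _ = core
    beta = np.asarray(fixed, dtype=float)
    c = omega3[:2, 2]
    s2 = omega3[2, 2] - np.einsum("jab,a,b->j", A, c, c)
    if np.any(s2 <= 0):
        return -np.inf
    w = stats.w
    ytil = stats.bp - t @ c
    m = ytil + np.einsum("jab,b->ja", A, c) @ beta[:2] - beta[2]
    Q = float(w @ (yVy - 2.0 * (t @ beta[:2])
                   + np.einsum("a,jab,b->j", beta[:2], A, beta[:2]))
              + (w / s2) @ (m * m))
    ntot = w.sum() * (stats.n_occ + 1)
    return -0.5 * (ntot * _LOG2PI + float(w @ logdet)
                   + float(w @ np.log(s2)) + Q)


# ---------------------------------------------------------------------------
# fitting

_MAXITER = 500


def _moment_start(data: TrajectoryData, weights, with_bp: bool):
    """Method-of-moments starting values from per-individual OLS summaries."""
    est = ols_summaries(data)
    b, g = est.b_hat, est.g_hat
    w = np.ones(b.size) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    x, y = data.ages, data.heights
    n = x.shape[1]
    fit = b[:, None] + g[:, None] * x
    rss = ((y - fit) ** 2).sum(axis=1)
    sig2 = max(float((w @ rss) / (wsum * (n - 2))), 1e-6)
    Ginv, _ = _inv2(_make_stats(data).G)
    U = np.stack([b, g], axis=1)
    mu = (w @ U) / wsum
    cov = np.einsum("j,ja,jb->ab", w, U - mu, U - mu) / wsum
    omega2 = cov - sig2 * np.einsum("j,jab->ab", w, Ginv) / wsum
    if not with_bp:
        return omega2, np.sqrt(sig2)
    bp = data.outcome
    mbp = (w @ bp) / wsum
    cvec = np.einsum("j,ja->a", w * (bp - mbp), U - mu) / wsum
    vbp = (w @ (bp - mbp) ** 2) / wsum
    omega3 = np.zeros((3, 3))
    omega3[:2, :2] = omega2
    omega3[:2, 2] = omega3[2, :2] = cvec
    omega3[2, 2] = vbp
    return omega3, np.sqrt(sig2)


def _kernel_args(stats: _Stats, with_bp: bool):
    args = (
        np.ascontiguousarray(stats.G[:, 0, 0]),
        np.ascontiguousarray(stats.G[:, 0, 1]),
        np.ascontiguousarray(stats.G[:, 1, 1]),
        np.ascontiguousarray(stats.Zy[:, 0]),
        np.ascontiguousarray(stats.Zy[:, 1]),
        stats.yy,
    )
    if with_bp:
        args = args + (stats.bp,)
    return args + (stats.w, stats.n_occ)


def _fit(data, weights, kind, start=None):
    from . import _kernels

    with_bp = kind == "bivariate"
    dim = 3 if with_bp else 2
    stats = _make_stats(data, weights, with_bp=with_bp)
    if start is None:
        omega0, sig0 = _moment_start(data, weights, with_bp)
        theta0 = _theta_from_cov(omega0, sig0, dim)
    elif isinstance(start, LmmFit):
        theta0 = _theta_from_cov(start.omega, start.sigma_eh, dim)
    else:
        theta0 = np.asarray(start, dtype=float)
    kernel = _kernels.biv_nll_grad if with_bp else _kernels.uni_nll_grad
    args = _kernel_args(stats, with_bp)

    def fun(theta):
        nll, grad, _, _ = kernel(theta, *args, True)
        return nll, grad

    bounds = []
    for i in range(dim):
        for j in range(i + 1):
            bounds.append((np.log(1e-8), 15.0) if i == j else (None, None))
    bounds.append((np.log(1e-4), 10.0))  # log sigma_eh
    res = minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAXITER, "ftol": 1e-11, "gtol": 1e-4},
    )
    nll, _, beta, M = kernel(res.x, *args, False)
    L = _chol_from_theta(res.x, dim)
    fixed_cov = np.linalg.inv(M)
    return LmmFit(
        kind=kind,
        fixed=beta,
        fixed_se=np.sqrt(np.diag(fixed_cov)),
        omega=L @ L.T,
        sigma_eh=float(np.exp(res.x[-1])),
        loglik=-float(nll),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


def fit_univariate_lmm(data: TrajectoryData, weights=None, start=None) -> LmmFit:
    """ML fit of the random-intercept/random-slope growth model.

    ``weights`` are per-individual frequency weights (bootstrap counts);
    ``start`` may be a previous :class:`LmmFit` for warm starting.
    """
    if data.n_occasions < 2:
        raise ValueError("need at least two occasions per individual")
    return _fit(data, weights, "univariate", start)


def fit_bivariate_lmm(data: TrajectoryData, weights=None, start=None) -> LmmFit:
    """Joint ML fit of the growth model and the distal-outcome equation.

    The stacked response per individual is (heights, outcome); the outcome
    row has no occasion-level residual — its variance and its covariances
    with the growth random effects are the third row of the 3x3 ``omega``.
    """
    return _fit(data, weights, "bivariate", start)


# ---------------------------------------------------------------------------
# BLUPs, re-inflation, estimates

def blup_residuals(fit: LmmFit, data: TrajectoryData, weights=None) -> ResidualSet:
    """Shrunken random-effect predictions, ``Omega Z' V^-1 (y - X beta)``."""
    with_bp = fit.kind == "bivariate"
    if not np.any(fit.omega):  # full-shrinkage limit
        k = 3 if with_bp else 2
        return ResidualSet(
            u_hat=np.zeros((data.n_individuals, k)),
            inflated=False,
            reference_cov=fit.omega.copy(),
        )
    stats = _make_stats(data, weights, with_bp=with_bp)
    sig2 = fit.sigma_eh**2
    omega2 = fit.omega[:2, :2]
    core = _core(stats, omega2, sig2)
    if core is None:
        raise np.linalg.LinAlgError("singular covariance in BLUP computation")
    A, t, _, _, _, _ = core
    beta_h = fit.fixed[:2]
    a = t - np.einsum("jab,b->ja", A, beta_h)
    if not with_bp:
        u = a @ omega2.T
        return ResidualSet(u_hat=u, inflated=False, reference_cov=fit.omega.copy())
    c = fit.omega[:2, 2]
    Ac = np.einsum("jab,b->ja", A, c)
    s2 = fit.omega[2, 2] - Ac @ c
    m = (stats.bp - t @ c) + Ac @ beta_h - fit.fixed[2]
    Gt = np.empty((data.n_individuals, 3))
    Gt[:, :2] = a - Ac * (m / s2)[:, None]
    Gt[:, 2] = m / s2
    u = Gt @ fit.omega.T
    return ResidualSet(u_hat=u, inflated=False, reference_cov=fit.omega.copy())


def _flip_chol(M):
    """Upper-triangular factor U with U U' = M (reverse-order Cholesky)."""
    F = np.arange(M.shape[0])[::-1]
    Lr = np.linalg.cholesky(M[np.ix_(F, F)])
    return Lr[np.ix_(F, F)]


def inflate_residuals(
    res: ResidualSet,
    target_cov: np.ndarray,
    weights=None,
    orientation: str = "lower",
) -> ResidualSet:
    """Re-inflate shrunken residuals so their sample covariance equals
    ``target_cov`` exactly.

    The transform is ``u* = ubar + T (u - ubar)`` with
    ``T = L_target L_sample^{-1}`` built from lower-triangular Cholesky
    factors (sample covariance: mean-centred, denominator J).  With the
    lower orientation the first (birth-length) component of ``u*`` is a
    pure positive rescaling of the input first component.  The ``upper``
    orientation (reverse-order factors, upper-triangular ``T``) is
    provided for the contrast experiment in which the birth-length
    component becomes a mixture and its association is no longer
    preserved.
    """
    if res.inflated:
        raise ValueError("residuals are already inflated")
    target_cov = np.asarray(target_cov, dtype=float)
    u = res.u_hat
    k = u.shape[1]
    if target_cov.shape != (k, k):
        raise ValueError("target_cov order does not match residuals")
    w = np.ones(u.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mean = (w @ u) / wsum
    uc = u - mean
    S = np.einsum("j,ja,jb->ab", w, uc, uc) / wsum
    try:
        if orientation == "lower":
            Lt = np.linalg.cholesky(target_cov)
            Ls = np.linalg.cholesky(S)
        elif orientation == "upper":
            Lt = _flip_chol(target_cov)
            Ls = _flip_chol(S)
        else:
            raise ValueError(f"unknown orientation: {orientation!r}")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sample covariance of residuals is singular; cannot calibrate"
        ) from exc
    T = Lt @ np.linalg.inv(Ls)
    u_star = mean + uc @ T.T
    return ResidualSet(u_hat=u_star, inflated=True, reference_cov=target_cov.copy())


def estimates_from_residuals(fit: LmmFit, res: ResidualSet) -> IndividualEstimates:
    """Add fixed-effect estimates to (possibly inflated) residuals."""
    k = res.u_hat.shape[1]
    if k != fit.fixed.size:
        raise ValueError("residual order does not match fit")
    prefix = "mlm" if fit.kind == "univariate" else "bvm"
    method = f"{prefix}_{'inflated' if res.inflated else 'shrunken'}"
    b = fit.fixed[0] + res.u_hat[:, 0]
    g = fit.fixed[1] + res.u_hat[:, 1]
    bp = fit.fixed[2] + res.u_hat[:, 2] if k == 3 else None
    return IndividualEstimates(method=method, b_hat=b, g_hat=g, bp_hat=bp)


def alpha_from_omega(omega3: np.ndarray):
    """Moment-based association estimates from a 3x3 joint covariance.

    ``(alpha3, alpha4) = Omega_growth^{-1} (sigma_u0BP, sigma_u1BP)`` and
    ``alpha1 = sigma_u0BP / sigma_u0^2``.
    """
    omega3 = np.asarray(omega3, dtype=float)
    block = omega3[:2, :2]
    cvec = omega3[:2, 2]
    det = block[0, 0] * block[1, 1] - block[0, 1] ** 2
    if det <= 0 or block[0, 0] <= 0:
        raise np.linalg.LinAlgError("growth covariance block is singular")
    a34 = np.linalg.solve(block, cvec)
    alpha1 = cvec[0] / block[0, 0]
    return float(alpha1), float(a34[0]), float(a34[1])
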