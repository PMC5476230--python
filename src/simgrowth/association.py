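"""Second-stage outcome regressions and the non-parametric bootstrap.

Every two-stage method ends the same way: regress the distal outcome on
the per-individual birth-length estimate alone (unconditional association
``alpha1``) and on birth length and growth rate together (conditional
associations ``alpha3``, ``alpha4``).  Estimates, classical least-squares
standard errors, and Wald 95% intervals (+/- 1.96 SE) are returned.

For the joint-model path, whose second stage ignores the uncertainty of
the first, :func:`bootstrap_joint` resamples individuals with replacement
and refits the entire pipeline (joint ML fit, BLUPs, simultaneous
re-inflation, second stage) per resample, yielding bootstrap standard
errors and both normal-approximation and percentile intervals.

The regressions are solved by closed-form normal equations with optional
frequency weights: a bootstrap resample is then exactly a weighted fit on
the original individuals, which is what keeps thousands of pipeline
refits affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixed_models import (
    LmmFit,
    blup_residuals,
    estimates_from_residuals,
    fit_bivariate_lmm,
    inflate_residuals,
)
from .simulate import TrajectoryData
from .trajectory_summaries import IndividualEstimates

__all__ = ["AssociationEstimate", "BootstrapResult", "second_stage", "bootstrap_joint"]

_Z95 = 1.96


@dataclass(frozen=True)
class AssociationEstimate:
    parameter: str  # "alpha1" | "alpha3" | "alpha4"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    ci_kind: str = "wald"

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def _wols(X, y, w=None):
    """Weighted least squares with classical SEs (frequency weights)."""
    if w is None:
        Xw = X
        n = float(X.shape[0])
    else:
        Xw = X * w[:, None]
        n = float(w.sum())
    XtX = X.T @ Xw
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("singular second-stage design (collinear summaries?)")
    coef = np.linalg.solve(XtX, Xw.T @ y)
    resid = y - X @ coef
    dof = n - X.shape[1]
    if dof <= 0:
        raise np.linalg.LinAlgError("too few individuals for second-stage SEs")
    s2 = float((resid * resid) @ (np.ones_like(y) if w is None else w)) / dof
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    return coef, se


def second_stage(
    estimates: IndividualEstimates,
    outcome: np.ndarray,
    weights=None,
) -> dict[str, AssociationEstimate]:
    """Run the two second-stage regressions.

    Returns ``{"alpha1": ..., "alpha3": ..., "alpha4": ...}``; ``alpha1``
    comes from the outcome-on-birth-length model, ``alpha3``/``alpha4``
    from the model with both summaries.
    """
    b, g = estimates.b_hat, estimates.g_hat
    outcome = np.asarray(outcome, dtype=float)
    if outcome.shape != b.shape:
        raise ValueError("outcome and estimates are not aligned")
    ones = np.ones_like(b)
    c1, s1 = _wols(np.column_stack([ones, b]), outcome, weights)
    c2, s2 = _wols(np.column_stack([ones, b, g]), outcome, weights)
    out = {}
    for name, est, se in [
        ("alpha1", c1[1], s1[1]),
        ("alpha3", c2[1], s2[1]),
        ("alpha4", c2[2], s2[2]),
    ]:
        out[name] = AssociationEstimate(
            parameter=name,
            estimate=float(est),
            se=float(se),
            ci_low=float(est - _Z95 * se),
            ci_high=float(est + _Z95 * se),
            method=estimates.method,
        )
    return out


def joint_two_stage(
    data: TrajectoryData,
    weights=None,
    start: LmmFit | None = None,
    orientation: str = "lower",
):
    """Full joint-model pipeline: bivariate ML fit, BLUPs, simultaneous
    re-inflation, second stage on the estimated outcome.

    Returns ``(fit, estimates, associations)``; ``associations`` is the
    :func:`second_stage` dict computed with the model-estimated outcome.
    """
    fit = fit_bivariate_lmm(data, weights=weights, start=start)
    res = blup_residuals(fit, data, weights=weights)
    res = inflate_residuals(res, fit.omega, weights=weights, orientation=orientation)
    est = estimates_from_residuals(fit, res)
    assoc = second_stage(est, est.bp_hat, weights=weights)
    return fit, est, assoc


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap summary for the joint-model associations."""

    point: dict[str, float]
    se: dict[str, float]
    n_boot: int
    n_failed: int
    flagged: bool
    samples: np.ndarray  # (n_ok, 2) columns alpha1, alpha4
    method: str = "bvm_inflated"

    def estimate(self, parameter: str, ci_kind: str = "bootstrap_normal"
                 ) -> AssociationEstimate:
        est = self.point[parameter]
        se = self.se[parameter]
        col = {"alpha1": 0, "alpha4": 1}[parameter]
        if ci_kind == "bootstrap_normal":
            lo, hi = est - _Z95 * se, est + _Z95 * se
        elif ci_kind == "bootstrap_percentile":
            lo, hi = np.percentile(self.samples[:, col], [2.5, 97.5])
        else:
            raise ValueError(f"unknown ci_kind: {ci_kind!r}")
        return AssociationEstimate(
            parameter=parameter, estimate=est, se=se,
            ci_low=float(lo), ci_high=float(hi),
            method=self.method, ci_kind=ci_kind,
        )


def bootstrap_joint(
    data: TrajectoryData,
    n_boot: int = 1000,
    seed=0,
    orientation: str = "lower",
) -> BootstrapResult:
    """Non-parametric bootstrap of the joint-model pipeline.

    Individuals are resampled with replacement; each resample refits the
    bivariate model (warm-started from the full-data fit), re-inflates,
    and reruns the second stage.  The SE is the SD of the bootstrap
    estimates.  The result is flagged when more than 10% of resamples
    fail to converge.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    J = data.n_individuals
    fit0, _, assoc0 = joint_two_stage(data, orientation=orientation)
    rng = np.random.default_rng(seed)
    samples = []
    n_failed = 0
    for _ in range(n_boot):
        w = np.bincount(rng.integers(0, J, J), minlength=J).astype(float)
        try:
            fit, _, assoc = joint_two_stage(
                data, weights=w, start=fit0, orientation=orientation
            )
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        samples.append((assoc["alpha1"].estimate, assoc["alpha4"].estimate))
    samples = np.asarray(samples)
    se = {
        "alpha1": float(samples[:, 0].std(ddof=1)) if len(samples) > 1 else 0.0,
        "alpha4": float(samples[:, 1].std(ddof=1)) if len(samples) > 1 else 0.0,
    }
    return BootstrapResult(
        point={"alpha1": assoc0["alpha1"].estimate, "alpha4": assoc0["alpha4"].estimate},
        se=se,
        n_boot=n_boot,
        n_failed=n_failed,
        flagged=n_failed > 0.1 * n_boot,
        samples=samples,
    )
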