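"""Synthetic growth-and-outcome data generator.

Emulates a cohort of ``J`` children each measured for length/height at
``I`` occasions (birth and four childhood visits), followed by a single
adult outcome (systolic blood pressure).  Heights follow a random
intercept / random slope Gaussian growth model,

    H_ij = beta0 + u0j + (beta1 + u1j) * Age_ij + e_ij,

with (u0j, u1j) bivariate normal and i.i.d. occasion-level residuals.
The distal outcome is linear in the *latent* individual deviations,

    BP_j = gamma0 + alpha3 * u0j + alpha4 * u1j + e_BPj,

so the true conditional associations (alpha3, alpha4) — and the implied
unconditional birth-length association — are known exactly, which is what
makes the Monte-Carlo bias/coverage comparisons in :mod:`.experiments`
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "OutcomeParams",
    "AgeSchedule",
    "TrajectoryData",
    "DEFAULT_MEAN_AGES",
    "DEFAULT_AGE_SDS",
    "draw_age_schedule",
    "simulate_trajectories",
    "write_long_csv",
    "read_long_csv",
]

#: Occasion mean ages (years): birth and four childhood visits.
DEFAULT_MEAN_AGES = (0.0, 2.5, 5.0, 7.5, 10.0)

#: Per-occasion SD of measurement age (years).  Birth is tightly
#: scheduled (~95% of births measured within +/- 2 weeks of age 0).
DEFAULT_AGE_SDS = (0.025, 0.5, 0.5, 0.5, 0.5)


class ConfigurationError(ValueError):
    """Invalid simulation configuration (non-PSD covariance, bad grids...)."""


@dataclass(frozen=True)
class GrowthParams:
    """True parameters of the linear growth model.

    Parameters
    ----------
    beta0 : population mean birth length (cm).
    beta1 : population mean linear growth rate (cm/y).
    sigma_u0 : SD of individual birth-length deviations (cm).
    sigma_u1 : SD of individual growth-rate deviations (cm/y).
    rho_u01 : correlation of intercept and slope deviations.
    sigma_eh : occasion-level (measurement) residual SD (cm).
    """

    beta0: float = 50.0
    beta1: float = 9.0
    sigma_u0: float = 2.5
    sigma_u1: float = 0.5
    rho_u01: float = 0.1
    sigma_eh: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_u0 < 0 or self.sigma_u1 < 0 or self.sigma_eh < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if abs(self.rho_u01) > 1:
            raise ConfigurationError("|rho_u01| must not exceed 1")

    @property
    def sigma_u01(self) -> float:
        """Covariance of intercept and slope deviations (cm^2/y)."""
        return self.rho_u01 * self.sigma_u0 * self.sigma_u1

    @property
    def omega(self) -> np.ndarray:
        """2x2 random-effect covariance matrix."""
        return np.array(
            [
                [self.sigma_u0**2, self.sigma_u01],
                [self.sigma_u01, self.sigma_u1**2],
            ]
        )


@dataclass(frozen=True)
class OutcomeParams:
    """True parameters of the distal-outcome model.

    gamma0 is the population mean outcome (mmHg); alpha3 and alpha4 the
    conditional effects of a 1 cm higher birth length and a 1 cm/y faster
    growth rate; sigma_ebp the outcome residual SD (mmHg).
    """

    gamma0: float = 120.0
    alpha3: float = 0.5
    alpha4: float = 2.0
    sigma_ebp: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_ebp < 0:
            raise ConfigurationError("sigma_ebp must be non-negative")


@dataclass(frozen=True)
class AgeSchedule:
    """Realised measurement ages, one row per individual."""

    mean_ages: np.ndarray
    age_sds: np.ndarray
    ages: np.ndarray  # (J, I)

    @property
    def n_individuals(self) -> int:
        return self.ages.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.ages.shape[1]


@dataclass(frozen=True)
class TrajectoryData:
    """A complete simulated (or loaded) dataset.

    ``true_u0``/``true_u1`` hold the realised random effects when the data
    come from the simulator; they are retained for validation/oracle use
    only and are ``None`` for user-supplied data.
    """

    ages: np.ndarray  # (J, I)
    heights: np.ndarray  # (J, I)
    outcome: np.ndarray  # (J,)
    true_u0: np.ndarray | None = field(default=None, repr=False)
    true_u1: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.ages.shape != self.heights.shape:
            raise ValueError("ages and heights must have identical shape")
        if self.outcome.shape != (self.ages.shape[0],):
            raise ValueError("need exactly one outcome value per individual")

    @property
    def n_individuals(self) -> int:
        return self.ages.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.ages.shape[1]


def draw_age_schedule(
    mean_ages=DEFAULT_MEAN_AGES,
    age_sds=DEFAULT_AGE_SDS,
    n_individuals: int = 1000,
    seed=0,
) -> AgeSchedule:
    """Draw per-individual measurement ages.

    Ages at each occasion are independent normals around the occasion
    mean (no covariance between occasions).  Individuals whose drawn ages
    are not strictly increasing are redrawn wholesale, which preserves the
    per-occasion marginal distributions.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    mean_ages = np.asarray(mean_ages, dtype=float)
    age_sds = np.asarray(age_sds, dtype=float)
    if mean_ages.shape != age_sds.shape:
        raise ConfigurationError("mean_ages and age_sds must have equal length")
    if np.any(np.diff(mean_ages) <= 0):
        raise ConfigurationError("mean_ages must be strictly increasing")
    if np.any(age_sds < 0):
        raise ConfigurationError("age_sds must be non-negative")

    rng = np.random.default_rng(seed)
    ages = rng.normal(mean_ages, age_sds, size=(n_individuals, mean_ages.size))
    # Redraw (not sort) rows violating monotonicity; rare under the
    # default schedule (occasion gaps are 5 SDs wide).
    for _ in range(1000):
        bad = np.where(~np.all(np.diff(ages, axis=1) > 0, axis=1))[0]
        if bad.size == 0:
            break
        ages[bad] = rng.normal(mean_ages, age_sds, size=(bad.size, mean_ages.size))
    else:  # pragma: no cover - only reachable with pathological schedules
        raise ConfigurationError("could not draw monotone ages; SDs too large?")
    return AgeSchedule(mean_ages=mean_ages, age_sds=age_sds, ages=ages)


def simulate_trajectories(
    schedule: AgeSchedule,
    growth: GrowthParams = GrowthParams(),
    outcome: OutcomeParams = OutcomeParams(),
    seed=0,
) -> TrajectoryData:
    """Simulate heights and the distal outcome on a fixed age schedule.

    A single master ``seed`` spawns independent sub-streams for the random
    effects, the height residuals and the outcome residuals, so altering
    one noise source never perturbs draws from the others.
    """
    omega = growth.omega
    # Cholesky of a 2x2 PSD matrix, tolerating zero variances.
    try:
        chol = np.linalg.cholesky(omega + 1e-300 * np.eye(2))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("random-effect covariance is not PSD") from exc

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_u, ss_eh, ss_ebp = ss.spawn(3)
    J, I = schedule.ages.shape

    u = np.random.default_rng(ss_u).standard_normal((J, 2)) @ chol.T
    e_h = np.random.default_rng(ss_eh).standard_normal((J, I)) * growth.sigma_eh
    e_bp = np.random.default_rng(ss_ebp).standard_normal(J) * outcome.sigma_ebp

    heights = (
        growth.beta0
        + u[:, [0]]
        + (growth.beta1 + u[:, [1]]) * schedule.ages
        + e_h
    )
    bp = outcome.gamma0 + outcome.alpha3 * u[:, 0] + outcome.alpha4 * u[:, 1] + e_bp
    return TrajectoryData(
        ages=schedule.ages,
        heights=heights,
        outcome=bp,
        true_u0=u[:, 0],
        true_u1=u[:, 1],
    )


# ---------------------------------------------------------------------------
# CSV round trip (long trajectory table + per-individual outcome table)

def write_long_csv(data: TrajectoryData, trajectory_path, outcome_path) -> None:
    """Write ``id,occasion,age,height`` and ``id,bp`` CSV tables."""
    J, I = data.ages.shape
    ids = np.repeat(np.arange(1, J + 1), I)
    occ = np.tile(np.arange(1, I + 1), J)
    pd.DataFrame(
        {
            "id": ids,
            "occasion": occ,
            "age": data.ages.ravel(),
            "height": data.heights.ravel(),
        }
    ).to_csv(trajectory_path, index=False)
    pd.DataFrame({"id": np.arange(1, J + 1), "bp": data.outcome}).to_csv(
        outcome_path, index=False
    )


def read_long_csv(trajectory_path, outcome_path) -> TrajectoryData:
    """Read the long-format trajectory and outcome tables back.

    Validates completeness: every individual must have the same set of
    occasions, strictly increasing ages within individual, and exactly one
    outcome row.
    """
    traj = pd.read_csv(trajectory_path)
    out = pd.read_csv(outcome_path)
    if traj.duplicated(["id", "occasion"]).any():
        dup = traj[traj.duplicated(["id", "occasion"])].iloc[0]
        raise ValueError(
            f"duplicate (id, occasion) row: id={int(dup['id'])}, "
            f"occasion={int(dup['occasion'])}"
        )
    wide_age = traj.pivot(index="id", columns="occasion", values="age").sort_index()
    wide_h = traj.pivot(index="id", columns="occasion", values="height").sort_index()
    if wide_age.isna().any().any() or wide_h.isna().any().any():
        missing = wide_age[wide_age.isna().any(axis=1)].index[0]
        raise ValueError(f"incomplete trajectory for id={int(missing)}")
    ages = wide_age.to_numpy(dtype=float)
    heights = wide_h.to_numpy(dtype=float)
    nonmono = np.where(~np.all(np.diff(ages, axis=1) > 0, axis=1))[0]
    if nonmono.size:
        raise ValueError(
            f"non-monotone ages for id={int(wide_age.index[nonmono[0]])}"
        )
    out = out.set_index("id")["bp"]
    missing_bp = wide_age.index.difference(out.index)
    if len(missing_bp):
        raise ValueError(f"missing outcome for id={int(missing_bp[0])}")
    bp = out.reindex(wide_age.index).to_numpy(dtype=float)
    return TrajectoryData(ages=ages, heights=heights, outcome=bp)
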