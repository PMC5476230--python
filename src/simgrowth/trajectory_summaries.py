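"""First-stage per-individual trajectory summaries (no pooling).

Two estimators of each individual's birth length and growth rate:

* ``simple_summaries`` — birth length is the first observed height, growth
  rate the (last - first) height difference divided by elapsed time;
  intermediate occasions are ignored.
* ``ols_summaries`` — intercept/slope of an ordinary least-squares line
  fitted to each individual's heights on their ages.

Both inherit the height measurement error: their between-individual
variances exceed the true random-effect variances, which is the source of
the attenuation ("regression dilution") the simulation study quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrajectoryData

__all__ = ["IndividualEstimates", "simple_summaries", "ols_summaries"]


@dataclass(frozen=True)
class IndividualEstimates:
    """Per-individual estimated birth length and growth rate.

    ``bp_hat`` (an estimated outcome) is present only for the joint-model
    path, where the second-stage regressions use it in place of the
    observed outcome.
    """

    method: str
    b_hat: np.ndarray
    g_hat: np.ndarray
    bp_hat: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        J = self.b_hat.size
        cols = {
            "id": np.arange(1, J + 1),
            "method": self.method,
            "b_hat": self.b_hat,
            "g_hat": self.g_hat,
        }
        if self.bp_hat is not None:
            cols["bp_hat"] = self.bp_hat
        return pd.DataFrame(cols)


def simple_summaries(data: TrajectoryData) -> IndividualEstimates:
    """Two-point summaries: first height, and (last-first)/elapsed-time."""
    if data.n_occasions < 2:
        raise ValueError("need at least two occasions per individual")
    dt = data.ages[:, -1] - data.ages[:, 0]
    zero = np.where(dt <= 0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"zero elapsed time between first and last occasion for "
            f"individual {zero[0] + 1}"
        )
    b = data.heights[:, 0].copy()
    g = (data.heights[:, -1] - data.heights[:, 0]) / dt
    return IndividualEstimates(method="simple", b_hat=b, g_hat=g)


def ols_summaries(data: TrajectoryData) -> IndividualEstimates:
    """Per-individual least-squares intercept and slope of height on age.

    Closed-form normal equations (two parameters, a handful of points);
    vectorised across individuals.
    """
    x = data.ages
    y = data.heights
    n = x.shape[1]
    xbar = x.mean(axis=1)
    ybar = y.mean(axis=1)
    sxx = ((x - xbar[:, None]) ** 2).sum(axis=1)
    degenerate = np.where(sxx <= 0)[0]
    if degenerate.size:
        raise np.linalg.LinAlgError(
            f"all ages identical for individual {degenerate[0] + 1}; "
            "per-individual regression is singular"
        )
    sxy = ((x - xbar[:, None]) * (y - ybar[:, None])).sum(axis=1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    del n
    return IndividualEstimates(method="ols", b_hat=intercept, g_hat=slope)
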