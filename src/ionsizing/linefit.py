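"""Weighted straight-line fits with x-intercepts, shared by the extrapolations.

Every size extrapolation in the pipeline (conductance vs diameter, diffusivity
vs diameter, threshold current vs activity, zero-activity threshold vs
diameter) is a weighted least-squares line whose x- or y-intercept carries the
physics.  statsmodels WLS supplies the fit and parameter covariance; the
x-intercept standard error follows by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["LineFit", "weighted_line_fit"]


@dataclass(frozen=True)
class LineFit:
    """A fitted line y = intercept + slope * x and derived intercepts."""

    intercept: float
    slope: float
    r_squared: float
    se_intercept: float
    se_slope: float
    x_intercept: float
    se_x_intercept: float
    n: int
    flagged: bool  # nonpositive slope: x-intercept extrapolation unreliable

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def weighted_line_fit(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    min_points: int = 3,
) -> LineFit:
    """WLS line fit; ``weights`` are inverse-variance weights (uniform if None).

    Raises ``ValueError`` for fewer than ``min_points`` points or degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_points:
        raise ValueError(
            f"insufficient data: need at least {min_points} points, got {x.size}"
        )
    if np.unique(x).size < 2:
        raise ValueError("x values must not all coincide")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with at least one positive")

    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    b0, b1 = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params(), dtype=float)
    se0, se1 = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))

    if b1 != 0.0:
        x0 = -b0 / b1
        # delta method: var(x0) = (1/b1^2) var(b0) + (b0/b1^2)^2 var(b1)
        #               - 2 (b0/b1^3) cov(b0,b1)
        var_x0 = (
            cov[0, 0] / b1**2
            + (b0**2 / b1**4) * cov[1, 1]
            - 2.0 * (b0 / b1**3) * cov[0, 1]
        )
        se_x0 = math.sqrt(max(var_x0, 0.0))
    else:
        x0, se_x0 = math.nan, math.nan

    # weighted R^2 (statsmodels reports centered R^2 for WLS directly)
    r2 = float(res.rsquared) if y.size > 2 else 1.0
    if not np.isfinite(r2):
        r2 = 1.0
    r2 = min(max(r2, 0.0), 1.0)

    return LineFit(
        intercept=b0, slope=b1, r_squared=r2, se_intercept=se0, se_slope=se1,
        x_intercept=x0, se_x_intercept=se_x0, n=int(x.size),
        flagged=bool(b1 <= 0.0),
    )
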