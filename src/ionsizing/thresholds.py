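"""Carrier-correlation statistics and the threshold-detection/extrapolation chain.

If the pore current is carried by N ions each contributing a single-carrier
current i with variance <di^2>, the variance of the summed current is the
double sum of the pairwise covariances,

    Var(sum i_n) = <di^2> [ N + N(N-1) xi ],

where xi in [0, 1] is the average pairwise correlation between the
single-carrier spectral densities.  Uncorrelated carriers (xi = 0) give a
normalized noise power S/I^2 ~ N/I0^2 (falling as the inverse square of the
current); fully correlated carriers (xi = 1) give S/I^2 ~ 1, independent of
current.  The current at which the measured normalized pink noise crosses
from the first regime to the second is the correlation threshold I_T.

The sizing chain is: per (pore, salt, concentration) fit (I0^2, S_1/f/I0^2)
piecewise in log-log coordinates -> I_T; regress I_T on activity (n >= 3) ->
zero-activity threshold I_T0; regress I_T0 on pore diameter -> the diameter
at which I_T0 vanishes, the correlation estimate of the de-hydrated ion size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .linefit import LineFit, weighted_line_fit

__all__ = [
    "CarrierEnsembleModel",
    "ThresholdFit",
    "ensemble_variance",
    "normalized_noise_power",
    "fit_threshold",
    "zero_activity_threshold",
    "ion_diameter_from_thresholds",
]


@dataclass(frozen=True)
class CarrierEnsembleModel:
    """N carriers of current i_single, variance var_single, pair correlation xi."""

    N: int
    i_single: float  # pA
    var_single: float  # pA^2
    xi: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("carrier count must be >= 1")
        if self.var_single < 0:
            raise ValueError("single-carrier variance must be >= 0")
        if not (0.0 <= self.xi <= 1.0):
            raise ValueError("xi must lie in [0, 1]")

    @property
    def mean_current(self) -> float:
        return self.N * self.i_single


def ensemble_variance(N: int, var_single: float, xi: float) -> float:
    """Var of the summed carrier current: var_single * [N + N(N-1) xi]."""
    if N < 1 or int(N) != N:
        raise ValueError("carrier count must be a positive integer")
    if var_single < 0:
        raise ValueError("single-carrier variance must be >= 0")
    if not (0.0 <= xi <= 1.0):
        raise ValueError("xi must lie in [0, 1]")
    N = int(N)
    return var_single * (N + N * (N - 1) * xi)


def normalized_noise_power(model: CarrierEnsembleModel) -> float:
    """Var(sum)/(N i)^2: ~1/N when xi = 0, N-independent when xi = 1."""
    if model.i_single == 0:
        raise ValueError("zero mean current: normalized power undefined")
    var = ensemble_variance(model.N, model.var_single, model.xi)
    return var / (model.N * model.i_single) ** 2


@dataclass
class ThresholdFit:
    """Piecewise fit of (I0^2, S_1/f / I0^2) and its downstream extrapolations."""

    present: bool
    I_T: Optional[float]  # pA
    sigma_lt: float  # below-threshold intercept at 1 pA, 1/Hz
    sigma_gt: Optional[float]  # correlated-branch level, 1/Hz
    zeta: float  # free below-threshold log-log slope (target -1)
    rss: float
    n_points: int
    n_below: int
    I_T0: Optional[float] = None  # pA, zero-activity threshold
    R2_activity: Optional[float] = None
    d_ion: Optional[float] = None  # nm
    R2_diameter: Optional[float] = None


def _branch_fit(u: np.ndarray, v: np.ndarray, k: int) -> tuple[float, float, float]:
    """Split at index k: forced slope -1 below, constant above.

    u = log10(I0^2), v = log10(S_1f/I0^2).  Returns (c1, c2, rss) where the
    branches are v = c1 - u and v = c2.
    """
    c1 = float(np.mean(v[:k] + u[:k]))
    c2 = float(np.mean(v[k:]))
    rss = float(np.sum((v[:k] - (c1 - u[:k])) ** 2) + np.sum((v[k:] - c2) ** 2))
    return c1, c2, rss


def _aicc(rss: float, n: int, k: int) -> float:
    if rss <= 1e-300:
        rss = 1e-300
    pen_den = n - k - 1
    pen = 2 * k * (k + 1) / pen_den if pen_den > 0 else math.inf
    return n * math.log(rss / n) + 2 * k + pen


def fit_threshold(
    points: Sequence[tuple[float, float]],
    min_span_decades: float = 1.5,
    rel_tol: float = 1e-3,
    max_iter: int = 50,
) -> ThresholdFit:
    """Detect the correlation threshold from (I0 [pA], S_1/f [pA^2/Hz]) pairs.

    In (u, v) = (log10 I0^2, log10 S_1f/I0^2) coordinates the model is a
    forced slope -1 power law below threshold (S_1f constant) and a constant
    above it (S_1f proportional to I0^2).  All contiguous splits are scanned
    for the minimum residual, the branch intersection is iterated to a fixed
    point, and the two-branch model must beat both single-branch models under
    a small-sample corrected information criterion for the threshold to be
    reported as present.
    """
    pts = sorted((float(i0), float(s)) for i0, s in points)
    i0 = np.array([p[0] for p in pts])
    s1f = np.array([p[1] for p in pts])
    if i0.size < 6:
        raise ValueError(f"need at least 6 points, got {i0.size}")
    if np.any(i0 <= 0) or np.any(s1f <= 0):
        raise ValueError("currents and pink amplitudes must be positive")
    span = math.log10(i0[-1] / i0[0])
    if span < min_span_decades:
        raise ValueError(
            f"I0 span {span:.2f} decades < required {min_span_decades}"
        )

    u = np.log10(i0**2)
    v = np.log10(s1f / i0**2)
    n = i0.size

    # free below-threshold slope diagnostic over the lower half
    half = max(n // 2, 2)
    zeta = float(np.polyfit(u[:half], v[:half], 1)[0])

    # exhaustive scan over contiguous splits (>= 2 points per branch)
    best = None
    for k in range(2, n - 1):
        c1, c2, rss = _branch_fit(u, v, k)
        if best is None or rss < best[2]:
            best = (c1, c2, rss, k)
    c1, c2, rss, _ = best

    # iterate the intersection to a fixed point
    for _ in range(max_iter):
        u_star = c1 - c2
        k = int(np.searchsorted(u, u_star))
        k = min(max(k, 2), n - 2)
        c1_new, c2_new, rss = _branch_fit(u, v, k)
        du = abs((c1_new - c2_new) - u_star)
        c1, c2 = c1_new, c2_new
        if du <= rel_tol * max(abs(u_star), 1.0):
            break

    # Exactly piecewise data is already solved; otherwise refine against the
    # smooth superposition of the two branches, sigma_< / I0^2 + sigma_>,
    # whose asymptotes are the fitted lines.  The hard split ignores the
    # 1/I0^2 tail that the uncorrelated branch contributes above threshold
    # and therefore biases I_T low whenever few points lie far above it.
    if rss > 1e-10 * n:

        def sum_rss(a: float, b: float) -> float:
            model = np.log10(10.0**a / 10.0**u + 10.0**b)
            return float(np.sum((v - model) ** 2))

        def golden(fun, center: float, half_width: float = 1.5) -> float:
            lo, hi = center - half_width, center + half_width
            for _ in range(50):
                m1 = lo + 0.381966 * (hi - lo)
                m2 = hi - 0.381966 * (hi - lo)
                if fun(m1) <= fun(m2):
                    hi = m2
                else:
                    lo = m1
            return 0.5 * (lo + hi)

        for _ in range(max_iter):
            c1_new = golden(lambda x: sum_rss(x, c2), c1)
            c2_new = golden(lambda x: sum_rss(c1_new, x), c2)
            du = abs((c1_new - c2_new) - (c1 - c2))
            c1, c2 = c1_new, c2_new
            if du <= rel_tol:
                break
        rss = sum_rss(c1, c2)

    u_star = c1 - c2
    i_t = 10.0 ** (u_star / 2.0)
    sigma_lt = 10.0**c1
    sigma_gt = 10.0**c2

    # single-branch alternatives: pure power law (S_1f constant) or pure plateau
    c_pow = float(np.mean(v + u))
    rss_pow = float(np.sum((v - (c_pow - u)) ** 2))
    c_flat = float(np.mean(v))
    rss_flat = float(np.sum((v - c_flat) ** 2))

    two_branch_aicc = _aicc(rss, n, 2)
    one_branch_aicc = min(_aicc(rss_pow, n, 1), _aicc(rss_flat, n, 1))
    present = two_branch_aicc < one_branch_aicc
    # a threshold outside the measured range is not a detection
    if not (i0[0] <= i_t <= i0[-1]):
        present = False

    if not present:
        if rss_pow <= rss_flat:
            return ThresholdFit(
                present=False, I_T=None, sigma_lt=10.0**c_pow, sigma_gt=None,
                zeta=zeta, rss=rss_pow, n_points=n, n_below=n,
            )
        return ThresholdFit(
            present=False, I_T=None, sigma_lt=10.0**c_flat, sigma_gt=10.0**c_flat,
            zeta=zeta, rss=rss_flat, n_points=n, n_below=0,
        )

    n_below = int(np.count_nonzero(u < u_star))
    return ThresholdFit(
        present=True, I_T=float(i_t), sigma_lt=float(sigma_lt),
        sigma_gt=float(sigma_gt), zeta=zeta, rss=rss, n_points=n,
        n_below=n_below,
    )


def zero_activity_threshold(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> LineFit:
    """WLS of I_T [pA] on activity [M]; the intercept at a = 0 is I_T0.

    Requires n >= 3 distinct activities (the printed rule); the slope is
    expected positive (the threshold grows with activity).
    """
    a, i_t = zip(*points)
    if len(set(a)) < 3:
        raise ValueError("need thresholds at n >= 3 distinct activities")
    return weighted_line_fit(a, i_t, weights, min_points=3)


def ion_diameter_from_thresholds(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> LineFit:
    """WLS of I_T0 [pA] on pore diameter [nm]; x-intercept is the ion diameter."""
    d, i_t0 = zip(*points)
    if len(set(d)) < 3:
        raise ValueError("need zero-activity thresholds for >= 3 distinct diameters")
    return weighted_line_fit(d, i_t0, weights, min_points=3)
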