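"""PSD estimation and pink/white/dielectric noise decomposition.

The low-frequency current noise of a voltage-clamped sub-nanopore is
classified by fitting the one-sided power spectral density to

    S_I(f) = S_1/f * (1/f) + S_0 + S_1 * f + ...

The pink amplitude S_1/f is the 1 Hz intercept of a forced-slope (-1) log-log
fit, preferentially weighted toward low frequencies (w(f) = f^-1/2, i.e. the
weight drops one order of magnitude every two decades so no hard upper
frequency cutoff is needed).  The white level S_0 is the mean logarithmic
(geometric-mean) PSD over the 1-5 kHz band where pink noise is not evident.
The two-component split is iterated to a fixed point of the piecewise fit;
the crossover frequency is f* = S_1/f / S_0.

Whether a pink component is present at all is decided by a small-sample
corrected information criterion comparing the pink+white model against a
white-only model, so a purely white trace reports S_1/f = 0 instead of a
spurious positive intercept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal

__all__ = [
    "CurrentTrace",
    "PSDSpectrum",
    "SpectralDecomposition",
    "expunge_settling",
    "compute_psd",
    "fit_decomposition",
    "fit_free_beta",
    "pink_weight",
]

DURATION_RANGE_S = (60.0, 300.0)
BETA_ACCEPT_RANGE = (0.5, 1.6)
S0_BAND_HZ = (1000.0, 5000.0)
DIELECTRIC_BAND_HZ = (5000.0, 50000.0)
BETA_BAND_HZ = (0.1, 100.0)


@dataclass
class CurrentTrace:
    """One voltage-clamp recording: samples in pA plus condition metadata."""

    samples: np.ndarray  # pA
    fs: float  # Hz
    v_bias: float  # V
    condition: object | None = None  # ElectrolyteCondition
    pore: object | None = None  # PoreModel
    t_start_offset: float = 0.0  # settling seconds already removed
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")

    @property
    def i0(self) -> float:
        """Mean open-pore current, pA."""
        return float(np.mean(self.samples))

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def validate(self) -> None:
        """Warn when the duration falls outside the standard recording range."""
        lo, hi = DURATION_RANGE_S
        if not (lo <= self.duration <= hi):
            warnings.warn(
                f"trace duration {self.duration:.1f} s outside the "
                f"[{lo:.0f}, {hi:.0f}] s recording range",
                stacklevel=2,
            )


def expunge_settling(trace: CurrentTrace, t_settle: float = 15.0) -> CurrentTrace:
    """Drop the first ``t_settle`` seconds (capacitive settling after a bias step)."""
    if t_settle < 0:
        raise ValueError("settling time must be non-negative")
    n_drop = int(round(t_settle * trace.fs))
    if n_drop >= trace.samples.size:
        raise ValueError(
            f"trace ({trace.duration:.1f} s) shorter than the {t_settle} s "
            "settling window"
        )
    return replace(
        trace,
        samples=trace.samples[n_drop:],
        t_start_offset=trace.t_start_offset + n_drop / trace.fs,
    )


@dataclass(frozen=True)
class PSDSpectrum:
    """One-sided PSD in pA^2/Hz with its frequency grid."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # pA^2/Hz
    df: float
    fs: float
    n_segments: int

    @property
    def f_max(self) -> float:
        return float(self.freqs[-1])


def compute_psd(
    trace: CurrentTrace, f_resolution: float = 0.1, nperseg: int | None = None
) -> PSDSpectrum:
    """Averaged modified periodograms (Hann, 50% overlap), one-sided pA^2/Hz.

    The segment length is the smallest power of two whose bin width
    fs/nperseg does not exceed ``f_resolution`` (maximizing the number of
    averaged segments at that resolution).  A trace too short for one such
    segment raises an error naming the minimum length.
    """
    n = trace.samples.size
    if nperseg is None:
        if f_resolution <= 0:
            raise ValueError("frequency resolution must be positive")
        nperseg = 1 << math.ceil(math.log2(trace.fs / f_resolution))
    if n < nperseg:
        raise ValueError(
            f"trace too short for {f_resolution} Hz resolution at "
            f"fs={trace.fs:.0f} Hz: need at least {nperseg} samples, got {n}"
        )
    freqs, psd = signal.welch(
        trace.samples,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    n_segments = 1 + (n - nperseg) // (nperseg // 2)
    # drop the DC bin: the mean current is not noise
    return PSDSpectrum(
        freqs=freqs[1:], psd=psd[1:], df=float(freqs[1] - freqs[0]),
        fs=trace.fs, n_segments=n_segments,
    )


@dataclass
class SpectralDecomposition:
    """Pink/white/dielectric decomposition of one trace's PSD."""

    S_1f: float  # pink amplitude at 1 Hz, pA^2/Hz (0 if no pink component)
    S_0: float  # white level, pA^2/Hz
    S_1: Optional[float]  # dielectric coefficient, pA^2/Hz^2, or None
    beta_free: float  # free-fit low-frequency exponent magnitude
    f_cross: float  # pink/white crossover, Hz (S_1f / S_0)
    residual: float  # weighted RSS of the forced-slope pink fit
    pink_present: bool
    converged: bool
    accepted: bool  # beta_free within the accepted range
    psd_freqs: np.ndarray = field(repr=False)
    psd_values: np.ndarray = field(repr=False)


def pink_weight(f: np.ndarray | float) -> np.ndarray | float:
    """Low-frequency-preferential fit weight w(f) = (f / 1 Hz)^(-1/2).

    Drops one order of magnitude every two decades: w(1 Hz)/w(100 Hz) = 10.
    """
    return np.asarray(f, dtype=float) ** -0.5


def _forced_slope_intercept(
    f: np.ndarray, log10_psd: np.ndarray, w: np.ndarray | None = None
) -> tuple[float, float]:
    """Weighted forced-slope(-1) fit: returns (log10 S_1f, weighted RSS)."""
    if w is None:
        w = pink_weight(f)
    c = float(np.sum(w * (log10_psd + np.log10(f))) / np.sum(w))
    resid = log10_psd - (c - np.log10(f))
    return c, float(np.sum(w * resid**2))


def _log_binned(
    f: np.ndarray, logp: np.ndarray, per_decade: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric-mean PSD in log-spaced frequency bins.

    Returns (bin center frequencies, mean log10 PSD, summed pink weight per
    bin) so downstream fits keep the printed w(f) = f^-1/2 weighting while
    operating on a few hundred points instead of ~1e5 raw bins.
    """
    logf = np.log10(f)
    edges = np.arange(
        math.floor(logf[0] * per_decade), math.ceil(logf[-1] * per_decade) + 1
    )
    idx = np.digitize(logf * per_decade, edges)
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    bounds = np.searchsorted(idx_s, np.unique(idx_s))
    bounds = np.append(bounds, idx_s.size)
    centers, means, weights = [], [], []
    w_all = pink_weight(f)
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = order[a:b]
        centers.append(10.0 ** float(np.mean(logf[sel])))
        means.append(float(np.mean(logp[sel])))
        weights.append(float(np.sum(w_all[sel])))
    return np.array(centers), np.array(means), np.array(weights)


def _geometric_mean_band(
    freqs: np.ndarray, log10_psd: np.ndarray, band: tuple[float, float]
) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(
            f"no positive-frequency bins in the {band[0]}-{band[1]} Hz band"
        )
    return 10.0 ** float(np.mean(log10_psd[mask]))


def fit_decomposition(
    spectrum: PSDSpectrum,
    f_split_init: float = 100.0,
    max_iter: int = 50,
    rel_tol: float = 1e-3,
) -> SpectralDecomposition:
    """Decompose a spectrum into S_1/f, S_0 (and S_1 when present).

    The split between the forced-slope pink branch and the white level is
    refined iteratively: starting from the naive forced-slope fit below
    ``f_split_init``, the amplitude of the full model S_1f/f + S_0 (whose
    branches intersect at f* = S_1f/S_0) is re-fit with the printed w(f)
    weights until the intersection reaches a fixed point (relative change
    < ``rel_tol``).  Fitting the summed model rather than a hard two-line
    split removes the bias a sharp cutoff introduces near the crossover.
    """
    f = spectrum.freqs
    p = spectrum.psd
    ok = p > 0
    f, p = f[ok], p[ok]
    if f.size < 8:
        raise ValueError("spectrum has too few positive bins to decompose")
    logp = np.log10(p)

    s0 = _geometric_mean_band(f, logp, S0_BAND_HZ)

    # log-binned spectrum below the white-estimation band upper edge
    fit_band = f <= S0_BAND_HZ[1]
    fb, yb, wb = _log_binned(f[fit_band], logp[fit_band])
    log_s0 = math.log10(s0)

    # initial pink intercept: forced-slope fit below the initial split
    mask0 = fb <= max(f_split_init, 4.0 * spectrum.df, float(fb[0]) * 4.0)
    if np.count_nonzero(mask0) < 2:
        mask0 = np.ones_like(fb, dtype=bool)
    c, _ = _forced_slope_intercept(fb[mask0], yb[mask0], wb[mask0])

    def weighted_rss(log_a: float, log_s0: float) -> float:
        model = np.log10(10.0**log_a / fb + 10.0**log_s0)
        return float(np.sum(wb * (yb - model) ** 2))

    def golden(fun, center: float, half_width: float) -> float:
        lo, hi = center - half_width, center + half_width
        for _ in range(50):
            m1 = lo + 0.381966 * (hi - lo)
            m2 = hi - 0.381966 * (hi - lo)
            if fun(m1) <= fun(m2):
                hi = m2
            else:
                lo = m1
        return 0.5 * (lo + hi)

    # iterate the two-component split to a fixed point of the intersection
    # f* = S_1f / S_0, alternating the pink intercept and the white level
    # (the geometric-mean S_0 above is the initial white line)
    log_s0 = log_s0_init = math.log10(s0)
    converged = False
    for _ in range(max_iter):
        f_cross_old = 10.0**c / 10.0**log_s0
        c = golden(lambda v: weighted_rss(v, log_s0), c, 2.0)
        log_s0 = golden(
            lambda v: weighted_rss(c, v),
            min(max(log_s0, log_s0_init - 1.5), log_s0_init + 1.5),
            1.5,
        )
        f_cross_new = 10.0**c / 10.0**log_s0
        if abs(f_cross_new - f_cross_old) <= rel_tol * max(f_cross_old, 1e-12):
            converged = True
            break
    s1f = 10.0**c
    s0 = 10.0**log_s0
    resid = weighted_rss(c, log_s0)

    # presence: pink+white model vs white-only, AICc on binned log residuals
    n_band = fb.size
    rss_pw = float(np.sum((yb - np.log10(s1f / fb + s0)) ** 2))
    s0_only = 10.0 ** float(np.mean(yb))
    rss_white = float(np.sum((yb - math.log10(s0_only)) ** 2))

    def _aicc(rss: float, k: int) -> float:
        if rss <= 0:
            return -math.inf
        return n_band * math.log(rss / n_band) + 2 * k + (
            2 * k * (k + 1) / max(n_band - k - 1, 1)
        )

    pink_present = _aicc(rss_pw, 2) < _aicc(rss_white, 1)
    if not pink_present:
        s1f = 0.0
        converged = True  # the white-only model needs no split iteration

    # dielectric term: only when the high band rises with frequency
    s1: Optional[float] = None
    hi = (f >= DIELECTRIC_BAND_HZ[0]) & (f <= DIELECTRIC_BAND_HZ[1])
    if np.count_nonzero(hi) >= 4:
        slope = np.polyfit(np.log10(f[hi]), logp[hi], 1)[0]
        if slope > 0:
            s1_est = float(np.mean((p[hi] - s0) / f[hi]))
            s1 = max(s1_est, 0.0)

    beta = fit_free_beta(spectrum)
    lo, hi_b = BETA_ACCEPT_RANGE
    return SpectralDecomposition(
        S_1f=s1f,
        S_0=s0,
        S_1=s1,
        beta_free=beta,
        f_cross=s1f / s0 if s0 > 0 else math.inf,
        residual=resid,
        pink_present=pink_present,
        converged=converged,
        accepted=bool(lo <= beta <= hi_b) if pink_present else True,
        psd_freqs=spectrum.freqs,
        psd_values=spectrum.psd,
    )


def fit_free_beta(
    spectrum: PSDSpectrum, band: tuple[float, float] = BETA_BAND_HZ
) -> float:
    """Unweighted log-log slope magnitude over ``band`` (the free exponent)."""
    f, p = spectrum.freqs, spectrum.psd
    mask = (f >= band[0]) & (f <= band[1]) & (p > 0)
    if np.count_nonzero(mask) < 2:
        raise ValueError(f"no usable bins in the {band[0]}-{band[1]} Hz band")
    slope = np.polyfit(np.log10(f[mask]), np.log10(p[mask]), 1)[0]
    return float(-slope)
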