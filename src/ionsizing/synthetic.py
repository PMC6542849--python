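"""Synthetic voltage-clamp traces with planted noise structure.

Everything the analysis pipeline consumes can be generated here with known
ground truth: pure power-law (pink) noise of chosen 1 Hz amplitude and
exponent, exactly-correlated carrier ensembles, and full multi-condition
experiments in which a de-hydrated ion diameter is planted through the
empirical threshold law

    I_T(d, a) = s_slope * (d - d_ion_true) * (1 + k_activity * a),

so the threshold grows with activity and diameter and vanishes at
d = d_ion_true.  Below threshold the pink amplitude is the uncorrelated
carrier sum (proportional to N <di^2>); above it the amplitude rises as the
fully correlated N^2 limit, i.e. S_1/f crosses from a current-independent
level to one growing as I0^2.  The correlation switch is a narrow logistic
in log10(I0) (width 0.1 decade) rather than a hard step.

Every output is a pure function of (plan, seed); manifests embed the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .electrolyte import ElectrolyteCondition, bulk_conductivity
from .noise import CurrentTrace
from .pore import PoreModel, biconical_volume, expected_ion_count, point_contact_conductance
from .thresholds import ensemble_variance

__all__ = [
    "ExperimentPlan",
    "gen_pink_noise",
    "gen_white_noise",
    "gen_correlated_carriers",
    "gen_experiment",
    "experiment_manifest",
    "ION_TO_SALT",
    "PLANTED_DIAMETERS",
]

ION_TO_SALT = {"Li": "LiCl", "Na": "NaCl", "K": "KCl", "Cs": "CsCl", "Mg": "MgCl2"}

# planted "true" diameters for the four study cations (nm): the correlation
# sizes the pipeline is asked to recover, ordered Li < Mg < Na < K
PLANTED_DIAMETERS = {"Li": 0.13, "Mg": 0.16, "Na": 0.22, "K": 0.25}

XI_SWITCH_WIDTH_DECADES = 0.1


@lru_cache(maxsize=8)
def _pink_scale(n_samples: int, fs: float, beta: float) -> np.ndarray:
    """Unit-amplitude spectral scale sqrt(f^-beta * fs * n / 2), cached."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    target = np.zeros_like(freqs)
    target[1:] = freqs[1:] ** (-beta)
    return np.sqrt(target * fs * n_samples / 2.0)


def gen_pink_noise(
    n_samples: int,
    fs: float,
    S1Hz: float,
    beta: float = 1.0,
    seed: int | np.random.Generator = 0,
    dtype=np.float64,
) -> np.ndarray:
    """Spectral-synthesis power-law noise with one-sided PSD S1Hz * f^-beta.

    Amplitudes scale as f^(-beta/2) with independent random phases; the DC
    bin is zeroed.  Identical seeds give bit-identical traces.  ``dtype``
    float32 halves the synthesis cost for bulk experiment generation.
    """
    if not (0.0 <= beta <= 2.0):
        raise ValueError("beta must lie in [0, 2]")
    if S1Hz < 0:
        raise ValueError("S1Hz must be non-negative")
    if S1Hz == 0.0:
        return np.zeros(n_samples, dtype=dtype)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = _pink_scale(n_samples, float(fs), float(beta)) * math.sqrt(S1Hz)
    n_bins = scale.size
    if dtype == np.float32:
        scale = scale.astype(np.float32)
        re = rng.standard_normal(n_bins, dtype=np.float32)
        im = rng.standard_normal(n_bins, dtype=np.float32)
        spec = (scale / np.float32(math.sqrt(2.0))) * (re + 1j * im)
    else:
        re = rng.standard_normal(n_bins)
        im = rng.standard_normal(n_bins)
        spec = scale * (re + 1j * im) / math.sqrt(2.0)
    spec[0] = 0.0
    if n_samples % 2 == 0:
        # Nyquist bin is real and carries no one-sided doubling
        spec[-1] = scale[-1] * math.sqrt(2.0) * re[-1]
    return np.fft.irfft(spec, n_samples).astype(dtype, copy=False)


def gen_white_noise(
    n_samples: int,
    fs: float,
    S0: float,
    seed: int | np.random.Generator = 0,
    dtype=np.float64,
) -> np.ndarray:
    """Gaussian white noise with one-sided PSD level S0 (pA^2/Hz)."""
    if S0 < 0:
        raise ValueError("S0 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = math.sqrt(S0 * fs / 2.0)
    if dtype == np.float32:
        return rng.standard_normal(n_samples, dtype=np.float32) * np.float32(sd)
    return rng.standard_normal(n_samples) * sd


def gen_correlated_carriers(
    N: int,
    i_single: float,
    var_single: float,
    xi: float,
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> CurrentTrace:
    """Sum of N carrier currents with exact pairwise correlation xi.

    Mixture construction: i_n(t) = i + sqrt(xi) s(t) + sqrt(1-xi) e_n(t) with
    s and e_n independent zero-mean processes of variance var_single, so
    every pair correlates at exactly xi and the summed variance equals
    var_single [N + N(N-1) xi].
    """
    if not (0.0 <= xi <= 1.0):
        raise ValueError("xi must lie in [0, 1]")
    if N < 1:
        raise ValueError("carrier count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = math.sqrt(var_single)
    shared = rng.standard_normal(n_samples) * sd
    total = np.full(n_samples, N * i_single, dtype=float)
    total += N * math.sqrt(xi) * shared
    for _ in range(N):
        total += math.sqrt(1.0 - xi) * rng.standard_normal(n_samples) * sd
    return CurrentTrace(samples=total, fs=fs, v_bias=0.0, trace_id="carriers")


@dataclass
class ExperimentPlan:
    """Study conditions for one planted-ion synthetic experiment.

    Defaults are the standard conditions: four concentrations at or below
    500 mM, five waist diameters spanning the fabricated range, eight biases
    spanning ~1.8 decades of open-pore current, 2^20-sample traces at 25 kHz
    (41.9 s) so the PSD resolves 0.1 Hz while staying cheap to synthesize.
    """

    ion: str = "Na"
    d_ion_true: float | None = None  # nm; defaults to PLANTED_DIAMETERS[ion]
    diameters: tuple = (0.35, 0.47, 0.62, 0.78, 0.97)
    concentrations: tuple = (0.125, 0.25, 0.375, 0.5)  # M
    voltages: tuple = tuple(np.geomspace(0.01, 0.6, 8).round(6))  # V
    s_slope: float = 300.0  # pA/nm: threshold sensitivity to diameter
    k_activity: float = 1.0  # 1/M: threshold sensitivity to activity
    S0: float = 5e-3  # white level, pA^2/Hz
    # below-threshold pink amplitude per carrier: places the pink/white
    # crossover at tens of Hz (pink evident over 0.1-100 Hz, white above)
    pink_per_carrier: float = 0.05
    theta: float = 15.0  # cone half-angle, degrees
    t_mem: float = 10.0  # nm
    beta: float = 1.0
    n_samples: int = 1 << 20
    fs: float = 25000.0
    activity_model: str = "TJ"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ion not in ION_TO_SALT:
            raise ValueError(f"unknown ion {self.ion!r}")
        if self.d_ion_true is None:
            self.d_ion_true = PLANTED_DIAMETERS.get(self.ion, 0.2)
        if not self.diameters or not self.concentrations or not self.voltages:
            raise ValueError("diameters, concentrations and voltages must be non-empty")
        if self.d_ion_true >= min(self.diameters):
            raise ValueError("planted ion diameter must be below every pore diameter")

    @property
    def salt(self) -> str:
        return ION_TO_SALT[self.ion]

    def threshold_current(self, d_mean: float, a: float) -> float:
        """Planted law I_T = s (d - d_ion) (1 + k a), pA."""
        return self.s_slope * (d_mean - self.d_ion_true) * (
            1.0 + self.k_activity * a
        )


def _xi_of_current(i0: float, i_t: float) -> float:
    """Correlation switch: logistic in log10 I0, width 0.1 decade."""
    if i0 <= 0:
        return 0.0
    return float(expit((math.log10(i0) - math.log10(i_t)) / XI_SWITCH_WIDTH_DECADES))


def _condition_rows(plan: ExperimentPlan) -> list[dict]:
    rows = []
    idx = 0
    for d in plan.diameters:
        pore_id = f"{plan.ion}_d{d:.2f}"
        vol = biconical_volume(d, plan.theta, plan.t_mem)
        for C in plan.concentrations:
            cond = ElectrolyteCondition.from_salt(plan.salt, C, plan.activity_model)
            sigma = bulk_conductivity(cond)
            g = point_contact_conductance(sigma, d)
            n_carriers = max(expected_ion_count(vol, C), 1.0)
            i_t = plan.threshold_current(d, cond.a)
            for V in plan.voltages:
                i0 = g * V * 1e12  # pA
                xi = _xi_of_current(i0, i_t)
                s1f_below = plan.pink_per_carrier * n_carriers
                if i0 == 0.0:
                    s1f = 0.0
                elif i_t > 0:
                    s1f = s1f_below * (1.0 + xi * (i0 / i_t) ** 2)
                else:
                    s1f = s1f_below
                rows.append(dict(
                    trace_id=f"{pore_id}_C{C:g}_V{V:g}_s{plan.seed}",
                    index=idx, pore_id=pore_id, ion=plan.ion, salt=plan.salt,
                    d_mean=d, theta=plan.theta, t_mem=plan.t_mem,
                    C_M=C, a_M=cond.a, V_bias=V, fs=plan.fs,
                    n_samples=plan.n_samples, seed=plan.seed,
                    I0_true_pA=i0, I_T_true_pA=i_t, N_carriers=n_carriers,
                    xi_true=xi, S1f_true=s1f, S0_true=plan.S0,
                ))
                idx += 1
    return rows


def experiment_manifest(plan: ExperimentPlan) -> pd.DataFrame:
    """Per-trace condition table (with planted truth columns) for a plan."""
    return pd.DataFrame(_condition_rows(plan))


def gen_experiment(plan: ExperimentPlan) -> Iterator[tuple[dict, CurrentTrace]]:
    """Yield (manifest row, trace) pairs lazily (traces are large).

    Each trace is mean current I0 plus planted pink noise of amplitude
    S1f_true (exponent beta) plus white noise at S0; its own RNG stream is
    derived from (plan.seed, trace index) so regeneration is reproducible
    trace by trace.
    """
    for row in _condition_rows(plan):
        rng = np.random.default_rng([plan.seed, row["index"]])
        # float32 is ample for PSD work at the few-percent level and halves
        # the cost of bulk generation
        samples = np.full(plan.n_samples, row["I0_true_pA"], dtype=np.float32)
        if row["S1f_true"] > 0:
            samples += gen_pink_noise(
                plan.n_samples, plan.fs, row["S1f_true"], plan.beta, rng,
                dtype=np.float32,
            )
        samples += gen_white_noise(
            plan.n_samples, plan.fs, plan.S0, rng, dtype=np.float32
        )
        cond = ElectrolyteCondition.from_salt(
            plan.salt, row["C_M"], plan.activity_model
        )
        pore = PoreModel(
            d_minor=row["d_mean"], d_major=row["d_mean"], theta=plan.theta,
            t_mem=plan.t_mem, pore_id=row["pore_id"],
        )
        trace = CurrentTrace(
            samples=samples, fs=plan.fs, v_bias=row["V_bias"],
            condition=cond, pore=pore, trace_id=row["trace_id"],
        )
        yield row, trace
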