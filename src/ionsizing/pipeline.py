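"""End-to-end orchestration: traces -> decompositions -> thresholds -> ion sizes.

The four processing steps compose as: (1) expunge settling and estimate the
PSD of every trace, decomposing it into S_1/f and S_0; (2) per (pore, salt,
concentration) series, fit the piecewise (I0^2, S_1/f/I0^2) model for the
threshold current I_T; (3) per pore, regress I_T on activity (n >= 3
activities enforced) and extrapolate to the zero-activity threshold I_T0;
(4) per ion, regress I_T0 on pore diameter and report the diameter at which
I_T0 vanishes.  Inverse-variance weights propagate between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .electrolyte import activity
from .linefit import LineFit, weighted_line_fit
from .noise import CurrentTrace, compute_psd, expunge_settling, fit_decomposition
from .synthetic import ExperimentPlan, gen_experiment
from .thresholds import (
    ThresholdFit,
    fit_threshold,
    ion_diameter_from_thresholds,
    zero_activity_threshold,
)

logger = logging.getLogger("ionsizing")

__all__ = [
    "AnalysisConfig",
    "IonSizeReport",
    "analyze_trace",
    "analyze_records",
    "run_ion_sizing",
    "run_synthetic_ion_sizing",
    "run_conductance_sizing",
    "threshold_standard_error",
]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the four-step pipeline (all units as noted)."""

    psd_resolution_hz: float = 0.1
    settle_s: float = 15.0
    activity_model: str = "TJ"  # EDH or TJ
    f_split_init_hz: float = 100.0
    fit_rel_tol: float = 1e-3
    fit_max_iter: int = 50
    min_span_decades: float = 1.5
    min_activities: int = 3
    weights_policy: str = "inverse_variance"  # or "uniform"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.psd_resolution_hz <= 0 or self.fit_rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.weights_policy not in ("inverse_variance", "uniform"):
            raise ValueError("weights_policy must be inverse_variance or uniform")
        if self.activity_model not in ("EDH", "TJ"):
            raise ValueError("activity_model must be EDH or TJ")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def threshold_standard_error(fit: ThresholdFit) -> float:
    """Approximate standard error of I_T from the piecewise-fit residuals.

    var(log10 I_T^2) = s^2 (1/n_below + 1/n_above) with s^2 the residual
    variance; the delta method converts to the current scale.
    """
    if not fit.present or fit.I_T is None:
        return math.inf
    n_above = fit.n_points - fit.n_below
    if fit.n_below < 1 or n_above < 1 or fit.n_points <= 2:
        return math.inf
    s2 = fit.rss / max(fit.n_points - 2, 1)
    var_u = s2 * (1.0 / fit.n_below + 1.0 / n_above)
    se_log10_it = math.sqrt(var_u) / 2.0
    return fit.I_T * math.log(10.0) * se_log10_it


def analyze_trace(trace: CurrentTrace, config: AnalysisConfig) -> dict:
    """Settle-expunge, PSD, and pink/white decomposition of one trace."""
    if config.settle_s > 0:
        trace = expunge_settling(trace, config.settle_s)
    spectrum = compute_psd(trace, f_resolution=config.psd_resolution_hz)
    dec = fit_decomposition(
        spectrum,
        f_split_init=config.f_split_init_hz,
        max_iter=config.fit_max_iter,
        rel_tol=config.fit_rel_tol,
    )
    return dict(
        trace_id=trace.trace_id,
        I0_pA=trace.i0,
        S1f=dec.S_1f,
        S0=dec.S_0,
        beta_free=dec.beta_free,
        f_cross=dec.f_cross,
        pink_present=dec.pink_present,
        converged=dec.converged,
    )


@dataclass
class IonSizeReport:
    """Full provenance-carrying output of the ion-sizing pipeline."""

    per_trace: pd.DataFrame
    per_series: pd.DataFrame  # one row per (pore, salt, C): threshold fits
    per_pore: pd.DataFrame  # one row per (pore, salt): I_T0 extrapolations
    per_ion: dict  # salt -> {d_ion, se, slope, r_squared, n_pores}
    config: dict
    version: str = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(
            version=self.version,
            config=self.config,
            per_ion=self.per_ion,
            per_trace=self.per_trace.to_dict(orient="records"),
            per_series=self.per_series.to_dict(orient="records"),
            per_pore=self.per_pore.to_dict(orient="records"),
        )
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IonSizeReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            per_trace=pd.DataFrame(payload["per_trace"]),
            per_series=pd.DataFrame(payload["per_series"]),
            per_pore=pd.DataFrame(payload["per_pore"]),
            per_ion=payload["per_ion"],
            config=payload["config"],
            version=payload["version"],
        )

    def write_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_trace.to_csv(outdir / "decompositions.csv", index=False)
        self.per_series.to_csv(outdir / "thresholds.csv", index=False)
        self.per_pore.to_csv(outdir / "zero_activity_thresholds.csv", index=False)
        self.to_json(outdir / "ion_size_report.json")


def analyze_records(
    records: Iterable[tuple[dict, CurrentTrace]], config: AnalysisConfig
) -> IonSizeReport:
    """Run the four-step chain on (metadata, trace) pairs.

    Metadata must carry pore_id, salt, C_M, a_M, d_mean and V_bias.  Traces
    are consumed lazily so datasets larger than memory stream through.
    """
    trace_rows = []
    for meta, trace in records:
        row = analyze_trace(trace, config)
        row.update(
            pore_id=meta["pore_id"], salt=meta["salt"], C_M=meta["C_M"],
            a_M=meta["a_M"], d_mean=meta["d_mean"], V_bias=meta["V_bias"],
        )
        trace_rows.append(row)
    per_trace = pd.DataFrame(trace_rows)
    if per_trace.empty:
        raise ValueError("no traces to analyze")

    series_rows = []
    for (pore_id, salt, c_m), grp in per_trace.groupby(["pore_id", "salt", "C_M"]):
        pts = grp[(grp.S1f > 0) & (grp.I0_pA > 0)]
        if len(pts) < 6:
            logger.warning(
                "series %s/%s/%.3g M: only %d usable traces, skipped",
                pore_id, salt, c_m, len(pts),
            )
            continue
        try:
            tf = fit_threshold(
                list(zip(pts.I0_pA, pts.S1f)),
                min_span_decades=config.min_span_decades,
                rel_tol=config.fit_rel_tol,
                max_iter=config.fit_max_iter,
            )
        except ValueError as exc:
            logger.warning("series %s/%s/%.3g M: %s", pore_id, salt, c_m, exc)
            continue
        series_rows.append(dict(
            pore_id=pore_id, salt=salt, C_M=c_m, a_M=float(grp.a_M.iloc[0]),
            d_mean=float(grp.d_mean.iloc[0]), present=tf.present,
            I_T_pA=tf.I_T if tf.present else math.nan,
            I_T_se_pA=threshold_standard_error(tf),
            sigma_lt=tf.sigma_lt, sigma_gt=tf.sigma_gt, zeta=tf.zeta,
            n_points=tf.n_points,
        ))
    per_series = pd.DataFrame(series_rows)
    if per_series.empty:
        raise ValueError("no series could be fit for thresholds")

    pore_rows = []
    detected = per_series[per_series.present]
    for (pore_id, salt), grp in detected.groupby(["pore_id", "salt"]):
        if grp.a_M.nunique() < config.min_activities:
            logger.warning(
                "pore %s/%s: thresholds at %d < %d activities, dropped",
                pore_id, salt, grp.a_M.nunique(), config.min_activities,
            )
            continue
        weights = None
        if config.weights_policy == "inverse_variance":
            se = grp.I_T_se_pA.to_numpy()
            if np.all(np.isfinite(se)) and np.all(se > 0):
                weights = 1.0 / se**2
        fit = zero_activity_threshold(
            list(zip(grp.a_M, grp.I_T_pA)), weights=weights
        )
        pore_rows.append(dict(
            pore_id=pore_id, salt=salt, d_mean=float(grp.d_mean.iloc[0]),
            I_T0_pA=fit.intercept, I_T0_se_pA=fit.se_intercept,
            slope_pA_per_M=fit.slope, R2_activity=fit.r_squared,
            n_activities=int(grp.a_M.nunique()),
        ))
    per_pore = pd.DataFrame(pore_rows)
    if per_pore.empty:
        raise ValueError(
            "all pores dropped: no pore has thresholds at "
            f"{config.min_activities}+ activities"
        )

    per_ion = {}
    for salt, grp in per_pore.groupby("salt"):
        if grp.d_mean.nunique() < 3:
            logger.warning("ion %s: fewer than 3 pore diameters, skipped", salt)
            continue
        weights = None
        if config.weights_policy == "inverse_variance":
            se = grp.I_T0_se_pA.to_numpy()
            if np.all(np.isfinite(se)) and np.all(se > 0):
                weights = 1.0 / se**2
        fit = ion_diameter_from_thresholds(
            list(zip(grp.d_mean, grp.I_T0_pA)), weights=weights
        )
        per_ion[str(salt)] = dict(
            d_ion_nm=fit.x_intercept, d_ion_se_nm=fit.se_x_intercept,
            slope_pA_per_nm=fit.slope, r_squared=fit.r_squared,
            n_pores=int(grp.d_mean.nunique()), flagged=fit.flagged,
        )

    return IonSizeReport(
        per_trace=per_trace, per_series=per_series, per_pore=per_pore,
        per_ion=per_ion, config=asdict(config),
    )


def run_ion_sizing(
    manifest: str | Path | pd.DataFrame,
    config: AnalysisConfig | None = None,
    trace_loader=None,
) -> IonSizeReport:
    """Run the pipeline from a manifest table referencing trace files.

    Manifest columns: trace_path, pore_id, salt, C_M, V_bias, fs and
    d_mean_nm (waist diameter per pore).  Activities are computed with the
    configured model.  Unreadable trace files raise an error naming the file.
    """
    from .io import read_trace  # local import to keep h5py optional at import

    config = config or AnalysisConfig()
    loader = trace_loader or read_trace
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    required = {"trace_path", "pore_id", "salt", "C_M", "V_bias", "d_mean_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    def records():
        for _, r in df.iterrows():
            trace = loader(r["trace_path"])
            meta = dict(
                pore_id=r["pore_id"], salt=r["salt"], C_M=float(r["C_M"]),
                a_M=activity(float(r["C_M"]), r["salt"], config.activity_model),
                d_mean=float(r["d_mean_nm"]), V_bias=float(r["V_bias"]),
            )
            yield meta, trace

    return analyze_records(records(), config)


def run_synthetic_ion_sizing(
    plans: ExperimentPlan | Sequence[ExperimentPlan],
    config: AnalysisConfig | None = None,
) -> IonSizeReport:
    """Generate planted experiments and push them through the pipeline.

    Synthetic traces carry no bias-step transient, so the settling expunge is
    skipped (settle_s = 0) unless the caller configures otherwise.
    """
    if isinstance(plans, ExperimentPlan):
        plans = [plans]
    if config is None:
        config = AnalysisConfig(settle_s=0.0)

    def records():
        for plan in plans:
            for row, trace in gen_experiment(plan):
                meta = dict(
                    pore_id=row["pore_id"], salt=row["salt"], C_M=row["C_M"],
                    a_M=row["a_M"], d_mean=row["d_mean"], V_bias=row["V_bias"],
                )
                yield meta, trace

    return analyze_records(records(), config)


def run_conductance_sizing(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    weights: Sequence[float] | None = None,
) -> dict:
    """Zero-conductance diameters per ion from (salt, d_mean_nm, g_nS) rows.

    Returns {salt: fit dict} plus a "mean" entry averaging the per-ion
    intercepts (the cross-ion consensus diameter).
    """
    required = {"salt", "d_mean_nm", "g_nS"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"conductance table missing columns: {sorted(missing)}")
    out = {}
    intercepts = []
    for salt, grp in table.groupby("salt"):
        if grp.d_mean_nm.nunique() < 3:
            logger.warning("ion %s: fewer than 3 diameters, skipped", salt)
            continue
        fit = weighted_line_fit(grp.d_mean_nm, grp.g_nS, weights)
        out[str(salt)] = dict(
            d_intercept_nm=fit.x_intercept, se_nm=fit.se_x_intercept,
            slope_nS_per_nm=fit.slope, r_squared=fit.r_squared,
            flagged=fit.flagged,
        )
        intercepts.append(fit.x_intercept)
    if not intercepts:
        raise ValueError("no ion had enough pores for a conductance fit")
    out["mean"] = dict(
        d_intercept_nm=float(np.mean(intercepts)), n_ions=len(intercepts)
    )
    return out
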