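"""File formats: trace files, spectra, manifests and pore tables.

Traces travel either as two-column delimited text (time_s, current_pA) or as
an HDF5 container with datasets /current (pA), /fs, /v_bias and string
attributes for the condition and pore identifiers.  Spectra export as
delimited text (freq_Hz, psd_pA2_per_Hz).  Pore descriptions are rows of a
CSV manifest.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .noise import CurrentTrace, PSDSpectrum
from .pore import PoreModel

__all__ = [
    "write_trace_text",
    "read_trace_text",
    "write_trace_hdf5",
    "read_trace_hdf5",
    "read_trace",
    "write_spectrum_text",
    "read_spectrum_text",
    "write_pore_table",
    "read_pore_table",
]

PORE_COLUMNS = [
    "pore_id", "d_minor_nm", "d_major_nm", "theta_deg", "t_mem_nm",
    "rho_s_e_per_nm2",
]


def write_trace_text(trace: CurrentTrace, path: str | Path) -> None:
    t = np.arange(trace.samples.size) / trace.fs
    header = (
        f"time_s\tcurrent_pA  # fs_Hz={trace.fs} v_bias_V={trace.v_bias} "
        f"trace_id={trace.trace_id}"
    )
    np.savetxt(
        path, np.column_stack([t, trace.samples]), fmt="%.9g",
        delimiter="\t", header=header,
    )


def read_trace_text(path: str | Path, v_bias: float = 0.0) -> CurrentTrace:
    path = Path(path)
    fs = None
    with open(path) as fh:
        first = fh.readline()
    if "fs_Hz=" in first:
        for token in first.replace("#", " ").split():
            if token.startswith("fs_Hz="):
                fs = float(token.split("=", 1)[1])
            elif token.startswith("v_bias_V="):
                v_bias = float(token.split("=", 1)[1])
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, current_pA)")
    if fs is None:
        dt = np.diff(data[:, 0])
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform time column")
        fs = 1.0 / dt[0]
    return CurrentTrace(
        samples=data[:, 1], fs=fs, v_bias=v_bias, trace_id=path.stem
    )


def write_trace_hdf5(trace: CurrentTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("current", data=trace.samples, compression="gzip")
        f["fs"] = trace.fs
        f["v_bias"] = trace.v_bias
        f.attrs["trace_id"] = trace.trace_id
        if trace.pore is not None:
            f.attrs["pore_id"] = getattr(trace.pore, "pore_id", "")
        if trace.condition is not None:
            f.attrs["salt"] = getattr(trace.condition, "salt", "")
            f.attrs["C_M"] = getattr(trace.condition, "C", float("nan"))


def read_trace_hdf5(path: str | Path) -> CurrentTrace:
    with h5py.File(path, "r") as f:
        return CurrentTrace(
            samples=f["current"][...],
            fs=float(f["fs"][()]),
            v_bias=float(f["v_bias"][()]),
            trace_id=str(f.attrs.get("trace_id", Path(path).stem)),
        )


def read_trace(path: str | Path) -> CurrentTrace:
    """Dispatch on extension: .h5/.hdf5 binary container, else delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_text(path)


def write_spectrum_text(spectrum: PSDSpectrum, path: str | Path) -> None:
    np.savetxt(
        path, np.column_stack([spectrum.freqs, spectrum.psd]), fmt="%.9g",
        delimiter="\t", header="freq_Hz\tpsd_pA2_per_Hz",
    )


def read_spectrum_text(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


def write_pore_table(pores: list[PoreModel], path: str | Path) -> None:
    rows = [
        (p.pore_id, p.d_minor, p.d_major, p.theta, p.t_mem, p.rho_s)
        for p in pores
    ]
    pd.DataFrame(rows, columns=PORE_COLUMNS).to_csv(path, index=False)


def read_pore_table(path: str | Path) -> list[PoreModel]:
    df = pd.read_csv(path)
    missing = set(PORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pore table missing columns: {sorted(missing)}")
    return [
        PoreModel(
            d_minor=float(r["d_minor_nm"]), d_major=float(r["d_major_nm"]),
            theta=float(r["theta_deg"]), t_mem=float(r["t_mem_nm"]),
            rho_s=float(r["rho_s_e_per_nm2"]), pore_id=str(r["pore_id"]),
        )
        for _, r in df.iterrows()
    ]
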