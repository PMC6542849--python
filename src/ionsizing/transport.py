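"""1-D Brownian-dynamics ion permeation along the pore axis.

Overdamped Langevin motion on a free-energy profile W(z) (the potential of
mean force, in units of kB T) tilted by a uniform axial field E acting on
charge q:

    z <- z + D [ -dW/dz + q E / kB T ] dt + sqrt(2 D dt) eta,

with eta standard normal.  Transport runs reflect at the entry (z = 0),
absorb at the exit (z = L) and immediately re-inject at the entry so the
channel holds a single ion at a time (one-at-a-time permeation).  Each
absorption is a translocation event; the average current is the event count
times the elementary charge over the simulated time, and the instantaneous
current assigns each event e divided by its translocation time.

From equilibrium runs (E = 0, reflecting at both ends) the PMF is recovered
by Boltzmann inversion of the stationary density and the diffusivity from
the slope of the mean square displacement (1-D: MSD = 2 D t).

Units: nm, ns, kB T, elementary charges; currents in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "TransportTrajectory",
    "brownian_transport",
    "pmf_from_trajectory",
    "msd_diffusivity",
    "average_current",
    "instantaneous_current",
    "KT_EV_300K",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
KT_EV_300K = 0.025852  # kB T in eV at 300 K
E_OVER_PA_NS = ELEMENTARY_CHARGE / 1e-12 / 1e-9  # pA = e / (this many ns) -> 160.22


@dataclass
class TransportTrajectory:
    """A Brownian path with its sampled positions and translocation events."""

    times: np.ndarray  # ns, subsampled
    positions: np.ndarray  # nm, subsampled
    events: list  # (entry time ns, exit time ns, direction +1)
    dt: float  # ns
    n_steps: int
    D: float  # nm^2/ns, input diffusivity
    q: float  # e
    E_field: float  # V/nm
    T: float  # K
    L: float  # nm, box length
    z_grid: np.ndarray  # nm, PMF grid
    pmf: np.ndarray  # kBT, PMF on z_grid
    absorbing: bool

    @property
    def total_time(self) -> float:
        return self.n_steps * self.dt


@njit(cache=False)
def _bd_loop(
    z0, n_steps, dt, D, tilt, z_lo, dz_grid, F_grid, L, absorbing,
    reflect_entry, noise, stride, out_pos, entry_steps, exit_steps, directions,
):  # pragma: no cover - compiled
    z = z0
    n_grid = F_grid.size
    sq = math.sqrt(2.0 * D * dt)
    n_events = 0
    entry = 0
    for i in range(n_steps):
        # linear interpolation of -dW/dz on the grid
        x = (z - z_lo) / dz_grid
        j = int(x)
        if j < 0:
            j = 0
        elif j > n_grid - 2:
            j = n_grid - 2
        frac = x - j
        force = F_grid[j] * (1.0 - frac) + F_grid[j + 1] * frac
        z = z + D * (force + tilt) * dt + sq * noise[i]
        if absorbing:
            if z < 0.0 and reflect_entry:
                z = -z
            # exit through an open end is recorded with its direction and the
            # ion re-injected at the entry point (single-ion channel)
            if z > L or z < 0.0:
                if n_events < entry_steps.size:
                    entry_steps[n_events] = entry
                    exit_steps[n_events] = i + 1
                    directions[n_events] = 1 if z > L else -1
                n_events += 1
                z = z0
                entry = i + 1
        else:
            if z < 0.0:
                z = -z
            if z > L:
                z = 2.0 * L - z
        if i % stride == 0:
            out_pos[i // stride] = z
    return n_events


def brownian_transport(
    pmf: Sequence[float] | Callable[[np.ndarray], np.ndarray],
    L: float = 5.0,
    D: float = 1.0,
    q: float = 1.0,
    E_field: float = 0.0,
    dt: float = 1e-4,
    n_steps: int = 1_000_000,
    T: float = 300.0,
    n_grid: int = 512,
    absorbing: bool = True,
    record_stride: int = 100,
    seed: int = 0,
    z0: float | None = None,
    reflect_entry: bool = False,
) -> TransportTrajectory:
    """Simulate overdamped Langevin transport through a 1-D channel.

    ``pmf`` is either W(z) values on a uniform grid over [0, L] or a callable
    evaluated on one; units kB T.  ``E_field`` in V/nm acts on charge ``q``
    (in e).  ``absorbing=True`` gives transport mode: exits through either
    end are translocation events with direction +1 (exit at L) or -1 (return
    through 0), after which the ion is re-injected at the entry point ``z0``
    (default L/2) so the channel holds one ion at a time.  The signed event
    sum gives the net current, which vanishes for a flat, field-free
    channel.  ``reflect_entry=True`` closes the z = 0 end instead (an ion
    pressed against the entry reservoir), so only forward translocations are
    recorded — the setup for barrier-escape comparisons.  ``absorbing=False``
    gives an equilibrium box reflecting at both ends (for PMF and MSD
    estimation).

    Raises ``ValueError`` when drift or diffusive steps violate the grid
    stability limit, naming a stable ``dt``.
    """
    if L <= 0 or D <= 0 or dt <= 0 or n_steps < 1:
        raise ValueError("L, D, dt must be positive and n_steps >= 1")
    z_grid = np.linspace(0.0, L, n_grid)
    w = np.asarray(pmf(z_grid), dtype=float) if callable(pmf) else np.asarray(
        pmf, dtype=float
    )
    if w.shape != z_grid.shape:
        if callable(pmf):
            raise ValueError("pmf callable must return one value per grid point")
        z_grid = np.linspace(0.0, L, w.size)
    if not np.all(np.isfinite(w)):
        raise ValueError("PMF must be finite on the box")
    dz = z_grid[1] - z_grid[0]
    F_grid = -np.gradient(w, dz)  # kBT/nm

    kt_ev = KT_EV_300K * (T / 300.0)
    tilt = q * E_field / kt_ev  # kBT/nm

    max_drift = D * (np.max(np.abs(F_grid)) + abs(tilt)) * dt
    diff_step = math.sqrt(2.0 * D * dt)
    limit = 0.1 * dz
    if max_drift > limit or diff_step > limit:
        dt_drift = limit / (D * (np.max(np.abs(F_grid)) + abs(tilt)) + 1e-300)
        dt_diff = limit**2 / (2.0 * D)
        raise ValueError(
            f"unstable step: drift {max_drift:.2e} nm or diffusive "
            f"{diff_step:.2e} nm exceeds 0.1 dz = {limit:.2e} nm; "
            f"use dt <= {min(dt_drift, dt_diff):.3e} ns"
        )

    if z0 is None:
        z0 = 0.5 * L
    if not (0.0 <= z0 <= L):
        raise ValueError("injection point z0 must lie inside [0, L]")
    rng = np.random.default_rng(seed)
    n_rec = (n_steps + record_stride - 1) // record_stride
    out_pos = np.empty(n_rec)
    max_events = max(n_steps // 100, 1024)
    entry_steps = np.full(max_events, -1, dtype=np.int64)
    exit_steps = np.full(max_events, -1, dtype=np.int64)
    directions = np.zeros(max_events, dtype=np.int8)
    noise = rng.standard_normal(n_steps)
    n_events = _bd_loop(
        float(z0), n_steps, dt, D, tilt, float(z_grid[0]), dz, F_grid, L,
        absorbing, reflect_entry, noise, record_stride, out_pos, entry_steps,
        exit_steps, directions,
    )
    n_kept = min(n_events, max_events)
    events = [
        (entry_steps[k] * dt, exit_steps[k] * dt, int(directions[k]))
        for k in range(n_kept)
    ]
    times = np.arange(n_rec) * (record_stride * dt)
    return TransportTrajectory(
        times=times, positions=out_pos, events=events, dt=dt, n_steps=n_steps,
        D=D, q=q, E_field=E_field, T=T, L=L, z_grid=z_grid, pmf=w,
        absorbing=absorbing,
    )


def pmf_from_trajectory(
    traj: TransportTrajectory, z0: float | None = None, n_bins: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann-invert the stationary density: W = -ln(rho), anchored at z0.

    Requires an equilibrium trajectory (no field, reflecting ends).  The
    anchor ``z0`` defaults to the free-energy minimum (where the mean force
    vanishes); W(z0) = 0 exactly.  Unvisited bins raise an error listing them.
    """
    if traj.absorbing or traj.E_field != 0.0:
        raise ValueError("PMF inversion requires an equilibrium trajectory")
    lo = float(np.min(traj.positions))
    hi = float(np.max(traj.positions))
    counts, edges = np.histogram(traj.positions, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    empty = centers[counts == 0]
    if empty.size:
        raise ValueError(
            f"unvisited bins at z = {np.round(empty, 3).tolist()} nm; "
            "sample longer or coarsen the bins"
        )
    w = -np.log(counts / counts.max())
    if z0 is None:
        anchor = int(np.argmin(w))
    else:
        anchor = int(np.argmin(np.abs(centers - z0)))
    w = w - w[anchor]
    return centers, w


def msd_diffusivity(
    positions: np.ndarray | TransportTrajectory,
    dt_sample: float | None = None,
    max_lag: int = 200,
    min_lag: int = 2,
) -> float:
    """Diffusivity from the MSD slope over a lag window (1-D: MSD = 2 D t).

    ``positions`` may be a trajectory (its recorded positions and sampling
    interval are used) or a bare array with ``dt_sample`` in ns.  Intended
    for unconfined/flat-potential segments where the MSD is linear.
    """
    if isinstance(positions, TransportTrajectory):
        dt_sample = float(positions.times[1] - positions.times[0])
        positions = positions.positions
    x = np.asarray(positions, dtype=float)
    if dt_sample is None or dt_sample <= 0:
        raise ValueError("dt_sample must be positive")
    if x.size < 10 * max_lag:
        raise ValueError(
            f"trajectory too short: need >= {10 * max_lag} recorded points"
        )
    lags = np.arange(min_lag, max_lag + 1)
    msd = np.array([np.mean((x[lag:] - x[:-lag]) ** 2) for lag in lags])
    slope = np.polyfit(lags * dt_sample, msd, 1)[0]
    return float(slope / 2.0)


def average_current(events: Sequence, total_time: float) -> float:
    """Net mean ionic current in pA: (signed translocation count) e / time (ns).

    Events are (entry, exit, direction) with direction +-1; forward-only
    event lists reduce to (number of translocations) * e / total time.
    """
    if total_time <= 0:
        raise ValueError("total time must be positive")
    signed = sum(int(ev[2]) for ev in events)
    return signed * E_OVER_PA_NS / total_time


def instantaneous_current(
    events: Sequence, t_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray] | list[tuple[float, float, float]]:
    """Per-event instantaneous current: e / (translocation time) during each event.

    Without ``t_grid`` returns the exact piecewise-constant representation as
    (t_entry, t_exit, amplitude_pA) tuples, whose time integral is exactly
    n_events * e.  With ``t_grid`` (ns) returns (t_grid, I(t) in pA).
    """
    segments = []
    for entry, exit_, direction in events:
        tau = exit_ - entry
        if tau <= 0:
            raise ValueError("event exit time must exceed entry time")
        segments.append((entry, exit_, direction * E_OVER_PA_NS / tau))
    if t_grid is None:
        return segments
    t_grid = np.asarray(t_grid, dtype=float)
    current = np.zeros_like(t_grid)
    for entry, exit_, amp in segments:
        current[(t_grid >= entry) & (t_grid < exit_)] += amp
    return t_grid, current
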