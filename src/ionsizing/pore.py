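"""Bi-conical pore geometry, conductance models and a steric-PB radial solver.

A sputtered sub-nanopore is modeled as two opposed conical frusta meeting at
an elliptical waist (reported via its geometric-mean diameter).  Because the
membrane is thin and the field focuses at the waist, the pore acts as an
electrolytic point contact with conductance g = sigma * d; extrapolating g(d)
to zero conductance gauges the diameter of the permeating (de-hydrated) ion.

The waist cross-section electrostatics follow a steric-modified
Poisson-Boltzmann equation in reduced potential Psi = e psi / kB T:

    laplacian(Psi) = sinh(Psi) / (lambda^2 (1 + alpha (cosh(Psi) - 1))),

with alpha = 2 a^3 n0 the steric (finite-ion-size) parameter.  alpha = 0
recovers classical PB; alpha > 0 caps the counter-ion concentration at the
wall.  The solver is 1-D radial (cylindrical waist) with a Gauss-law flux
condition at the charged wall and symmetry on the axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import iv

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    EPSILON_0,
)
from .electrolyte import ElectrolyteCondition, bulk_conductivity
from .linefit import LineFit, weighted_line_fit

__all__ = [
    "PoreModel",
    "ContinuumField",
    "PBSolverError",
    "mean_waist_diameter",
    "biconical_volume",
    "expected_ion_count",
    "point_contact_conductance",
    "fit_zero_conductance_diameter",
    "fit_zero_diffusivity_diameter",
    "surface_charge_from_min_conductivity",
    "modified_pb_radial",
    "reduced_conductance",
]

THETA_RANGE = (4.0, 37.0)  # observed cone half-angle range, degrees


def mean_waist_diameter(d_minor: float, d_major: float) -> float:
    """Geometric-mean waist diameter in nm (report rounded to 2 d.p.)."""
    if d_minor <= 0 or d_major <= 0:
        raise ValueError("waist axes must be positive")
    if d_minor > d_major:
        raise ValueError("d_minor must not exceed d_major")
    return math.sqrt(d_minor * d_major)


@dataclass
class PoreModel:
    """Bi-conical pore: waist axes, cone half-angle, thickness, surface charge.

    ``rho_s`` is the surface charge density in e/nm^2 (non-positive by the
    sign convention for silicon nitride in water).
    """

    d_minor: float
    d_major: float
    theta: float  # cone half-angle per side, degrees
    t_mem: float  # membrane thickness, nm
    rho_s: float = 0.0  # e/nm^2, <= 0
    pore_id: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.d_minor <= self.d_major):
            raise ValueError("require 0 < d_minor <= d_major")
        if self.t_mem <= 0:
            raise ValueError("membrane thickness must be positive")
        if self.rho_s > 0:
            raise ValueError("surface charge density must be <= 0")
        if not (THETA_RANGE[0] <= self.theta <= THETA_RANGE[1]):
            warnings.warn(
                f"cone half-angle {self.theta} deg outside the observed "
                f"{THETA_RANGE[0]}-{THETA_RANGE[1]} deg range",
                stacklevel=2,
            )

    @property
    def d_mean(self) -> float:
        return mean_waist_diameter(self.d_minor, self.d_major)

    @property
    def volume(self) -> float:
        return biconical_volume(self.d_mean, self.theta, self.t_mem)

    @property
    def q_total(self) -> float:
        """Total surface charge in e over the bi-conical lumen wall."""
        h = self.t_mem / 2.0
        r_w = self.d_mean / 2.0
        tan_t = math.tan(math.radians(self.theta))
        r_ap = r_w + h * tan_t
        slant = math.hypot(h, r_ap - r_w)
        area = 2.0 * math.pi * (r_w + r_ap) * slant  # two frusta lateral area
        return self.rho_s * area


def biconical_volume(d_mean: float, theta: float, t_mem: float) -> float:
    """Volume (nm^3) of two equal conical frusta of height t_mem/2.

    Wall radius r(z) = d_mean/2 + z tan(theta) from the waist outward;
    theta = 0 reduces exactly to the cylinder pi d^2 t / 4.
    """
    if d_mean <= 0 or t_mem <= 0:
        raise ValueError("diameter and thickness must be positive")
    if not (0 <= theta < 90):
        raise ValueError("cone half-angle must be in [0, 90) degrees")
    h = t_mem / 2.0
    r1 = d_mean / 2.0
    r2 = r1 + h * math.tan(math.radians(theta))
    frustum = math.pi * h / 3.0 * (r1**2 + r1 * r2 + r2**2)
    return 2.0 * frustum


def expected_ion_count(V_pore: float, C: float) -> float:
    """Expected cation count in a pore of volume ``V_pore`` nm^3 at ``C`` M."""
    if V_pore < 0 or C < 0:
        raise ValueError("volume and concentration must be non-negative")
    return C * AVOGADRO * V_pore * 1e-24  # mol/L * /mol * nm^3 * L/nm^3


def point_contact_conductance(sigma: float, d_mean: float) -> float:
    """Ideal point-contact conductance g = sigma * d, in S (sigma S/m, d nm)."""
    if sigma < 0 or d_mean < 0:
        raise ValueError("conductivity and diameter must be non-negative")
    return sigma * d_mean * 1e-9


def fit_zero_conductance_diameter(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> LineFit:
    """Weighted line through (d_mean, g); x_intercept is the ion-size estimate."""
    d, g = zip(*points)
    return weighted_line_fit(d, g, weights)


def fit_zero_diffusivity_diameter(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> LineFit:
    """Weighted line through (d_mean, D_eff); x_intercept is the size estimate."""
    d, D = zip(*points)
    return weighted_line_fit(d, D, weights)


def surface_charge_from_min_conductivity(
    sigma_min: float, mu_plus: float, d_mean: float
) -> float:
    """Invert sigma_min = 4 mu+ |rho_s| / d for rho_s (returned <= 0, e/nm^2).

    ``sigma_min`` in S/m, ``mu_plus`` in m^2/(V s), ``d_mean`` in nm.
    """
    if sigma_min < 0:
        raise ValueError("sigma_min must be non-negative")
    if mu_plus <= 0 or d_mean <= 0:
        raise ValueError("mobility and diameter must be positive")
    rho_si = sigma_min * (d_mean * 1e-9) / (4.0 * mu_plus)  # C/m^2
    return -rho_si / (ELEMENTARY_CHARGE * 1e18)  # -> e/nm^2, negative convention


class PBSolverError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final residual {residual:.3e})")
        self.residual = residual


@dataclass
class ContinuumField:
    """Radial solution of the steric-modified PB equation at the waist."""

    r_grid: np.ndarray  # nm
    Psi: np.ndarray  # reduced potential e psi / kB T
    c_profiles: dict  # species label -> concentration profile, M
    alpha: float
    a_solv: float  # nm
    lambda_D: float  # nm
    residual: float
    iterations: int
    sigma_bulk: float | None = None  # S/m
    g: float | None = None  # S
    sigma_min: float | None = None  # S/m
    D_eff: float | None = None  # nm^2/ns

    @property
    def wall_concentration(self) -> float:
        """Counter-ion concentration at the wall, M."""
        return float(self.c_profiles["counter"][-1])


def _reduced_wall_gradient(rho_s: float, cond: ElectrolyteCondition) -> float:
    """dPsi/dr at the wall in 1/nm from Gauss's law for rho_s in e/nm^2."""
    sigma_surf = rho_s * ELEMENTARY_CHARGE * 1e18  # C/m^2
    grad_m = ELEMENTARY_CHARGE * sigma_surf / (
        cond.epsilon_r * EPSILON_0 * BOLTZMANN * cond.T
    )
    return grad_m * 1e-9


def _pb_rhs(psi: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    psi = np.clip(psi, -60.0, 60.0)  # intermediate Newton iterates only
    if alpha == 0.0:
        return np.sinh(psi) / lam**2
    denom = 1.0 + alpha * (np.cosh(psi) - 1.0)
    return np.sinh(psi) / (lam**2 * denom)


def _pb_rhs_prime(psi: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    psi = np.clip(psi, -60.0, 60.0)
    ch, sh = np.cosh(psi), np.sinh(psi)
    if alpha == 0.0:
        return ch / lam**2
    denom = 1.0 + alpha * (ch - 1.0)
    return (ch * denom - alpha * sh**2) / (lam**2 * denom**2)


def modified_pb_radial(
    pore: PoreModel,
    cond: ElectrolyteCondition,
    a_solv: float = 0.0,
    n_grid: int = 2000,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ContinuumField:
    """Solve the steric-modified PB equation on the waist cross-section.

    Symmetric-electrolyte reduction: the bulk number density entering lambda
    and alpha is the ionic strength.  ``a_solv`` is the solvated-ion radius in
    nm; ``a_solv = 0`` gives the classical (alpha = 0) equation.

    Returns the converged :class:`ContinuumField`; raises
    :class:`PBSolverError` if the damped Newton iteration does not reach a
    sup-norm residual below ``tol`` within ``max_iter`` iterations.
    """
    if a_solv < 0:
        raise ValueError("solvated radius must be non-negative")
    R = pore.d_mean / 2.0
    lam = cond.lambda_D
    n0 = cond.I_strength * AVOGADRO * 1e-27 * 1e3  # ions/nm^3 (mol/L -> 1/nm^3)
    alpha = 2.0 * a_solv**3 * n0
    r = np.linspace(0.0, R, n_grid)
    h = r[1] - r[0]
    s = _reduced_wall_gradient(pore.rho_s, cond)

    if pore.rho_s == 0.0 or not math.isfinite(lam):
        psi = np.zeros(n_grid)
        c_bulk = cond.I_strength
        return ContinuumField(
            r_grid=r, Psi=psi,
            c_profiles={"counter": np.full(n_grid, c_bulk),
                        "co": np.full(n_grid, c_bulk)},
            alpha=alpha, a_solv=a_solv, lambda_D=lam, residual=0.0, iterations=0,
        )

    # initial guess: linearized (Debye-Hueckel) solution with the flux BC,
    # Psi(r) = s lam I0(r/lam) / I1(R/lam)
    psi = s * lam * iv(0, r / lam) / iv(1, R / lam)

    def residual_vec(p: np.ndarray, s_val: float = s) -> np.ndarray:
        f = _pb_rhs(p, lam, alpha)
        res = np.empty_like(p)
        res[0] = 4.0 * (p[1] - p[0]) / h**2 - f[0]
        res[1:-1] = (
            (p[2:] - 2.0 * p[1:-1] + p[:-2]) / h**2
            + (p[2:] - p[:-2]) / (2.0 * h * r[1:-1])
            - f[1:-1]
        )
        # wall: ghost node from (psi_N - psi_{N-2}) / 2h = s
        res[-1] = (
            2.0 * (p[-2] - p[-1] + h * s_val) / h**2 + s_val / R - f[-1]
        )
        return res

    def jacobian_banded(p: np.ndarray) -> np.ndarray:
        fp = _pb_rhs_prime(p, lam, alpha)
        ab = np.zeros((3, p.size))
        # ab[0]: superdiag, ab[1]: diag, ab[2]: subdiag
        ab[1, 0] = -4.0 / h**2 - fp[0]
        ab[0, 1] = 4.0 / h**2
        ri = r[1:-1]
        ab[1, 1:-1] = -2.0 / h**2 - fp[1:-1]
        ab[0, 2:] = 1.0 / h**2 + 1.0 / (2.0 * h * ri)
        ab[2, :-2] = 1.0 / h**2 - 1.0 / (2.0 * h * ri)
        ab[1, -1] = -2.0 / h**2 - fp[-1]
        ab[2, -2] = 2.0 / h**2
        return ab

    # roundoff floor of the discrete residual: second differences of O(|Psi|)
    # values divided by h^2 cannot resolve below ~eps |Psi| / h^2
    def _floor(p: np.ndarray) -> float:
        return 32.0 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(p)))) / h**2

    def _newton(psi0: np.ndarray, s_val: float, budget: int) -> tuple:
        p = psi0.copy()
        res = residual_vec(p, s_val)
        norm = float(np.max(np.abs(res)))
        norm2 = float(np.linalg.norm(res))
        it = 0
        while norm > max(tol, _floor(p)) and it < budget:
            delta = solve_banded((1, 1), jacobian_banded(p), -res)
            # trust region: never move the reduced potential by more than
            # 2 kBT/e in one step (prevents overshoot into the saturated
            # regime where the steric rhs flattens)
            max_move = float(np.max(np.abs(delta)))
            if max_move > 2.0:
                delta *= 2.0 / max_move
            step = 1.0
            for _ in range(40):
                trial = p + step * delta
                trial_res = residual_vec(trial, s_val)
                trial_norm2 = float(np.linalg.norm(trial_res))
                if trial_norm2 < norm2:
                    break
                step *= 0.5
            else:
                break  # line search stalled
            p, res, norm2 = trial, trial_res, trial_norm2
            norm = float(np.max(np.abs(res)))
            it += 1
        return p, norm, it

    psi, norm, it = _newton(psi, s, max_iter)
    if norm > max(tol, _floor(psi)):
        # globalize by ramping the wall charge adaptively, reusing each
        # solution as the next initial guess (continuation in the boundary
        # flux); the increment halves whenever a sub-solve fails
        psi = np.zeros_like(r)
        it = 0
        frac, step_frac = 0.0, 0.25
        while frac < 1.0 and step_frac >= 1e-3 and it < 50 * max_iter:
            target = min(frac + step_frac, 1.0)
            trial, norm, used = _newton(psi, s * target, max_iter)
            it += used
            if norm <= max(tol, _floor(trial)):
                psi, frac = trial, target
            else:
                step_frac /= 2.0
    if norm > max(tol, _floor(psi)):
        raise PBSolverError(
            f"PB Newton did not converge in {max_iter} iterations", norm
        )

    c_bulk = cond.I_strength
    denom = 1.0 + alpha * (np.cosh(psi) - 1.0)
    c_counter = c_bulk * np.exp(-psi) / denom  # cations at a negative wall
    c_co = c_bulk * np.exp(psi) / denom
    return ContinuumField(
        r_grid=r, Psi=psi, c_profiles={"counter": c_counter, "co": c_co},
        alpha=alpha, a_solv=a_solv, lambda_D=lam, residual=norm, iterations=it,
    )


def reduced_conductance(
    pore: PoreModel,
    cond: ElectrolyteCondition,
    D_eff_ratio: float = 1.0,
) -> float:
    """Reduced-order bi-conical conductance, in S.

    Series resistance integral over the frustum area profile plus the
    standard disk access resistance at each aperture, in parallel with the
    counter-ion surface term 4 mu+ |rho_s| (the sigma_min * d product):

        g = [R_access + integral dz / (sigma_pore A(z))]^-1 + 4 mu+ |rho_s|

    ``D_eff_ratio`` in [0, 1] scales the bulk conductivity inside the pore to
    mimic confinement-reduced diffusivity.
    """
    if not (0.0 <= D_eff_ratio <= 1.0):
        raise ValueError("D_eff_ratio must be within [0, 1]")
    sigma_bulk = bulk_conductivity(cond)
    sigma_pore = sigma_bulk * D_eff_ratio

    r_w = pore.d_mean / 2.0 * 1e-9  # m
    h = pore.t_mem / 2.0 * 1e-9
    tan_t = math.tan(math.radians(pore.theta))
    r_ap = r_w + h * tan_t
    if r_w <= 0:
        raise ValueError("degenerate geometry: zero waist radius")

    # surface (counter-ion) term: sigma_min * d = 4 mu+ |rho_s|
    mu_plus = abs(cond.cation.mu_bulk)
    rho_si = abs(pore.rho_s) * ELEMENTARY_CHARGE * 1e18  # C/m^2
    g_surface = 4.0 * mu_plus * rho_si

    if sigma_pore == 0.0 or sigma_bulk == 0.0:
        return g_surface

    if tan_t > 0:
        r_bulk = 2.0 / (math.pi * sigma_pore * tan_t) * (1.0 / r_w - 1.0 / r_ap)
    else:
        r_bulk = 2.0 * h / (sigma_pore * math.pi * r_w**2)
    r_access = 2.0 * (1.0 / (4.0 * sigma_bulk * r_ap))  # disk access, both sides
    return 1.0 / (r_access + r_bulk) + g_surface
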