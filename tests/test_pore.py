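"""Pore geometry, conductance models, surface charge and the PB radial solver."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import iv

from ionsizing.constants import ELEMENTARY_CHARGE
from ionsizing.electrolyte import ION_REGISTRY, ElectrolyteCondition, bulk_conductivity
from ionsizing.pore import (
    PBSolverError,
    PoreModel,
    _reduced_wall_gradient,
    biconical_volume,
    expected_ion_count,
    fit_zero_conductance_diameter,
    fit_zero_diffusivity_diameter,
    mean_waist_diameter,
    modified_pb_radial,
    point_contact_conductance,
    reduced_conductance,
    surface_charge_from_min_conductivity,
)


class TestWaistDiameter:
    @pytest.mark.parametrize(
        "dmin,dmaj,expected",
        [(0.30, 0.40, 0.35), (0.95, 1.00, 0.97), (0.50, 0.55, 0.52)],
    )
    def test_reported_geometric_means(self, dmin, dmaj, expected):
        assert round(mean_waist_diameter(dmin, dmaj), 2) == expected

    def test_circular_waist_identity(self):
        assert mean_waist_diameter(0.42, 0.42) == 0.42

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mean_waist_diameter(0.0, 0.4)
        with pytest.raises(ValueError):
            mean_waist_diameter(0.5, 0.4)


class TestBiconicalVolume:
    def test_reference_worked_examples(self):
        assert biconical_volume(0.35, 5.0, 10.0) == pytest.approx(5.4, abs=0.05)
        assert biconical_volume(0.97, 20.0, 10.0) == pytest.approx(69.8, abs=0.05)

    def test_zero_angle_reduces_to_cylinder(self):
        d, t = 0.6, 8.0
        assert biconical_volume(d, 0.0, t) == pytest.approx(
            math.pi * d**2 * t / 4, rel=1e-14
        )

    def test_strictly_increasing_in_each_argument(self):
        base = biconical_volume(0.5, 10.0, 10.0)
        assert biconical_volume(0.6, 10.0, 10.0) > base
        assert biconical_volume(0.5, 12.0, 10.0) > base
        assert biconical_volume(0.5, 10.0, 12.0) > base

    def test_degenerate_angle_rejected(self):
        with pytest.raises(ValueError):
            biconical_volume(0.5, 90.0, 10.0)


class TestOccupancy:
    def test_reference_occupancies(self):
        assert expected_ion_count(5.371, 0.125) == pytest.approx(0.4, abs=0.05)
        assert expected_ion_count(69.80, 0.5) == pytest.approx(21.0, abs=0.5)

    def test_empty_solution(self):
        assert expected_ion_count(100.0, 0.0) == 0.0


class TestPointContact:
    def test_closed_pore_and_product_symmetry(self):
        assert point_contact_conductance(3.2, 0.0) == 0.0
        assert point_contact_conductance(2.0, 0.5) == pytest.approx(
            point_contact_conductance(1.0, 1.0), rel=1e-14
        )

    def test_quarter_molar_nacl_half_nm_pore(self, nacl_250mM):
        g = point_contact_conductance(bulk_conductivity(nacl_250mM), 0.5)
        assert g == pytest.approx(1.6e-9, rel=0.02)  # ~1.6 nS


class TestZeroInterceptFits:
    def test_collinear_points_exact(self):
        d = np.array([0.3, 0.5, 0.7, 0.9])
        g = 2.5 * (d - 0.24)
        fit = fit_zero_conductance_diameter(list(zip(d, g)))
        assert fit.x_intercept == pytest.approx(0.24, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.flagged

    def test_per_ion_intercepts_consolidate(self):
        # the four reference per-ion zero-conductance intercepts average to 0.24 nm
        intercepts = [0.21, 0.24, 0.26, 0.23]
        assert abs(float(np.mean(intercepts)) - 0.24) <= 0.005 + 1e-12

    def test_monte_carlo_coverage_two_se(self, rng):
        d = np.array([0.3, 0.45, 0.6, 0.75, 0.9])
        slope, d0 = 2.0, 0.24
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            g = slope * (d - d0)
            noisy = g + rng.normal(0, 0.05 * g)
            fit = fit_zero_conductance_diameter(list(zip(d, noisy)))
            if abs(fit.x_intercept - d0) <= 2 * fit.se_x_intercept:
                hits += 1
        assert hits / n_rep >= 0.93

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_zero_conductance_diameter([(0.3, 1.0), (0.5, 2.0)])
        with pytest.raises(ValueError):
            fit_zero_diffusivity_diameter([(0.3, 1.0)])

    def test_negative_slope_flagged(self):
        fit = fit_zero_conductance_diameter([(0.3, 3.0), (0.5, 2.0), (0.7, 1.0)])
        assert fit.flagged

    def test_diffusivity_intercept_recovery(self, rng):
        d = np.array([0.3, 0.4, 0.55, 0.7, 0.85, 1.0])
        D = 1.8 * (d - 0.22)
        hits = 0
        for _ in range(400):
            fit = fit_zero_diffusivity_diameter(
                list(zip(d, D + rng.normal(0, 0.1 * D)))
            )
            if abs(fit.x_intercept - 0.22) <= 2 * fit.se_x_intercept:
                hits += 1
        assert hits / 400 >= 0.9


class TestSurfaceCharge:
    def test_round_trip_identity(self):
        rho = -0.19  # e/nm^2
        mu = ION_REGISTRY["Na"].mu_bulk
        d = 0.52
        sigma_min = 4 * mu * abs(rho) * ELEMENTARY_CHARGE * 1e18 / (d * 1e-9)
        back = surface_charge_from_min_conductivity(sigma_min, mu, d)
        assert back == pytest.approx(rho, rel=1e-12)

    def test_zero_conductivity_means_neutral_wall(self):
        assert surface_charge_from_min_conductivity(
            0.0, ION_REGISTRY["Na"].mu_bulk, 0.5
        ) == 0.0

    def test_recovery_from_synthetic_g_of_C(self, rng):
        # g(C) = sigma(C) d + 4 mu |rho_s|: the zero-activity intercept of g
        # is the counter-ion term, inverted back to the planted charge
        rho_true = -0.19
        mu = ION_REGISTRY["Na"].mu_bulk
        d = 0.52
        g_surf = 4 * mu * abs(rho_true) * ELEMENTARY_CHARGE * 1e18
        concs = np.array([0.005, 0.01, 0.05, 0.1, 0.25, 0.5])
        g = np.array([
            point_contact_conductance(
                bulk_conductivity(ElectrolyteCondition.from_salt("NaCl", C)), d
            ) + g_surf
            for C in concs
        ]) * (1 + rng.normal(0, 0.02, concs.size))
        coef = np.polyfit(concs, g, 1)
        sigma_min = coef[1] / (d * 1e-9)
        rho_est = surface_charge_from_min_conductivity(sigma_min, mu, d)
        assert rho_est == pytest.approx(rho_true, rel=0.10)


def _shooting_oracle(cond, R, s):
    """Classical PB in the cylinder via shooting from the axis (fine RK)."""
    lam = cond.lambda_D

    def shoot(psi0):
        def rhs(r, y):
            return [y[1], np.sinh(y[0]) / lam**2 - y[1] / r]

        eps = 1e-8
        return solve_ivp(
            rhs, [eps, R], [psi0, 0.5 * np.sinh(psi0) / lam**2 * eps],
            rtol=1e-12, atol=1e-14, dense_output=True,
        )

    psi0 = brentq(lambda p: shoot(p).y[1][-1] - s, -25, 0, xtol=1e-13)
    return shoot(psi0).sol


class TestModifiedPBRadial:
    def test_uncharged_wall_gives_zero_field(self, nacl_250mM):
        pore = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=10, rho_s=0.0)
        fld = modified_pb_radial(pore, nacl_250mM)
        assert np.all(fld.Psi == 0.0)
        assert np.allclose(fld.c_profiles["counter"], nacl_250mM.I_strength)

    def test_classical_limit_matches_shooting_oracle(self, charged_pore, nacl_250mM):
        fld = modified_pb_radial(charged_pore, nacl_250mM, a_solv=0.0)
        R = charged_pore.d_mean / 2
        s = _reduced_wall_gradient(charged_pore.rho_s, nacl_250mM)
        oracle = _shooting_oracle(nacl_250mM, R, s)
        err = np.max(np.abs(fld.Psi[1:] - oracle(fld.r_grid[1:])[0]))
        assert err < 1e-6

    def test_small_charge_matches_linearized_bessel_form(self, nacl_250mM):
        pore = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=10, rho_s=-0.003)
        fld = modified_pb_radial(pore, nacl_250mM)
        assert np.max(np.abs(fld.Psi)) < 0.1
        R, lam = pore.d_mean / 2, nacl_250mM.lambda_D
        s = _reduced_wall_gradient(pore.rho_s, nacl_250mM)
        lin = s * lam * iv(0, fld.r_grid / lam) / iv(1, R / lam)
        rel = np.max(np.abs(fld.Psi - lin)) / np.max(np.abs(lin))
        assert rel < 0.01

    def test_gauss_law_charge_neutrality(self, charged_pore, nacl_250mM):
        fld = modified_pb_radial(charged_pore, nacl_250mM)
        lam = nacl_250mM.lambda_D
        R = charged_pore.d_mean / 2
        s = _reduced_wall_gradient(charged_pore.rho_s, nacl_250mM)
        integral = np.trapezoid(
            np.sinh(fld.Psi) / lam**2 * 2 * np.pi * fld.r_grid, fld.r_grid
        )
        assert integral / (2 * np.pi * R * s) == pytest.approx(1.0, abs=1e-3)

    def test_counterion_enhanced_coion_depleted_at_wall(self, charged_pore, nacl_250mM):
        fld = modified_pb_radial(charged_pore, nacl_250mM)
        bulk = nacl_250mM.I_strength
        assert fld.c_profiles["counter"][-1] > bulk
        assert fld.c_profiles["co"][-1] < bulk
        # |Psi| decays monotonically from the wall toward the axis
        assert np.all(np.diff(np.abs(fld.Psi)) >= -1e-12)

    def test_steric_term_caps_wall_concentration(self, nacl_250mM):
        # finite-size saturation: the counter-ion concentration never exceeds
        # 2 n0 / alpha, while the classical solution grows without bound
        a_solv = 0.4
        alpha = 2 * a_solv**3 * (0.25 * 0.602214076)
        c_max = 2 * 0.25 / alpha
        charges = [-0.5, -1.0, -2.0, -3.0]
        classical, steric = [], []
        for rho in charges:
            pore = PoreModel(d_minor=1.0, d_major=1.0, theta=10, t_mem=10, rho_s=rho)
            classical.append(modified_pb_radial(pore, nacl_250mM).wall_concentration)
            steric.append(
                modified_pb_radial(pore, nacl_250mM, a_solv=a_solv).wall_concentration
            )
        assert all(s < c_max for s in steric)
        assert classical[-1] > c_max
        growth_classical = classical[-1] / classical[0]
        growth_steric = steric[-1] / steric[0]
        assert growth_classical > 2 * growth_steric
        assert all(s <= c for s, c in zip(steric, classical))

    def test_alpha_zero_recovered_when_no_solvated_radius(self, charged_pore, nacl_250mM):
        fld = modified_pb_radial(charged_pore, nacl_250mM, a_solv=0.0)
        assert fld.alpha == 0.0

    def test_infeasible_steric_packing_raises_with_residual(self, nacl_250mM):
        # at maximum steric packing a 0.25 nm-radius cross-section cannot
        # neutralize 2 e/nm^2 of wall charge: no converged solution exists
        pore = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=10, rho_s=-2.0)
        with pytest.raises(PBSolverError) as err:
            modified_pb_radial(pore, nacl_250mM, a_solv=0.4)
        assert err.value.residual > 0


class TestReducedConductance:
    def test_cylinder_matches_hand_integration(self, nacl_250mM):
        pore = PoreModel(d_minor=0.6, d_major=0.6, theta=0.0, t_mem=8.0, rho_s=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = reduced_conductance(pore, nacl_250mM, D_eff_ratio=1.0)
        sigma = bulk_conductivity(nacl_250mM)
        r = 0.3e-9
        r_bulk = 8.0e-9 / (sigma * math.pi * r**2)
        r_acc = 1.0 / (2 * sigma * r)
        assert g == pytest.approx(1.0 / (r_acc + r_bulk), rel=1e-10)

    def test_thin_membrane_limit_is_point_contact(self, nacl_250mM):
        pore = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=1e-6, rho_s=0.0)
        g = reduced_conductance(pore, nacl_250mM, D_eff_ratio=1.0)
        g_pc = point_contact_conductance(bulk_conductivity(nacl_250mM), 0.5)
        assert g == pytest.approx(g_pc, rel=0.05)

    def test_blocked_pore_conducts_only_via_surface_term(self, nacl_250mM):
        pore = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=10, rho_s=0.0)
        assert reduced_conductance(pore, nacl_250mM, D_eff_ratio=0.0) == 0.0
        charged = PoreModel(d_minor=0.5, d_major=0.5, theta=10, t_mem=10, rho_s=-0.19)
        g_surf = reduced_conductance(charged, nacl_250mM, D_eff_ratio=0.0)
        mu = ION_REGISTRY["Na"].mu_bulk
        assert g_surf == pytest.approx(
            4 * mu * 0.19 * ELEMENTARY_CHARGE * 1e18, rel=1e-12
        )

    def test_monotone_in_diameter(self, nacl_250mM):
        gs = []
        for d in np.linspace(0.2, 1.0, 9):
            pore = PoreModel(d_minor=d, d_major=d, theta=10, t_mem=10, rho_s=-0.1)
            gs.append(reduced_conductance(pore, nacl_250mM, 0.5))
        assert all(a < b for a, b in zip(gs, gs[1:]))

    def test_invalid_ratio_rejected(self, charged_pore, nacl_250mM):
        with pytest.raises(ValueError):
            reduced_conductance(charged_pore, nacl_250mM, D_eff_ratio=1.5)


class TestPoreModel:
    def test_angle_outside_observed_range_warns(self):
        with pytest.warns(UserWarning, match="cone half-angle"):
            PoreModel(d_minor=0.5, d_major=0.5, theta=45.0, t_mem=10.0)

    def test_positive_surface_charge_rejected(self):
        with pytest.raises(ValueError):
            PoreModel(d_minor=0.5, d_major=0.5, theta=10.0, t_mem=10.0, rho_s=0.1)
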