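"""Electrolyte property model: activities, mobilities, screening, conductivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionsizing import constants as k
from ionsizing.electrolyte import (
    ION_REGISTRY,
    SALTS,
    ElectrolyteCondition,
    activity,
    activity_coefficient,
    bulk_conductivity,
    debye_length,
    einstein_diffusivity,
    ionic_strength,
    registry_from_table,
    registry_to_table,
    stokes_mobility,
)

ALL_SALTS = sorted(SALTS)


class TestRegistry:
    def test_table1_activity_parameters(self):
        expected = {
            "Li": (0.38, 0.20), "Na": (0.36, 0.06), "K": (0.33, 0.01),
            "Cs": (0.33, 0.01), "Mg": (0.43, 0.21),
        }
        for name, (a0, b) in expected.items():
            assert ION_REGISTRY[name].a0 == a0
            assert ION_REGISTRY[name].b == b

    def test_valences_in_scope(self):
        assert {ION_REGISTRY[n].z for n in ("Li", "Na", "K", "Cs")} == {1}
        assert ION_REGISTRY["Mg"].z == 2
        assert ION_REGISTRY["Cl"].z == -1

    def test_roundtrip_through_csv(self, tmp_path):
        path = tmp_path / "ions.csv"
        registry_to_table(path)
        loaded = registry_from_table(path)
        assert loaded == ION_REGISTRY

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,z\nNa,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            registry_from_table(path)


class TestIonicStrength:
    @pytest.mark.parametrize(
        "C,salt,expected",
        [(0.125, "KCl", 0.125), (0.25, "MgCl2", 0.75), (0.0, "NaCl", 0.0)],
    )
    def test_group_one_and_two(self, C, salt, expected):
        assert ionic_strength(C, salt) == pytest.approx(expected)

    def test_unknown_salt_rejected(self):
        with pytest.raises(KeyError, match="unknown salt"):
            ionic_strength(0.1, "CaCl2")


class TestActivityCoefficient:
    def test_infinite_dilution_limit(self):
        for salt in ALL_SALTS:
            for model in ("EDH", "TJ"):
                assert activity_coefficient(0.0, salt, model) == 1.0

    def test_nacl_500mM_truesdell_jones(self):
        # direct hand evaluation: log10 g = -0.5085*sqrt(.5)/(1+0.3281*3.6*sqrt(.5)) + 0.06*0.5
        sqrt_i = math.sqrt(0.5)
        log10_g = -0.5085 * sqrt_i / (1 + 0.3281 * 3.6 * sqrt_i) + 0.06 * 0.5
        assert activity_coefficient(0.5, "NaCl", "TJ") == pytest.approx(
            10**log10_g, rel=1e-12
        )
        # cross-check against the published mean activity value ~0.68
        assert activity_coefficient(0.5, "NaCl", "TJ") == pytest.approx(0.68, abs=0.01)

    @pytest.mark.parametrize("salt", ALL_SALTS)
    @pytest.mark.parametrize("C", [0.005, 0.125, 0.25, 0.5, 1.0, 2.0])
    def test_matches_direct_formula_evaluation(self, salt, C):
        cation = ION_REGISTRY[SALTS[salt][0]]
        I = C if salt != "MgCl2" else 3 * C
        sqrt_i = math.sqrt(I)
        log10_g = -0.5085 * cation.z**2 * sqrt_i / (
            1 + 0.3281 * (cation.a0 * 10) * sqrt_i
        )
        assert activity_coefficient(C, salt, "EDH") == pytest.approx(
            10**log10_g, rel=1e-12
        )
        assert activity_coefficient(C, salt, "TJ") == pytest.approx(
            10 ** (log10_g + cation.b * I), rel=1e-12
        )

    @pytest.mark.parametrize("salt", ALL_SALTS)
    @pytest.mark.parametrize("C", [0.005, 0.125, 0.5, 2.0])
    def test_tj_exceeds_edh_by_exactly_b_times_i(self, salt, C):
        cation = ION_REGISTRY[SALTS[salt][0]]
        ratio = activity_coefficient(C, salt, "TJ") / activity_coefficient(
            C, salt, "EDH"
        )
        assert ratio == pytest.approx(10 ** (cation.b * ionic_strength(C, salt)),
                                      rel=1e-12)

    def test_bounded_by_unity_at_study_concentrations(self):
        # gamma < 1 throughout the study's working range (<= 500 mM); the
        # b*I term lifts gamma above 1 only beyond ~1 M for Li+/Mg2+, as
        # real activity data also do
        for salt in ALL_SALTS:
            for C in np.linspace(0.001, 0.5, 15):
                assert 0 < activity_coefficient(C, salt, "TJ") <= 1
        for salt in ("NaCl", "KCl", "CsCl"):
            for C in np.linspace(0.001, 2.0, 15):
                assert 0 < activity_coefficient(C, salt, "TJ") <= 1

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            activity_coefficient(-0.1, "NaCl")


class TestActivity:
    def test_zero_and_reference_value(self):
        assert activity(0.0, "NaCl") == 0.0
        assert activity(0.5, "NaCl", "TJ") == pytest.approx(
            0.5 * activity_coefficient(0.5, "NaCl", "TJ"), rel=1e-14
        )
        assert activity(0.5, "NaCl", "TJ") == pytest.approx(0.34, abs=0.01)

    @given(st.floats(min_value=1e-4, max_value=1.99))
    @settings(deadline=None, max_examples=40)
    def test_strictly_increasing(self, C):
        eps = 0.005
        for salt in ("NaCl", "MgCl2"):
            assert activity(C, salt) < activity(C + eps, salt)

    @given(st.floats(min_value=1e-4, max_value=0.5))
    @settings(deadline=None, max_examples=40)
    def test_below_C_in_study_range(self, C):
        for salt in ("NaCl", "MgCl2", "LiCl"):
            assert activity(C, salt) <= C


class TestTransportConstants:
    def test_stokes_mobility_closed_form(self):
        mu = stokes_mobility(1, 0.89e-3, 0.234e-9)
        assert mu == pytest.approx(
            k.ELEMENTARY_CHARGE / (3 * math.pi * 0.89e-3 * 0.234e-9), rel=1e-14
        )
        # inverse proportionality and valence linearity
        assert stokes_mobility(1, 0.89e-3, 0.468e-9) == pytest.approx(mu / 2)
        assert stokes_mobility(2, 0.89e-3, 0.234e-9) == pytest.approx(2 * mu)

    def test_stokes_domain_errors(self):
        with pytest.raises(ValueError):
            stokes_mobility(1, 0.0, 1e-9)
        with pytest.raises(ValueError):
            stokes_mobility(1, 1e-3, -1e-9)

    def test_einstein_relation_linearity(self):
        assert einstein_diffusivity(0.0, 298.15) == 0.0
        mu = 5e-8
        assert einstein_diffusivity(mu, 2 * 298.15) == pytest.approx(
            2 * einstein_diffusivity(mu, 298.15)
        )
        with pytest.raises(ValueError):
            einstein_diffusivity(mu, 0.0)

    def test_bulk_sodium_diffusivity_implies_known_mobility(self):
        # D_Na+ = 1.33 nm^2/ns at 298 K inverts to mu ~ 5.2e-8 m^2/(Vs)
        mu = 1.33e-9 * k.ELEMENTARY_CHARGE / (k.BOLTZMANN * 298.15)
        assert mu == pytest.approx(5.2e-8, rel=0.01)
        assert einstein_diffusivity(mu, 298.15) == pytest.approx(1.33e-9, rel=1e-12)

    def test_stokes_einstein_composition(self):
        d = 0.3e-9
        D = einstein_diffusivity(stokes_mobility(1, k.ETA_WATER, d), 298.15)
        closed = k.BOLTZMANN * 298.15 / (3 * math.pi * k.ETA_WATER * d)
        assert D == pytest.approx(closed, rel=1e-12)


class TestDebyeLength:
    def test_reference_value_100mM(self):
        assert debye_length(0.1, 298.15, 78.4) == pytest.approx(0.96, abs=0.01)

    def test_inverse_square_root_scaling(self):
        assert debye_length(0.4) == pytest.approx(debye_length(0.1) / 2, rel=1e-12)
        assert debye_length(0.025) == pytest.approx(2 * debye_length(0.1), rel=1e-12)

    def test_zero_strength_rejected(self):
        with pytest.raises(ValueError):
            debye_length(0.0)


class TestBulkConductivity:
    def test_reference_and_linearity(self):
        c1 = bulk_conductivity(ElectrolyteCondition.from_salt("NaCl", 0.25))
        assert c1 == pytest.approx(3.2, abs=0.1)  # F(mu_Na+mu_Cl)*250 mol/m^3
        c2 = bulk_conductivity(ElectrolyteCondition.from_salt("NaCl", 0.5))
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        assert bulk_conductivity(ElectrolyteCondition.from_salt("NaCl", 0.0)) == 0.0

    def test_mgcl2_counts_both_charge_and_stoichiometry(self):
        cond = ElectrolyteCondition.from_salt("MgCl2", 0.1)
        mg, cl = ION_REGISTRY["Mg"], ION_REGISTRY["Cl"]
        expected = k.FARADAY * 100.0 * (2 * mg.mu_bulk + 2 * abs(cl.mu_bulk))
        assert bulk_conductivity(cond) == pytest.approx(expected, rel=1e-12)


class TestElectrolyteCondition:
    def test_condition_invariants(self):
        for salt in ALL_SALTS:
            for C in (0.005, 0.25, 0.5):
                cond = ElectrolyteCondition.from_salt(salt, C)
                assert 0 < cond.gamma <= 1
                assert cond.a == pytest.approx(cond.gamma * cond.C, rel=1e-14)
                expected_i = C if salt != "MgCl2" else 3 * C
                assert cond.I_strength == pytest.approx(expected_i)

    def test_debye_length_decreases_with_strength(self):
        lams = [
            ElectrolyteCondition.from_salt("NaCl", C).lambda_D
            for C in (0.05, 0.1, 0.5, 1.0)
        ]
        assert all(a > b for a, b in zip(lams, lams[1:]))
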