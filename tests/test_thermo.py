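"""Closed-form thermodynamics: Gibbs energies, Nernst potentials,
equilibrium hydrogen pressures and ion-translocation energies."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from syntherm import (
    CONSTANTS,
    Conditions,
    IonInvestment,
    LACTATE_FERMENTATION,
    METHANOGENESIS,
    Reaction,
    ThermoConstants,
    couple_halves,
    delta_g_at_conditions,
    equilibrium_h2_pressure,
    ion_translocation_energy,
    nernst_potential,
    potential_shift,
    standard_delta_g,
    tolerated_pressure_with_investment,
)

RT = CONSTANTS.rt_kj(298.15)  # 2.479 kJ/mol


class TestStandardDeltaG:
    def test_lactate_fermentation_is_strongly_endergonic(self, table):
        # lactate⁻ → pyruvate⁻ + H2 sits ~43 kJ/mol uphill at standard state
        dg = standard_delta_g(LACTATE_FERMENTATION, table)
        assert dg == pytest.approx(43.2, rel=0.01)

    def test_empty_reaction_is_zero(self, table):
        assert standard_delta_g(Reaction("empty", {}), table) == 0.0

    def test_self_reaction_cancels(self, table):
        r = Reaction("null", {"lactate": 0.0})
        assert standard_delta_g(r, table) == 0.0
        r2 = Reaction("ab", {"pyruvate": 1.0, "lactate": 1.0})
        r2_rev = Reaction("ba", {"pyruvate": -1.0, "lactate": -1.0})
        assert standard_delta_g(r2, table) + standard_delta_g(r2_rev, table) == pytest.approx(0.0)

    def test_missing_compound_named_in_error(self, table):
        with pytest.raises(KeyError, match="unobtainium"):
            standard_delta_g(Reaction("x", {"unobtainium": 1.0}), table)

    def test_missing_formation_energy_named_in_error(self, table):
        with pytest.raises(KeyError, match="alanine"):
            standard_delta_g(Reaction("x", {"alanine": 1.0}), table)

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scaling_linearity(self, factor):
        base = standard_delta_g(LACTATE_FERMENTATION)
        scaled = standard_delta_g(LACTATE_FERMENTATION.scaled(factor))
        assert scaled == pytest.approx(factor * base, rel=1e-9)

    def test_charge_balance_of_embedded_reactions(self, table):
        assert LACTATE_FERMENTATION.charge_balance(table) == 0
        assert METHANOGENESIS.charge_balance(table) == 0


class TestDeltaGAtConditions:
    def test_standard_state_returns_dg0(self, table, standard):
        dg = delta_g_at_conditions(LACTATE_FERMENTATION, 43.2, standard, table)
        assert dg == pytest.approx(43.2)

    def test_low_product_activities_pull_to_equilibrium(self, table):
        # oracle: 43.2 + RT·ln(1e-4 · 2.7e-7 / 1e-3) ≈ −0.003 kJ/mol
        cond = Conditions(298.15, {"lactate": 1e-3, "pyruvate": 1e-4, "H2": 2.7e-7})
        dg = delta_g_at_conditions(LACTATE_FERMENTATION, 43.2, cond, table)
        assert dg == pytest.approx(43.2 + RT * math.log(1e-4 * 2.7e-7 / 1e-3), abs=1e-9)
        assert abs(dg) < 0.05

    def test_one_bar_hydrogen_keeps_it_uphill(self, table):
        cond = Conditions(298.15, {"lactate": 1e-3, "pyruvate": 1e-4, "H2": 1.0})
        dg = delta_g_at_conditions(LACTATE_FERMENTATION, 43.2, cond, table)
        assert dg == pytest.approx(37.5, abs=0.1)

    def test_water_excluded_from_quotient(self, table):
        # methanogenesis produces 2 H2O; its activity must not enter ΔG
        cond = Conditions(298.15, {"H2": 1.0, "CO2": 1.0, "CH4": 1.0})
        assert delta_g_at_conditions(METHANOGENESIS, -131.0, cond, table) == pytest.approx(-131.0)

    def test_non_positive_activity_rejected(self):
        with pytest.raises(ValueError):
            Conditions(298.15, {"H2": 0.0})
        with pytest.raises(ValueError):
            Conditions(298.15, {"H2": -1e-6})

    @given(lnp=st.floats(-25.0, 2.0), lnp2=st.floats(-25.0, 2.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dg_strictly_increases_with_hydrogen_pressure(self, table, lnp, lnp2):
        lo, hi = sorted((lnp, lnp2))
        if hi - lo < 1e-9:
            return
        c_lo = Conditions(298.15, {"H2": math.exp(lo)})
        c_hi = Conditions(298.15, {"H2": math.exp(hi)})
        dg_lo = delta_g_at_conditions(LACTATE_FERMENTATION, 43.2, c_lo, table)
        dg_hi = delta_g_at_conditions(LACTATE_FERMENTATION, 43.2, c_hi, table)
        assert dg_hi > dg_lo


class TestNernst:
    def test_standard_state_returns_e0(self, table, standard):
        for name in table.couples:
            cpl = table.couple(name)
            assert nernst_potential(cpl, standard, table) == pytest.approx(cpl.e0_prime)

    def test_hydrogen_couple_at_methanogen_threshold(self, table):
        cond = Conditions(298.15, {"H2": 1.83e-6})
        e = nernst_potential(table.couple("H+/H2"), cond, table)
        assert e * 1000 == pytest.approx(-244, abs=2)

    def test_lactate_couple_shifts_with_pyruvate_ratio(self, table):
        # oracle: −0.190 + (RT/2F)·ln(0.1)
        cond = Conditions(298.15, {"pyruvate": 0.1, "lactate": 1.0})
        e = nernst_potential(table.couple("pyruvate/lactate"), cond, table)
        expected = -0.190 + (8.3145 * 298.15) / (2 * 96485.0) * math.log(0.1)
        assert e == pytest.approx(expected, abs=1e-9)
        assert e == pytest.approx(-0.220, abs=5e-4)

    def test_e0_consistent_with_formation_energies_to_1mv(self, table):
        """Where both ΔGf°′ and E°′ are tabulated they must agree:
        E°′ = −ΔG°′/(nF) within 1 mV."""
        checked = 0
        for name in table.couples:
            e_from_dgf = table.couple_e0_from_formation(name)
            if e_from_dgf is None:
                continue
            assert abs(e_from_dgf - table.couple(name).e0_prime) < 1e-3, name
            checked += 1
        assert checked >= 5  # LDH, H2, formate, sulfite/sulfide, ethanol at least


class TestCoupleHalves:
    def test_lactate_to_proton_reduction_energy_barrier(self, table, standard):
        de, dg = couple_halves(table.couple("pyruvate/lactate"), table.couple("H+/H2"),
                               standard, table)
        assert de == pytest.approx(-0.224, abs=1e-3)
        assert dg == pytest.approx(43.2, rel=0.01)

    def test_self_coupling_is_equilibrium(self, table, standard):
        cpl = table.couple("pyruvate/lactate")
        de, dg = couple_halves(cpl, cpl, standard, table)
        assert de == 0.0 and dg == 0.0

    def test_nernst_adjusted_equal_potentials_give_zero_dg(self, table):
        # raise the H2 couple to −0.190 V by lowering P_H2
        target = table.couple("pyruvate/lactate").e0_prime
        rt_over_2f = 8.3145 * 298.15 / (2 * 96485.0)
        p = math.exp(-(target - (-0.414)) / rt_over_2f)
        cond = Conditions(298.15, {"H2": p})
        de, dg = couple_halves(table.couple("pyruvate/lactate"), table.couple("H+/H2"),
                               cond, table)
        assert abs(de) < 1e-9 and abs(dg) < 1e-6

    def test_sign_convention_dg_negative_iff_de_positive(self, table, standard):
        de, dg = couple_halves(table.couple("H+/H2"), table.couple("pyruvate/lactate"),
                               standard, table)
        assert de > 0 and dg < 0

    def test_mismatched_electron_counts(self, table, standard):
        with pytest.raises(ValueError, match="electron counts"):
            couple_halves(table.couple("pyruvate/lactate"), table.couple("sulfite/HS-"),
                          standard, table)
        de, dg = couple_halves(table.couple("pyruvate/lactate"), table.couple("sulfite/HS-"),
                               standard, table, scale=True)
        # lcm(2, 6) = 6 electrons
        assert dg == pytest.approx(-6 * 96485.0 * de / 1000.0)


class TestEquilibriumH2:
    def test_lactate_fermentation_threshold(self, table, physiological):
        p = equilibrium_h2_pressure(LACTATE_FERMENTATION, 43.2, physiological, table)
        assert p == pytest.approx(0.027, abs=0.002)

    def test_standard_state_zero_dg0_gives_one_bar(self, table, standard):
        p = equilibrium_h2_pressure(LACTATE_FERMENTATION, 0.0, standard, table)
        assert p == pytest.approx(1e5, rel=1e-9)

    def test_methanogenesis_minimum(self, table, standard):
        p = equilibrium_h2_pressure(METHANOGENESIS, -131.0, standard, table)
        assert p == pytest.approx(0.18, abs=0.02)

    def test_no_h2_in_reaction_is_an_error(self, table, standard):
        with pytest.raises(ValueError, match="H2"):
            equilibrium_h2_pressure(Reaction("x", {"lactate": -1.0, "pyruvate": 1.0}),
                                    0.0, standard, table)

    @given(dg0=st.floats(-150.0, 80.0), lac=st.floats(1e-6, 1.0), pyr=st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_dg_is_zero_at_solved_pressure(self, dg0, lac, pyr):
        cond = Conditions(298.15, {"lactate": lac, "pyruvate": pyr})
        p_pa = equilibrium_h2_pressure(LACTATE_FERMENTATION, dg0, cond)
        at_eq = cond.with_activity("H2", p_pa / 1e5)
        dg = delta_g_at_conditions(LACTATE_FERMENTATION, dg0, at_eq)
        assert abs(dg) < 1e-6

    def test_round_trip_with_consuming_stoichiometry(self, table, standard):
        p_pa = equilibrium_h2_pressure(METHANOGENESIS, -131.0, standard, table)
        at_eq = standard.with_activity("H2", p_pa / 1e5)
        assert abs(delta_g_at_conditions(METHANOGENESIS, -131.0, at_eq, table)) < 1e-6


class TestIonInvestment:
    def test_two_ions_hundredfold_is_minus_23(self):
        e = ion_translocation_energy(2, 100, 298.15)
        assert e == pytest.approx(-23, abs=0.25)
        assert e == pytest.approx(-2 * RT * math.log(100), abs=1e-12)

    def test_no_ions_or_unit_gradient_is_free(self):
        assert ion_translocation_energy(0, 1e6) == 0.0
        assert ion_translocation_energy(5, 1.0) == 0.0
        assert IonInvestment.none().energy == 0.0

    def test_single_ion_two_ph_units(self):
        e = ion_translocation_energy(1, delta_ph=2, temperature=298.15)
        assert e == pytest.approx(-RT * math.log(100), abs=1e-12)
        assert e == pytest.approx(-11.4, abs=0.05)

    def test_uphill_gradient_rejected(self):
        with pytest.raises(ValueError):
            ion_translocation_energy(1, 0.5)
        with pytest.raises(ValueError):
            IonInvestment(1, 0.5)

    def test_energy_is_never_positive(self):
        for m in (0, 1, 2.5):
            for fold in (1, 10, 1e4):
                assert ion_translocation_energy(m, fold) <= 0


class TestToleratedPressure:
    def test_single_ion_two_ph_units_is_exactly_hundredfold(self):
        inv = IonInvestment.from_delta_ph(1, 2)
        assert tolerated_pressure_with_investment(0.03, inv) == pytest.approx(3.0, rel=1e-9)

    def test_zero_investment_is_identity(self):
        assert tolerated_pressure_with_investment(0.03, IonInvestment.none()) == 0.03

    def test_two_ions_hundredfold_reaches_observed_stationary_pressure(self):
        # 0.03 Pa × 100² = 300 Pa — the order of the measured stationary H2
        inv = IonInvestment(2, 100)
        assert tolerated_pressure_with_investment(0.03, inv) == pytest.approx(300.0, rel=1e-9)

    @given(m=st.floats(0.0, 4.0), dm=st.floats(0.1, 2.0), fold=st.floats(1.0, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_ion_count(self, m, dm, fold):
        if fold == 1.0:
            return
        lo = tolerated_pressure_with_investment(0.03, IonInvestment(m, fold))
        hi = tolerated_pressure_with_investment(0.03, IonInvestment(m + dm, fold))
        assert hi > lo

    @given(fold=st.floats(1.0, 1e3), factor=st.floats(1.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_gradient(self, fold, factor):
        lo = tolerated_pressure_with_investment(0.03, IonInvestment(1, fold))
        hi = tolerated_pressure_with_investment(0.03, IonInvestment(1, fold * factor))
        assert hi > lo


class TestPotentialShift:
    def test_minus_23_over_two_electrons(self):
        inv = IonInvestment(2, 100)
        assert potential_shift(inv, 2) == pytest.approx(abs(inv.energy) * 1000 / (2 * 96485), rel=1e-12)
        assert potential_shift(inv, 2) == pytest.approx(0.119, abs=0.001)

    def test_zero_energy_zero_shift(self):
        assert potential_shift(IonInvestment.none(), 2) == 0.0

    def test_single_ion_shift(self):
        assert potential_shift(IonInvestment.from_delta_ph(1, 2), 2) == pytest.approx(0.0592, abs=3e-4)


class TestConstants:
    def test_immutable_and_positive(self):
        c = ThermoConstants()
        with pytest.raises(AttributeError):
            c.faraday = 1.0
        with pytest.raises(ValueError):
            ThermoConstants(gas_constant=-1.0)

    def test_water_and_proton_forced_to_unit_activity(self):
        cond = Conditions(298.15, {"H2O": 0.5, "H+": 1e-7})
        assert cond.activity("H2O") == 1.0
        assert cond.activity("H+") == 1.0
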