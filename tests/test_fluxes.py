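"""Membrane and paracellular flux laws: equilibria, bounds, stoichiometry."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from nephrosim import fluxes as fl
from nephrosim.units import RT_OVER_F

conc = st.floats(0.1, 300.0)
positive = st.floats(1e-6, 1.0)


class TestGhk:
    def test_zero_potential_equal_concentrations(self):
        assert fl.ghk_flux(1e-4, 1.0, 50.0, 50.0, 0.0) == pytest.approx(0.0)

    @given(c1=conc, c2=conc)
    @settings(deadline=None, max_examples=40)
    def test_fick_limit(self, c1, c2):
        """GHK reduces to Fick's law as the potential vanishes.

        The comparison needs a non-degenerate gradient: at c1 ~ c2 the
        (physically real) residual drift term dominates the vanishing
        diffusive flux.
        """
        assume(abs(c1 - c2) > 0.2 * max(c1, c2))
        fick = 1e-4 * (c1 - c2)
        ghk = fl.ghk_flux(1e-4, 1.0, c1, c2, 1e-6)
        assert abs(ghk - fick) / abs(fick) < 1e-6

    @given(c1=conc, c2=conc, v=st.floats(-100, 100))
    @settings(deadline=None, max_examples=40)
    def test_neutral_solute_ignores_potential(self, c1, c2, v):
        assert fl.ghk_flux(1e-5, 0.0, c1, c2, v) == \
            pytest.approx(1e-5 * (c1 - c2), rel=1e-12)

    def test_nernst_equilibrium(self):
        """Flux vanishes when the potential equals the Nernst potential."""
        c1, c2 = 140.0, 10.0
        # for a +1 cation the zero-flux potential is (RT/F) ln(c2/c1)
        v_eq = RT_OVER_F * np.log(c2 / c1)
        assert fl.ghk_flux(1e-4, 1.0, c1, c2, v_eq) == \
            pytest.approx(0.0, abs=1e-12)

    def test_anion_attracted_to_positive_side(self):
        # equal concentrations, cis side positive: anion flows trans -> cis
        j = fl.ghk_flux(1e-4, -1.0, 100.0, 100.0, 20.0)
        assert j < 0


class TestSglt:
    def test_equilibrium_state_gives_zero(self):
        j_glu, j_na = fl.sglt_flux("SGLT2", 5.0, 140.0, 5.0, 140.0, 1e-3,
                                   2.0, 30.0)
        assert j_glu == pytest.approx(0.0, abs=1e-18)
        assert j_na == pytest.approx(0.0, abs=1e-18)

    def test_saturation_limit(self):
        j_glu, _ = fl.sglt_flux("SGLT2", 1e6, 1e6, 1e-6, 1e-6, 1e-3,
                                2.0, 30.0)
        assert j_glu == pytest.approx(1e-3, rel=1e-3)

    @pytest.mark.parametrize("kind,stoich", [("SGLT2", 1), ("SGLT1", 2)])
    @given(lg=conc, ln=conc, cg=conc, cn=conc)
    @settings(deadline=None, max_examples=30)
    def test_na_coupling_stoichiometry(self, kind, stoich, lg, ln, cg, cn):
        j_glu, j_na = fl.sglt_flux(kind, lg, ln, cg, cn, 1e-3, 2.0, 30.0)
        assert j_na == pytest.approx(stoich * j_glu, rel=1e-12, abs=1e-30)

    @given(f=st.floats(0.0, 1.0), lg=conc, cg=conc)
    @settings(deadline=None, max_examples=40)
    def test_inhibition_exactly_linear(self, f, lg, cg):
        j0, _ = fl.sglt_flux("SGLT2", lg, 140.0, cg, 10.0, 1e-3, 2.0, 30.0)
        jf, _ = fl.sglt_flux("SGLT2", lg, 140.0, cg, 10.0, 1e-3, 2.0, 30.0,
                             inhibition_fraction=f)
        assert jf == pytest.approx((1.0 - f) * j0, rel=1e-12, abs=1e-30)

    @given(lg=conc, ln=conc, cg=conc, cn=conc)
    @settings(deadline=None, max_examples=40)
    def test_bounded_by_vmax(self, lg, ln, cg, cn):
        j_glu, _ = fl.sglt_flux("SGLT1", lg, ln, cg, cn, 1e-3, 0.5, 30.0)
        assert abs(j_glu) <= 1e-3 + 1e-18

    def test_negative_concentration_rejected(self):
        with pytest.raises(fl.DomainError):
            fl.sglt_flux("SGLT2", -1.0, 140.0, 5.0, 10.0, 1e-3, 2.0, 30.0)


class TestGlut:
    def test_symmetry_zero_at_equal(self):
        assert fl.glut_flux(7.7, 7.7, 1e-3, 17.0) == pytest.approx(0.0)

    def test_saturation(self):
        assert fl.glut_flux(1e7, 0.0, 1e-3, 17.0) == pytest.approx(
            1e-3, rel=1e-3)

    @given(a=conc, b=conc)
    @settings(deadline=None, max_examples=40)
    def test_odd_under_face_swap(self, a, b):
        fwd = fl.glut_flux(a, b, 1e-3, 17.0)
        rev = fl.glut_flux(b, a, 1e-3, 17.0)
        assert fwd == pytest.approx(-rev, rel=1e-12, abs=1e-30)


class TestCoupledCotransporters:
    def test_nkcc2_zero_at_equal_occupancy(self):
        j = fl.nkcc2_flux(100.0, 5.0, 100.0, 100.0, 5.0, 100.0, 1e-2)
        assert all(x == pytest.approx(0.0, abs=1e-18) for x in j)

    @given(ln=conc, lk=conc, lc=conc, cn=conc, ck=conc, cc=conc)
    @settings(deadline=None, max_examples=40)
    def test_nkcc2_electroneutral_stoichiometry(self, ln, lk, lc, cn, ck, cc):
        j_na, j_k, j_cl = fl.nkcc2_flux(ln, lk, lc, cn, ck, cc, 1e-2)
        assert j_k == pytest.approx(j_na, rel=1e-12, abs=1e-30)
        assert j_cl == pytest.approx(2 * j_na, rel=1e-12, abs=1e-30)
        # net charge per cycle: +1 +1 -2 = 0
        assert j_na * 1 + j_k * 1 + j_cl * (-1) == \
            pytest.approx(-j_na + j_k, rel=1e-9, abs=1e-25)

    def test_ncc_zero_flux_and_coupling(self):
        j_na, j_cl = fl.ncc_flux(50.0, 50.0, 50.0, 50.0, 1e-2)
        assert j_na == pytest.approx(0.0, abs=1e-18)
        j_na, j_cl = fl.ncc_flux(100.0, 100.0, 10.0, 10.0, 1e-2)
        assert j_cl == pytest.approx(j_na)

    def test_nhe3_carries_one_anion_per_na(self):
        j_na, j_an = fl.nhe3_flux(140.0, 110.0, 15.0, 20.0, 1e-2)
        assert j_an == pytest.approx(j_na)
        assert j_na > 0

    def test_nhe3_equilibrium_with_proton_bias(self):
        # zero flux when luminal occupancy equals beta * cell occupancy
        j, _ = fl.nhe3_flux(30.0, 70.0, 30.0, 70.0, 1e-2, beta=1.0)
        assert j == pytest.approx(0.0, abs=1e-18)

    @given(v=st.floats(1e-5, 1e-1))
    @settings(deadline=None, max_examples=25)
    def test_doubling_vmax_doubles_flux(self, v):
        j1 = fl.nkcc2_flux(140, 5, 110, 10, 120, 20, v)[0]
        j2 = fl.nkcc2_flux(140, 5, 110, 10, 120, 20, 2 * v)[0]
        assert j2 == pytest.approx(2 * j1, rel=1e-12, abs=1e-30)

    def test_kcl_zero_at_equal(self):
        j = fl.kcl_flux(120.0, 20.0, 120.0, 20.0, 1e-3)
        assert all(x == pytest.approx(0.0, abs=1e-18) for x in j)


class TestPump:
    def test_rate_vanishes_at_zero_na(self):
        j_na, j_k = fl.nak_atpase_flux(1e-9, 1e-2)
        assert j_na == pytest.approx(0.0, abs=1e-12)

    def test_saturation(self):
        j_na, _ = fl.nak_atpase_flux(1e6, 1e-2, km_na=6.0)
        assert j_na == pytest.approx(1e-2, rel=1e-4)

    @given(na=st.floats(0.1, 200.0))
    @settings(deadline=None, max_examples=40)
    def test_three_to_two_stoichiometry(self, na):
        j_na, j_k = fl.nak_atpase_flux(na, 1e-2)
        assert j_na == pytest.approx(1.5 * j_k, rel=1e-12)


class TestParacellularAndWater:
    def test_zero_at_full_equilibrium(self):
        j = fl.paracellular_flux(1e-4, 1.0, 0.8, 140.0, 140.0, 0.0, 0.0)
        assert j == pytest.approx(0.0, abs=1e-15)

    def test_higher_luminal_glucose_is_reabsorbed(self):
        j = fl.paracellular_flux(1e-5, 0.0, 1.0, 50.0, 5.0, 0.0, 0.0)
        assert j > 0

    def test_solvent_drag_direction(self):
        # reabsorptive water flux entrains solute when sigma < 1
        j = fl.paracellular_flux(0.0, 0.0, 0.5, 100.0, 100.0, 0.0, 1e-4)
        assert j == pytest.approx(0.5 * 1e-4 * 100.0, rel=1e-9)

    def test_water_flux_zero_at_osmotic_equilibrium(self):
        c = np.array([140.0, 5.0, 145.0, 5.0, 5.0])
        assert fl.water_flux(0.2, np.ones(5), c, c) == pytest.approx(0.0)

    def test_water_flux_zero_pf(self):
        a = np.array([100.0, 5.0, 100.0, 5.0, 5.0])
        b = a + 200.0
        assert fl.water_flux(0.0, np.ones(5), a, b) == pytest.approx(0.0)

    @given(pf=st.floats(1e-3, 2.0))
    @settings(deadline=None, max_examples=30)
    def test_water_flux_linear_in_pf(self, pf):
        a = np.array([100.0, 5.0, 100.0, 5.0, 5.0])
        b = a + 50.0
        j1 = fl.water_flux(1.0, np.ones(5), a, b)
        assert fl.water_flux(pf, np.ones(5), a, b) == \
            pytest.approx(pf * j1, rel=1e-12)

    @given(a=st.floats(1e-6, 1e3), b=st.floats(1e-6, 1e3))
    @settings(deadline=None, max_examples=40)
    def test_logmean_between_min_and_max(self, a, b):
        lm = float(fl.logmean(a, b))
        assert min(a, b) - 1e-12 <= lm <= max(a, b) + 1e-12


class TestTorque:
    def test_reference_state_gives_unity(self):
        assert fl.torque_multiplier(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_high_flow_stimulates(self):
        assert fl.torque_multiplier(2.0, 1.0, 1.0, 1.0) > 1.0

    def test_sensitivity_off(self):
        assert fl.torque_multiplier(5.0, 1.0, 1.0, 1.0, sensitivity=0.0) \
            == pytest.approx(1.0)

    def test_clamped(self):
        assert fl.torque_multiplier(100.0, 1.0, 1.0, 1.0) == 3.0
        assert fl.torque_multiplier(1e-6, 1.0, 1.0, 1.0) == 0.2
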