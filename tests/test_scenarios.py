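"""Scenario overlays: parameter values, filtered-load arithmetic, purity."""

import pytest

import nephrosim as ns
from nephrosim.architecture import single_kidney_gfr
from nephrosim.reporting import filtered_load
from nephrosim.scenarios import get_scenario


class TestDiabeticOverlayValues:
    @pytest.mark.parametrize("scenario,field,expected", [
        ("mod", "plasma_glucose", 8.6),
        ("sev", "plasma_glucose", 20.0),
        ("mod", "sngfr_multiplier_superficial", 1.27),
        ("mod", "sngfr_multiplier_jm", 1.10),
        ("mod", "proximal_diameter", 1.10),
        ("sev", "proximal_diameter", 1.28),
        ("mod", "distal_diameter", 1.18),
        ("sev", "distal_diameter", 1.42),
        ("mod", "distal_length", 1.07),
    ])
    def test_geometry_and_filtration(self, scenario, field, expected):
        s = (ns.moderate_diabetes() if scenario == "mod"
             else ns.severe_diabetes())
        assert getattr(s, field) == expected

    @pytest.mark.parametrize("transporter,segment,factor", [
        ("SGLT2", "PCT", 1.38),
        ("GLUT2", "PCT", 1.50),
        ("SGLT1", "S3", 0.67),
        ("NKCC2", "mTAL", 1.10),
        ("NKCC2", "cTAL", 1.10),
        ("NaKATPase", "PCT", 1.10),
        ("NaKATPase", "mTAL", 1.20),
        ("NaKATPase", "cTAL", 1.20),
    ])
    def test_transporter_multipliers(self, transporter, segment, factor):
        s = ns.moderate_diabetes()
        assert s.transporter_multipliers[transporter][segment] == factor

    def test_water_permeability_multipliers(self):
        s = ns.severe_diabetes()
        assert s.water_perm_multipliers == {"CCD": 1.55, "IMCD": 1.40}

    def test_imcd_pump_profiles(self):
        mod = ns.moderate_diabetes()
        assert mod.imcd_pump_profile == ((0.0, 2 / 3, 1.5), (2 / 3, 1.0, 2.5))
        sev = ns.severe_diabetes()
        assert sev.imcd_pump_profile == ((0.0, 1.0, 2.5),)


class TestApplication:
    def test_nondiabetic_is_identity_overlay(self, default_params):
        nd = ns.nondiabetic()
        params, arch = nd.apply(default_params)
        assert params.get("plasma.glucose") == 5.0
        _, gfr = single_kidney_gfr(arch)
        assert gfr == pytest.approx(151.2, rel=1e-3)

    def test_application_is_declarative(self, default_params):
        s = ns.with_sglt2i(ns.severe_diabetes())
        p1, a1 = s.apply(default_params)
        p2, a2 = s.apply(default_params)
        assert p1.content_hash() == p2.content_hash()
        assert a1.nephron_class("jm2").sngfr == a2.nephron_class("jm2").sngfr

    def test_severe_gfr_rises_by_24_percent(self, default_params):
        _, arch = ns.severe_diabetes().apply(default_params)
        _, base = ns.nondiabetic().apply(default_params)
        ratio = single_kidney_gfr(arch)[1] / single_kidney_gfr(base)[1]
        assert ratio == pytest.approx(1.24, abs=0.01)

    def test_moderate_results_text_variant_is_plus_10(self, default_params):
        _, arch = ns.moderate_diabetes(gfr_mode="results_text").apply(
            default_params)
        assert single_kidney_gfr(arch)[1] == pytest.approx(1.10 * 151.2,
                                                           rel=1e-9)

    def test_sglt2i_on_nondiabetic_cuts_sngfr_3_percent(self, default_params):
        s = ns.with_sglt2i(ns.nondiabetic())
        assert s.sngfr_multiplier_superficial == pytest.approx(0.97)
        assert s.sglt2_inhibition_fraction == 0.9
        _, arch = s.apply(default_params)
        assert arch.nephron_class("superficial").sngfr == pytest.approx(97.0)

    def test_sglt2i_on_diabetic_normalises_gfr(self, default_params):
        s = ns.with_sglt2i(ns.severe_diabetes())
        assert s.gfr_override_l_day == 151.2
        assert s.plasma_glucose == 20.0  # acute: glycemia unchanged
        _, arch = s.apply(default_params)
        assert single_kidney_gfr(arch)[1] == pytest.approx(151.2, rel=1e-12)

    def test_sglt2i_changes_nothing_else(self, default_params):
        base = ns.severe_diabetes()
        treated = ns.with_sglt2i(base)
        pb, _ = base.apply(default_params)
        pt, _ = treated.apply(default_params)
        # only SGLT2 inhibition_fraction differs in the parameter tree
        for seg in pb.raw["segments"]:
            for tid, spec in pb.raw["segments"][seg].get(
                    "transporters", {}).items():
                other = pt.raw["segments"][seg]["transporters"][tid]
                assert spec["vmax"] == other["vmax"], (seg, tid)
                if tid != "SGLT2":
                    assert spec.get("inhibition_fraction", 0) == \
                        other.get("inhibition_fraction", 0)

    def test_double_inhibition_rejected(self):
        with pytest.raises(ValueError):
            ns.with_sglt2i(ns.with_sglt2i(ns.nondiabetic()))

    def test_unknown_scenario_key_rejected(self):
        with pytest.raises(KeyError):
            get_scenario("nope")


class TestFilteredLoadArithmetic:
    def test_nondiabetic_glucose(self, default_params):
        load = filtered_load(ns.nondiabetic(), "glucose", default_params)
        # 151.2 L/day x 5 mM = 0.756 mol/day (at the exact GFR, 0.7556)
        assert load == pytest.approx(0.756, rel=1e-3)

    def test_severe_diabetes_glucose(self, default_params):
        load = filtered_load(ns.severe_diabetes(), "glucose", default_params)
        # printed 3.75 mol/day uses the rounded +24% GFR; exact +23.7%
        assert load == pytest.approx(3.75, rel=5e-3)

    def test_moderate_sglt2i_glucose(self, default_params):
        load = filtered_load(ns.with_sglt2i(ns.moderate_diabetes()),
                             "glucose", default_params)
        assert load == pytest.approx(1.30, rel=1e-3)

    def test_zero_plasma_concentration_gives_zero(self, default_params):
        import dataclasses
        s = dataclasses.replace(ns.nondiabetic(), plasma_glucose=0.0,
                                name="zero-glucose")
        # zero concentration must be representable without error
        assert filtered_load(s, "glucose", default_params) == 0.0
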