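"""Nephron population, geometry and coalescence topology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nephrosim.architecture import (InvalidParameterError,
                                    JUXTAMEDULLARY_CHAIN, SUPERFICIAL_CHAIN,
                                    build_default_architecture, merge_flows,
                                    scale_geometry, serialize_architecture,
                                    single_kidney_gfr)


@pytest.fixture(scope="module")
def arch():
    return build_default_architecture()


class TestDefaultArchitecture:
    def test_six_classes_with_85_15_split(self, arch):
        assert len(arch.nephron_classes) == 6
        sup = arch.nephron_class("superficial")
        assert sup.population_fraction == 0.85
        jm_total = sum(c.population_fraction for c in arch.nephron_classes
                       if c.id != "superficial")
        assert jm_total == pytest.approx(0.15, abs=1e-12)

    def test_population_fractions_sum_to_one(self, arch):
        total = sum(c.population_fraction for c in arch.nephron_classes)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_sngfr_values(self, arch):
        assert arch.nephron_class("superficial").sngfr == 100.0
        for i in range(1, 6):
            assert arch.nephron_class(f"jm{i}").sngfr == 133.0

    def test_segment_chain_order(self, arch):
        sup_ids = [s.segment_id for s in arch.segments["superficial"]]
        assert tuple(sup_ids) == SUPERFICIAL_CHAIN
        jm_ids = [s.segment_id for s in arch.segments["jm3"]]
        assert tuple(jm_ids) == JUXTAMEDULLARY_CHAIN
        assert [s.segment_id for s in arch.collecting_duct] == \
            ["CCD", "OMCD", "IMCD"]

    def test_jm_loop_depths_staggered_and_consistent(self, arch):
        depths = [arch.nephron_class(f"jm{i}").loop_turn_depth
                  for i in range(1, 6)]
        assert depths == sorted(depths)
        # limb lengths must match the stated turn depth (mm -> cm)
        for i in range(1, 6):
            segs = {s.segment_id: s for s in arch.segments[f"jm{i}"]}
            assert segs["LDL"].length == pytest.approx(depths[i - 1] / 10.0)
            assert segs["LAL"].length == pytest.approx(depths[i - 1] / 10.0)

    def test_most_long_loops_turn_in_upper_inner_medulla(self, arch):
        # population fraction decreases with loop depth
        fracs = [arch.nephron_class(f"jm{i}").population_fraction
                 for i in range(1, 6)]
        assert fracs == sorted(fracs, reverse=True)

    def test_topology_defaults(self, arch):
        assert arch.topology.cnt_merge_ratio == 10
        assert arch.total_nephrons == 1e6
        assert arch.n_ccd == pytest.approx(1e5)
        assert arch.topology.papillary_duct_count(arch.n_ccd) == \
            pytest.approx(6250)


class TestGfr:
    def test_single_kidney_gfr_matches_published_values(self, arch):
        ml_min, l_day = single_kidney_gfr(arch)
        # printed values are rounded (0.85*100 + 0.15*133 = 104.95 nL/min)
        assert ml_min == pytest.approx(105.0, rel=1e-3)
        assert l_day == pytest.approx(151.2, rel=1e-3)
        assert l_day == pytest.approx(ml_min * 1440 * 1e-3, rel=1e-12)

    @given(factor=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_gfr_linear_in_sngfr(self, factor):
        a = build_default_architecture()
        base = single_kidney_gfr(a)[0]
        for c in a.nephron_classes:
            c.sngfr *= factor
        assert single_kidney_gfr(a)[0] == pytest.approx(base * factor,
                                                        rel=1e-12)

    def test_gfr_linear_in_nephron_count(self, arch):
        base = single_kidney_gfr(arch)[0]
        arch2 = build_default_architecture({"total_nephrons": 2e6})
        assert single_kidney_gfr(arch2)[0] == pytest.approx(2 * base,
                                                            rel=1e-12)


class TestGeometryScaling:
    def test_proximal_scaling(self, arch):
        scaled = scale_geometry(arch, "proximal", 1.10, 1.10)
        for cid in ("superficial", "jm1"):
            for orig, new in zip(arch.segments[cid], scaled.segments[cid]):
                factor = 1.10 if orig.segment_id in ("PCT", "S3") else 1.0
                assert new.inner_diameter == pytest.approx(
                    orig.inner_diameter * factor)
                assert new.length == pytest.approx(orig.length * factor)

    def test_identity_scaling_is_noop(self, arch):
        scaled = scale_geometry(arch, "all", 1.0, 1.0)
        assert serialize_architecture(scaled) == serialize_architecture(arch)

    def test_original_unchanged(self, arch):
        before = serialize_architecture(arch)
        scale_geometry(arch, "distal", 1.42, 1.07)
        assert serialize_architecture(arch) == before

    @given(a=st.floats(0.5, 2.0), b=st.floats(0.5, 2.0))
    @settings(deadline=None, max_examples=20)
    def test_scaling_commutes(self, a, b):
        arch = build_default_architecture()
        two_step = scale_geometry(scale_geometry(arch, "proximal", a, a),
                                  "proximal", b, b)
        one_step = scale_geometry(arch, "proximal", a * b, a * b)
        for s1, s2 in zip(two_step.segments["superficial"],
                          one_step.segments["superficial"]):
            assert s1.inner_diameter == pytest.approx(s2.inner_diameter,
                                                      rel=1e-12)

    def test_nonpositive_multiplier_rejected(self, arch):
        with pytest.raises(InvalidParameterError):
            scale_geometry(arch, "proximal", 0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            scale_geometry(arch, "proximal", 1.0, -2.0)


class TestCoalescence:
    @given(st.lists(st.tuples(
        st.floats(1e-9, 1e-3), st.floats(0.0, 300.0), st.floats(0.0, 300.0)),
        min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_merge_conserves_every_flow(self, streams):
        flows = [np.array([fv, fv * c1, fv * c2]) for fv, c1, c2 in streams]
        weights = [float(i + 1) for i in range(len(flows))]
        merged = merge_flows(flows, weights)
        expected = sum(w * f for w, f in zip(weights, flows))
        residual = np.abs(merged - expected) / np.maximum(np.abs(expected),
                                                          1e-300)
        assert np.all(residual < 1e-10)

    def test_serialization_roundtrip_keys(self, arch):
        d = serialize_architecture(arch)
        assert set(d) == {"total_nephrons", "outer_medulla_depth_cm",
                          "inner_medulla_depth_cm", "nephron_classes",
                          "topology", "segments"}
        assert len(d["nephron_classes"]) == 6
        assert "collecting_duct" in d["segments"]
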