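"""Four-bar kinematics: scaling, closure, instant centre, lines of action."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from tcusim.geometry import (ANGULAR_PARAMS, LINEAR_PARAMS, PARAM_REGISTRY,
                             ClosureError, KneeGeometry, default_geometry,
                             load_geometry, scale_geometry, solve_four_bar,
                             structure_loas)


def _lengths(geom, state):
    ac = np.linalg.norm(state.ac_femur - geom.ac_tibia)
    pc = np.linalg.norm(state.pc_femur - geom.pc_tibia)
    link = np.linalg.norm(state.pc_femur - state.ac_femur)
    return ac, pc, link


class TestScaling:
    def test_identity_scale(self, base_geometry):
        out = scale_geometry(base_geometry, base_geometry.reference_tibia_length)
        for name in LINEAR_PARAMS + ANGULAR_PARAMS:
            assert out.param(name) == base_geometry.param(name)

    @given(factor=st_.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneity(self, factor):
        base = default_geometry()
        out = scale_geometry(base, factor * base.reference_tibia_length)
        for name in LINEAR_PARAMS:
            assert out.param(name) == pytest.approx(factor * base.param(name),
                                                    rel=1e-12)
        for name in ANGULAR_PARAMS:
            assert out.param(name) == base.param(name)

    def test_elementwise_oracle_137(self, base_geometry):
        # independent oracle: plain elementwise multiplication by 1.37
        out = scale_geometry(base_geometry,
                             1.37 * base_geometry.reference_tibia_length)
        expected = {n: base_geometry.param(n) * 1.37 for n in LINEAR_PARAMS}
        for name, want in expected.items():
            assert out.param(name) == pytest.approx(want, rel=1e-12)

    def test_nonpositive_tibia_rejected(self, base_geometry):
        with pytest.raises(ValueError):
            scale_geometry(base_geometry, 0.0)
        with pytest.raises(ValueError):
            scale_geometry(base_geometry, -0.4)


class TestFourBar:
    def test_range_enforced(self, base_geometry):
        with pytest.raises(ValueError, match="flexion angle"):
            solve_four_bar(base_geometry, -1.0)
        with pytest.raises(ValueError, match="flexion angle"):
            solve_four_bar(base_geometry, 135.5)

    def test_unsolvable_geometry_names_angle(self, base_geometry):
        with pytest.raises(ClosureError, match="deg"):
            # construction itself solves the extension pose and must fail loudly
            dataclasses.replace(base_geometry, ac_length=0.012, pc_length=0.012)

    def test_isometry_over_range(self, base_geometry):
        # cruciate isometric-fibre lengths must hold at every angle
        for ang in np.linspace(0.0, 135.0, 1000):
            state = solve_four_bar(base_geometry, float(ang))
            ac, pc, link = _lengths(base_geometry, state)
            assert abs(ac - base_geometry.ac_length) < 1e-9
            assert abs(pc - base_geometry.pc_length) < 1e-9
            assert abs(link - base_geometry.femoral_link_length) < 1e-9

    def test_instant_centre_oracle(self, base_geometry):
        # brute-force 2-line intersection of the returned cruciate lines
        state = solve_four_bar(base_geometry, 45.0)
        p1, d1 = base_geometry.ac_tibia, state.ac_femur - base_geometry.ac_tibia
        p2, d2 = base_geometry.pc_tibia, state.pc_femur - base_geometry.pc_tibia
        A = np.column_stack([d1, -d2])
        t = np.linalg.solve(A, p2 - p1)
        ic = p1 + t[0] * d1
        assert np.linalg.norm(ic - state.instant_centre) < 1e-9

    def test_ic_on_both_cruciate_lines(self, base_geometry):
        for ang in (0.0, 30.0, 90.0, 135.0):
            state = solve_four_bar(base_geometry, ang)
            for p, q in ((base_geometry.ac_tibia, state.ac_femur),
                         (base_geometry.pc_tibia, state.pc_femur)):
                d = (q - p) / np.linalg.norm(q - p)
                r = state.instant_centre - p
                assert abs(r[0] * d[1] - r[1] * d[0]) < 1e-9

    def test_rollback_monotone_and_continuous(self, base_geometry):
        angles = np.arange(0.0, 135.0 + 1e-9, 0.1)
        cx = np.array([solve_four_bar(base_geometry, a).contact_point[0]
                       for a in angles])
        # femoral rollback: contact point migrates posteriorly, no jumps
        assert np.all(np.diff(cx) < 1e-12)
        plateau = base_geometry.ac_tibia_anterior + base_geometry.pc_tibia_posterior
        assert np.max(np.abs(np.diff(cx))) < plateau / 100.0

    def test_reference_state_is_extension(self, base_geometry):
        ref = base_geometry.reference_state()
        assert ref.flexion_angle == 0.0
        again = solve_four_bar(base_geometry, 0.0)
        assert np.allclose(ref.ac_femur, again.ac_femur)


class TestStructureLoAs:
    @pytest.mark.parametrize("angle", [0.0, 15.0, 45.0, 90.0, 120.0, 135.0])
    def test_unit_directions(self, base_geometry, angle):
        loas = structure_loas(base_geometry, solve_four_bar(base_geometry, angle))
        for s, d in loas.directions.items():
            assert abs(np.linalg.norm(d) - 1.0) < 1e-12, s

    @pytest.mark.parametrize("angle", [5.0, 60.0, 100.0, 130.0])
    def test_tf_line_contains_instant_centre(self, base_geometry, angle):
        state = solve_four_bar(base_geometry, angle)
        loas = structure_loas(base_geometry, state)
        r = state.instant_centre - loas.origin("TF")
        d = loas.direction("TF")
        assert abs(r[0] * d[1] - r[1] * d[0]) < 1e-9

    def test_pt_origin_is_tuberosity_tibia_fixed(self, base_geometry):
        for angle in (0.0, 90.0):
            loas = structure_loas(base_geometry,
                                  solve_four_bar(base_geometry, angle))
            assert np.allclose(loas.origin("PT"), base_geometry.tuberosity)
        assert np.allclose(
            structure_loas(base_geometry, solve_four_bar(base_geometry, 0.0)).origin("HT"),
            base_geometry.hamstring_tibia)

    def test_provenance_mismatch_rejected(self, base_geometry):
        other = scale_geometry(base_geometry, 0.5)
        state = solve_four_bar(base_geometry, 30.0)
        with pytest.raises(ValueError, match="different geometry"):
            structure_loas(other, state)


class TestRegistryAndConfig:
    def test_exactly_fourteen_parameters(self, base_geometry):
        assert base_geometry.n_params == 14
        assert len(PARAM_REGISTRY) == 14
        tags = {t for _, t in PARAM_REGISTRY}
        assert tags == {"linear", "angular"}

    def test_with_param_roundtrip(self, base_geometry):
        g = base_geometry.with_param("trochlea_radius", 0.03)
        assert g.trochlea_radius == 0.03
        with pytest.raises(KeyError):
            base_geometry.with_param("nonexistent", 1.0)

    def test_config_rejects_wrong_parameter_set(self, tmp_path, base_geometry):
        doc = json.loads(
            (__import__("pathlib").Path(__import__("tcusim").__file__).parent
             / "data" / "default_geometry.json").read_text())
        doc["parameters"] = doc["parameters"][:-1]
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="exactly"):
            load_geometry(p)

    def test_nonpositive_length_rejected(self, base_geometry):
        with pytest.raises(ValueError, match="positive"):
            base_geometry.with_param("ac_length", -0.01)
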