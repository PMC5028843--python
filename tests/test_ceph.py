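"""Clinical measurements and skeletal classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cephaloc.ceph import (LandmarkSet, angle_at, angle_between_lines,
                           classify, compute_parameters, PARAMETER_NAMES)
from cephaloc.synth import make_template


def template_lm(spacing=1.0):
    return LandmarkSet(points=make_template(), spacing=spacing)


finite_coord = st.floats(-1000, 1000, allow_nan=False)


class TestAngles:
    def test_right_angle(self):
        assert angle_at((0, 0), (1, 0), (0, 1)) == pytest.approx(90.0)

    def test_collinear_same_side_is_zero(self):
        assert angle_at((0, 0), (2, 2), (5, 5)) == pytest.approx(0.0)

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            angle_at((1, 1), (1, 1), (0, 0))

    @given(st.lists(finite_coord, min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_dot_product_oracle(self, coords):
        v, p, q = np.array(coords).reshape(3, 2)
        if np.allclose(p, v) or np.allclose(q, v):
            return
        u1, u2 = p - v, q - v
        cosv = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        expected = math.degrees(math.acos(np.clip(cosv, -1, 1)))
        assert angle_at(v, p, q) == pytest.approx(expected, abs=1e-6)

    def test_perpendicular_and_parallel_lines(self):
        assert angle_between_lines((0, 0), (1, 0), (5, 5), (5, 9)) == pytest.approx(90.0)
        assert angle_between_lines((0, 0), (1, 1), (4, 0), (6, 2)) == pytest.approx(0.0)

    def test_acute_form_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a1, a2, b1, b2 = rng.uniform(-10, 10, (4, 2))
            u, v = a2 - a1, b2 - b1
            phi = math.degrees(abs(math.atan2(u[0] * v[1] - u[1] * v[0],
                                              np.dot(u, v))))
            expected = min(phi, 180.0 - phi)
            assert angle_between_lines(a1, a2, b1, b2) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            angle_between_lines((0, 0), (0, 0), (1, 0), (2, 0))


class TestParameters:
    def test_modified_wits_three_four_five(self):
        lm = template_lm(spacing=0.1)
        lm.points[10] = (100.0, 50.0)   # L11
        lm.points[11] = (103.0, 54.0)   # L12
        assert compute_parameters(lm)["MW"] == pytest.approx(0.5)

    def test_fhi_hand_computed(self):
        lm = template_lm(spacing=1.0)
        lm.points[0] = (0.0, 0.0)     # L1
        lm.points[9] = (0.0, 70.0)    # L10
        lm.points[1] = (10.0, 0.0)    # L2
        lm.points[7] = (10.0, 100.0)  # L8
        assert compute_parameters(lm)["FHI"] == pytest.approx(0.70)

    def test_mw_zero_when_x_coordinates_tie(self):
        lm = template_lm()
        lm.points[10] = (50.0, 60.0)
        lm.points[11] = (50.0, 55.0)
        assert compute_parameters(lm)["MW"] == 0.0

    def test_all_parameters_finite_on_template(self):
        values = compute_parameters(template_lm())
        assert set(values) == set(PARAMETER_NAMES)
        assert all(np.isfinite(v) for v in values.values())

    def test_translation_invariance(self):
        lm = template_lm()
        moved = LandmarkSet(points=lm.points + [123.0, -45.0], spacing=lm.spacing)
        v1, v2 = compute_parameters(lm), compute_parameters(moved)
        for p in PARAMETER_NAMES:
            assert v1[p] == pytest.approx(v2[p], abs=1e-9)

    def test_angles_invariant_to_rotation_and_scale(self):
        lm = template_lm()
        ang = 0.4
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = LandmarkSet(points=2.5 * lm.points @ R.T, spacing=lm.spacing)
        v1, v2 = compute_parameters(lm), compute_parameters(moved)
        for p in ("ANB", "SNB", "SNA", "ODI", "APDI", "FMA", "FHI"):
            assert v1[p] == pytest.approx(v2[p], abs=1e-9)

    def test_anb_equals_sna_minus_snb_when_rays_align(self):
        # place sella, A and B so that N->S, N->A, N->B angles nest
        lm = template_lm()
        lm.points[1] = (0.0, 0.0)            # nasion at the vertex
        lm.points[0] = (-100.0, 0.0)         # sella
        for deg_a, deg_b in ((60.0, 40.0), (100.0, 70.0)):
            lm.points[4] = 80 * np.array([np.cos(np.radians(deg_a)),
                                          np.sin(np.radians(deg_a))])
            lm.points[5] = 90 * np.array([np.cos(np.radians(deg_b)),
                                          np.sin(np.radians(deg_b))])
            v = compute_parameters(lm)
            assert v["ANB"] == pytest.approx(abs(v["SNA"] - v["SNB"]), abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("param,value,expected", [
        ("ANB", 4.0, "C1"), ("ANB", 3.2, "C1"), ("ANB", 5.7, "C1"),
        ("ANB", 5.71, "C2"), ("ANB", 3.19, "C3"),
        ("SNB", 76.0, "C1"), ("SNB", 74.5, "C2"), ("SNB", 78.8, "C3"),
        ("SNA", 80.0, "C1"), ("SNA", 83.3, "C2"), ("SNA", 79.3, "C3"),
        ("ODI", 74.0, "C1"), ("ODI", 80.6, "C2"), ("ODI", 68.3, "C3"),
        ("APDI", 81.0, "C1"), ("APDI", 77.5, "C2"), ("APDI", 85.3, "C3"),
        ("FHI", 0.70, "C1"), ("FHI", 0.80, "C2"), ("FHI", 0.64, "C3"),
        ("FMA", 29.0, "C1"), ("FMA", 31.5, "C2"), ("FMA", 26.7, "C3"),
        ("MW", 3.0, "C1"), ("MW", 0.0, "C2"), ("MW", -1.0, "C3"),
        ("MW", 5.0, "C4"), ("MW", 1.0, "C5"), ("MW", 2.0, "C1"),
        ("MW", 4.5, "C1"), ("MW", 1.99, "C5"),
    ])
    def test_class_boundaries(self, param, value, expected):
        values = compute_parameters(template_lm())
        values[param] = value
        assert classify(values)[param] == expected

    def test_partition_is_total_and_changes_only_at_boundaries(self):
        # scan a fine grid over each parameter's domain: exactly one class
        # everywhere, and class changes only at the published thresholds
        domains = {
            "ANB": (np.linspace(-5, 15, 2001), {3.2, 5.7}),
            "SNB": (np.linspace(60, 95, 3501), {74.6, 78.7}),
            "SNA": (np.linspace(65, 95, 3001), {79.4, 83.2}),
            "ODI": (np.linspace(50, 100, 5001), {68.4, 80.5}),
            "APDI": (np.linspace(60, 100, 4001), {77.6, 85.2}),
            "FHI": (np.linspace(0.4, 1.0, 6001), {0.65, 0.75}),
            "FMA": (np.linspace(10, 50, 4001), {26.8, 31.4}),
            "MW": (np.linspace(-5, 10, 1501), {0.0, 2.0, 4.5}),
        }
        base = compute_parameters(template_lm())
        for param, (grid, boundaries) in domains.items():
            values = dict(base)
            prev_class, prev_v = None, None
            for v in grid:
                values[param] = float(v)
                cls = classify(values)[param]
                assert cls in {"C1", "C2", "C3", "C4", "C5"}
                if prev_class is not None and cls != prev_class:
                    crossed = any(min(prev_v, v) <= b <= max(prev_v, v)
                                  for b in boundaries)
                    assert crossed, f"{param} changed class away from a boundary"
                prev_class, prev_v = cls, v

    def test_non_finite_value_rejected(self):
        values = compute_parameters(template_lm())
        values["FMA"] = float("nan")
        with pytest.raises(ValueError):
            classify(values)

    def test_missing_parameter_rejected(self):
        values = compute_parameters(template_lm())
        del values["ANB"]
        with pytest.raises(ValueError):
            classify(values)
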