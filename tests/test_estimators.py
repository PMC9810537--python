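import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from lvvol.estimators import (bod_volume, chord_diameters, cone_volume,
                              frustum_volume, sbr_volume, slant_angle,
                              tbc_volume)
from lvvol.geometry import Contour2D
from lvvol.synthetic import (ParaboloidSpec, ViewConfig, truth_volume,
                             view_pair)

from .conftest import pentagon_contour, semicircle_contour
from .oracles import hemisphere_disk_sum_ml


def quad_frustum_ml(a1, b1, a2, b2, h):
    """1-D quadrature of pi*a(t)*b(t)/4 over the element height."""

    def area(t):
        a = a1 + (a2 - a1) * t
        b = b1 + (b2 - b1) * t
        return np.pi * a * b / 4.0

    val, _ = integrate.quad(area, 0.0, 1.0, epsabs=1e-14, epsrel=1e-13)
    return val * h / 1000.0


class TestElementVolumes:
    def test_cylinder_limit(self):
        assert frustum_volume(20, 20, 20, 20, 10) == pytest.approx(
            np.pi * 20 * 20 * 10 / 4 / 1000)

    def test_cone_limit_and_consistency(self):
        expected = np.pi * 20 * 20 * 10 / 12 / 1000  # 1047.2 mm^3
        assert cone_volume(20, 20, 10) == pytest.approx(expected)
        assert cone_volume(0, 15, 10) == 0.0
        assert frustum_volume(20, 20, 0, 0, 10) == pytest.approx(
            cone_volume(20, 20, 10))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            frustum_volume(-1, 2, 3, 4, 5)
        with pytest.raises(ValueError):
            cone_volume(1, 2, -3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 60.0), min_size=4, max_size=4),
           st.floats(0.5, 30.0))
    def test_frustum_matches_quadrature(self, diams, h):
        a1, b1, a2, b2 = diams
        assert frustum_volume(a1, b1, a2, b2, h) == pytest.approx(
            quad_frustum_ml(a1, b1, a2, b2, h), rel=1e-9, abs=1e-15)


class TestChordProfiles:
    def test_constant_width_region(self):
        c = pentagon_contour(width=30.0, height=60.0, apex_drop=20.0)
        prof = chord_diameters(c, "long_axis_perpendicular", 20, "midpoint")
        # levels inside the straight-walled band all read the full width
        band = (prof.levels > 25.0) & (prof.levels < 75.0)
        assert band.sum() >= 5
        assert np.allclose(prof.diameters[band], 30.0)

    def test_semicircle_boundary_chords(self):
        r = 30.0
        c = semicircle_contour(radius=r, n=2001)
        prof = chord_diameters(c, "long_axis_perpendicular", 10, "boundary")
        # level i sits at depth r - i*r/10 from the base
        depth = r - prof.levels
        expected = 2 * np.sqrt(np.clip(r**2 - depth**2, 0, None))
        assert np.allclose(prof.diameters, expected, atol=0.05)

    def test_directions_agree_for_flat_base(self):
        c = semicircle_contour(radius=25.0, n=1001)
        p1 = chord_diameters(c, "long_axis_perpendicular", 8, "boundary")
        p2 = chord_diameters(c, "basal_parallel", 8, "boundary")
        assert np.allclose(p1.diameters, p2.diameters, atol=1e-6)

    def test_slanted_base_stacking_direction_matters(self, ideal_view):
        # at a 20 deg slanted base, chords parallel to the basal chord reach
        # the full annulus width while long-axis-perpendicular chords are
        # clipped by the slant (the disk misfit that biases SBR low)
        spec = ParaboloidSpec.for_view_slant(20.0, ideal_view,
                                             eccentricity=1.1)
        c, _ = view_pair(spec, ideal_view)
        basal = chord_diameters(c, "basal_parallel", 20, "boundary")
        perp = chord_diameters(c, "long_axis_perpendicular", 20, "boundary")
        assert basal.diameters[-1] == pytest.approx(c.basal_chord_length,
                                                    rel=1e-6)
        assert perp.diameters[-1] < 0.85 * basal.diameters[-1]

    def test_levels_outside_contour_read_zero(self):
        c = semicircle_contour(radius=20.0)
        prof = chord_diameters(c, "long_axis_perpendicular", 10, "midpoint",
                               span=40.0)
        assert prof.diameters[-1] == 0.0


class TestSlantAngle:
    def test_symmetric_contour_zero(self):
        assert slant_angle(semicircle_contour()) == pytest.approx(0, abs=1e-9)

    def test_constructed_angle_recovered(self):
        w, h, ang = 25.0, 70.0, 10.0
        dz = 2 * w * np.tan(np.radians(ang))
        u = np.linspace(-w, w, 401)
        z = h * (u / w) ** 2 + (u + w) / (2 * w) * dz
        assert abs(slant_angle(Contour2D(np.column_stack([u, z])))) == \
            pytest.approx(ang, abs=1.0)

    def test_workbench_view_slant(self, slanted_pair):
        cA, cB = slanted_pair
        assert abs(slant_angle(cA)) == pytest.approx(7.0, abs=0.5)
        assert abs(slant_angle(cB)) == pytest.approx(7.0, abs=0.5)


class TestEstimators:
    def test_sbr_hemisphere_matches_disk_sum_oracle(self):
        r = 30.0
        c = semicircle_contour(radius=r, n=2001)
        stack = sbr_volume(c, c, n=20)
        assert stack.total_volume == pytest.approx(
            hemisphere_disk_sum_ml(r, 20), rel=1e-3)

    def test_sbr_exact_on_unslanted_paraboloid(self, unslanted_spec,
                                               ideal_view):
        # cross-section area is linear in height, so the midpoint rule is
        # exact for any disk count
        cA, cB = view_pair(unslanted_spec, ideal_view)
        truth = truth_volume(unslanted_spec)
        for n in (4, 7, 20, 33):
            err = abs(sbr_volume(cA, cB, n=n).total_volume - truth) / truth
            assert err < 1e-3

    def test_no_slant_degeneracy_tbc_equals_bod(self, unslanted_spec,
                                                ideal_view):
        cA, cB = view_pair(unslanted_spec, ideal_view)
        tbc = tbc_volume(cA, cB)
        bod = bod_volume(cA, cB)
        assert not any(e.kind == "half_cylinder" for e in tbc.elements)
        assert tbc.total_volume == pytest.approx(bod.total_volume, rel=1e-6)
        assert bod.total_volume == pytest.approx(
            truth_volume(unslanted_spec), rel=1e-2)

    def test_swapping_views_changes_nothing(self, slanted_pair):
        cA, cB = slanted_pair
        for method in (sbr_volume, tbc_volume, bod_volume):
            v1 = method(cA, cB).total_volume
            v2 = method(cB, cA).total_volume
            assert v2 == pytest.approx(v1, rel=1e-9)

    def test_rigid_motion_and_cubic_scaling(self, slanted_pair):
        cA, cB = slanted_pair
        s = 1.6
        cAm = cA.transformed(rotation_deg=40.0, translation=(7, -3), scale=s)
        cBm = cB.transformed(rotation_deg=-15.0, translation=(0, 9), scale=s)
        for method in (sbr_volume, tbc_volume, bod_volume):
            v = method(cA, cB).total_volume
            vm = method(cAm, cBm).total_volume
            assert vm == pytest.approx(s**3 * v, rel=1e-6)

    def test_disk_count_convergence(self, slanted_pair):
        cA, cB = slanted_pair
        for method in (sbr_volume, tbc_volume, bod_volume):
            v20 = method(cA, cB, n=20).total_volume
            v2000 = method(cA, cB, n=2000).total_volume
            assert abs(v20 - v2000) / v2000 < 0.005

    def test_stack_bookkeeping(self, slanted_pair):
        cA, cB = slanted_pair
        stack = bod_volume(cA, cB)
        assert stack.n == 20
        assert len(stack.elements) == 20
        assert stack.elements[0].kind == "cone"
        assert all(e.kind == "frustum" for e in stack.elements[1:])
        heights = sum(e.h for e in stack.elements)
        assert heights == pytest.approx(stack.L_used, rel=1e-9)
        assert stack.total_volume == pytest.approx(
            sum(e.volume_ml for e in stack.elements))

    def test_tbc_overestimates_when_one_view_slanted(self):
        # worst case: one view slanted 20 deg, the other flat; the inflated
        # shared length plus the basal add-on overshoot beyond the magnitude
        # of the plain disk-sum underestimation
        from lvvol.synthetic import analytic_view_contour

        spec = ParaboloidSpec(eccentricity=1.1, slant_angle_deg=20.0,
                              slant_axis="minor")
        truth = truth_volume(spec)
        c1 = analytic_view_contour(spec, 0.0)    # sees the full slant
        c2 = analytic_view_contour(spec, 90.0)   # flat base
        e_tbc = tbc_volume(c1, c2).total_volume / truth - 1.0
        e_sbr = sbr_volume(c1, c2).total_volume / truth - 1.0
        assert e_tbc > 0 > e_sbr
        assert e_tbc > abs(e_sbr)

    def test_sbr_error_grows_with_slant(self, ideal_view):
        errs = []
        for b in (0, 5, 10, 15, 20):
            spec = ParaboloidSpec.for_view_slant(b, ideal_view,
                                                 eccentricity=1.1)
            cA, cB = view_pair(spec, ideal_view)
            truth = truth_volume(spec)
            errs.append(abs(sbr_volume(cA, cB).total_volume - truth) / truth)
        assert np.all(np.diff(errs) > 0)

    def test_bod_most_accurate_under_strong_slant(self, ideal_view):
        spec = ParaboloidSpec.for_view_slant(20.0, ideal_view,
                                             eccentricity=1.1)
        cA, cB = view_pair(spec, ideal_view)
        truth = truth_volume(spec)
        errs = {m.__name__: abs(m(cA, cB).total_volume - truth) / truth
                for m in (sbr_volume, tbc_volume, bod_volume)}
        assert errs["bod_volume"] < errs["sbr_volume"]
        assert errs["bod_volume"] < errs["tbc_volume"]
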