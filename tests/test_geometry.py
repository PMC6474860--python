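"""Geometric measurands: thickness, radius fit, displacement, cap height/volume."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octinflate as oi
from octinflate.errors import (
    DegenerateFitError,
    InvalidParameterError,
    MissingReferenceError,
    WindowCoverageError,
)
from octinflate.geometry import GeometrySeries

from test_segmentation import make_pair


def circle_pair(radius_mm, span_mm=8.0, n=801, apex_depth=500.0, gap=1000.0):
    x = np.linspace(-span_mm * 500, span_mm * 500, n)
    r_um = radius_mm * 1000.0
    ant = apex_depth + r_um - np.sqrt(r_um**2 - x**2)
    return make_pair(x - x.min(), ant, ant + gap, units="physical")


class TestApexThickness:
    def test_flat_slab_returns_constant_gap(self):
        x = np.arange(0, 8000.0, 10.0)
        pair = make_pair(x, np.full_like(x, 300.0), np.full_like(x, 1300.0), "physical")
        assert oi.apex_thickness(pair) == pytest.approx(1000.0)

    def test_synthetic_cornea_at_15_mmhg(self, noiseless_measured):
        rec = next(r for r in noiseless_measured if r.P == 15.0 and r.phase == "loading")
        assert rec.T_um == pytest.approx(968.1, abs=2.2)

    def test_short_traces_raise(self):
        x = np.arange(0, 2000.0, 10.0)  # 2 mm only
        pair = make_pair(x, np.full_like(x, 300.0), np.full_like(x, 1300.0), "physical")
        with pytest.raises(WindowCoverageError):
            oi.apex_thickness(pair)


class TestRadiusFit:
    def test_exact_circle_recovered(self):
        pair = circle_pair(8.448)
        assert oi.fit_radius(pair) == pytest.approx(8.448, rel=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_three_points_give_the_circumcircle(self, data):
        pts = data.draw(
            st.lists(
                st.tuples(st.floats(-1000, 1000), st.floats(-1000, 1000)),
                min_size=3,
                max_size=3,
                unique=True,
            )
        )
        (x1, y1), (x2, y2), (x3, y3) = pts
        area2 = abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
        if area2 < 100.0:  # nearly collinear: ill-conditioned, skip
            return
        a = np.hypot(x2 - x3, y2 - y3)
        b = np.hypot(x1 - x3, y1 - y3)
        c = np.hypot(x1 - x2, y1 - y2)
        circumradius = a * b * c / (2.0 * area2)
        if circumradius > 1e5:
            return
        from octinflate.geometry import _fit_circle

        _, _, r = _fit_circle(np.array([x1, x2, x3]), np.array([y1, y2, y3]))
        assert r == pytest.approx(circumradius, rel=1e-6)

    def test_collinear_points_raise(self):
        from octinflate.geometry import _fit_circle

        with pytest.raises(DegenerateFitError):
            _fit_circle(np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0, 3.0]))

    def test_translation_and_order_invariance(self):
        from octinflate.geometry import _fit_circle

        rng = np.random.default_rng(0)
        theta = rng.uniform(1.2, 1.9, 40)
        x, z = 7000 * np.cos(theta), 7000 * np.sin(theta)
        _, _, r0 = _fit_circle(x, z)
        _, _, r_shift = _fit_circle(x + 1234.5, z - 987.6)
        perm = rng.permutation(len(x))
        _, _, r_perm = _fit_circle(x[perm], z[perm])
        assert r_shift == pytest.approx(r0, rel=1e-9)
        assert r_perm == pytest.approx(r0, rel=1e-9)

    def test_noiseless_bscan_radius_within_one_percent(self, noiseless_measured):
        rec = next(r for r in noiseless_measured if r.P == 15.0 and r.phase == "loading")
        assert rec.R_mm == pytest.approx(8.373, rel=0.01)


class TestApexDisplacement:
    def test_identical_traces_give_zero(self):
        pair = circle_pair(8.4)
        assert oi.apex_displacement(pair, pair) == pytest.approx(0.0, abs=1e-9)

    def test_shallower_trace_gives_positive_shift(self):
        ref = circle_pair(8.4, apex_depth=500.0)
        cur = circle_pair(8.4, apex_depth=450.0)
        assert oi.apex_displacement(cur, ref) == pytest.approx(50.0, abs=1e-9)

    def test_missing_reference_raises(self):
        with pytest.raises(MissingReferenceError):
            oi.apex_displacement(circle_pair(8.4), None)

    def test_full_noiseless_stack_displacement_within_one_pixel(
        self, noiseless_measured, cycle_states, noiseless_optics
    ):
        ref_D = next(s.D_um for s in cycle_states if s.P == 2.0 and s.phase == "loading")
        px = noiseless_optics.axial_um_per_px
        for rec, truth in zip(noiseless_measured, cycle_states):
            assert abs(rec.dD_um - (truth.D_um - ref_D)) <= px


class TestCapHeightAndVolume:
    def test_reference_identity(self):
        assert oi.cap_height(3.0, 0.0, 0.0) == pytest.approx(3.0)

    def test_hand_arithmetic_example(self):
        assert oi.cap_height(3.0, 143.0, 52.0) == pytest.approx(3.195)

    def test_non_positive_reference_raises(self):
        with pytest.raises(InvalidParameterError):
            oi.cap_height(0.0, 10.0, 10.0)

    def test_collapsed_height_raises(self):
        with pytest.raises(InvalidParameterError):
            oi.cap_height(1.0, -2000.0, 0.0)

    def test_volume_zero_height(self):
        assert oi.cap_volume(0.0, 5.25) == 0.0

    def test_volume_hand_arithmetic(self):
        assert oi.cap_volume(3.0, 5.25) == pytest.approx(np.pi / 2 * 3.0 * 5.25**2)
        assert oi.cap_volume(3.0, 5.25) == pytest.approx(129.89, abs=0.01)

    def test_negative_height_raises(self):
        with pytest.raises(InvalidParameterError):
            oi.cap_volume(-1.0, 5.25)

    @settings(deadline=None, max_examples=50)
    @given(H=st.floats(0.01, 10), B=st.floats(0.1, 20), k=st.floats(0.1, 10))
    def test_scaling_linear_in_height_quadratic_in_base(self, H, B, k):
        v = oi.cap_volume(H, B)
        assert oi.cap_volume(k * H, B) == pytest.approx(k * v, rel=1e-12)
        assert oi.cap_volume(H, k * B) == pytest.approx(k * k * v, rel=1e-12)


class TestFullGeometryRoundTrip:
    def test_noiseless_stack_reproduces_every_truth_field(
        self, noiseless_measured, cycle_states, noiseless_optics, params
    ):
        """Noiseless render -> segment -> measure recovers T, R, D, H."""
        px = noiseless_optics.axial_um_per_px
        ref_D = next(s.D_um for s in cycle_states if s.P == 2.0 and s.phase == "loading")
        for rec, truth in zip(noiseless_measured, cycle_states):
            assert abs(rec.T_um - truth.T_um) <= max(px, 2.2)
            assert rec.R_mm == pytest.approx(truth.R_mm, rel=0.01)
            assert abs(rec.dD_um - (truth.D_um - ref_D)) <= px
            assert rec.H_mm == pytest.approx(truth.H_mm, abs=0.005)

    def test_truth_series_requires_reference_step(self, params):
        schedule = oi.PressureSchedule(
            (oi.PressureStep(5.0, "loading"), oi.PressureStep(10.0, "loading"))
        )
        states = oi.simulate_geometry(schedule, params)
        with pytest.raises(MissingReferenceError):
            GeometrySeries.from_truth(states)
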