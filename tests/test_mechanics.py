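"""Thin-shell stress, volumetric strain, tangent modulus and loop area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octinflate as oi
from octinflate.errors import (
    DisjointStrainError,
    InvalidParameterError,
    MissingReferenceError,
)
from octinflate.geometry import GeometrySeries
from octinflate.mechanics import HysteresisResult, MechanicsConfig, StressStrainCurve
from octinflate.pipeline import hysteresis_by_hour


def curve(eps, sigma, phase="loading", hour=0.0):
    eps = np.asarray(eps, float)
    return StressStrainCurve(phase, hour, np.arange(len(eps), dtype=float), np.asarray(sigma, float), eps)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "mmhg,kpa", [(0.0, 0.0), (10.5, 1.4), (15.8, 2.1)]
    )
    def test_printed_pressure_pairs(self, mmhg, kpa):
        assert round(oi.mmhg_to_kpa(mmhg), 1) == kpa


class TestStress:
    def test_zero_pressure_zero_stress(self):
        assert oi.circumferential_stress(0.0, 8.4, 1000.0) == 0.0

    def test_hand_evaluation_at_15_mmhg(self):
        assert oi.circumferential_stress(15.0, 8.373, 980.0) == pytest.approx(8.54, abs=0.01)

    @settings(deadline=None, max_examples=40)
    @given(P=st.floats(0.1, 60), R=st.floats(5, 12), T=st.floats(500, 1500), k=st.floats(1.1, 4))
    def test_scaling_linear_in_pressure_inverse_in_thickness(self, P, R, T, k):
        s = oi.circumferential_stress(P, R, T)
        assert oi.circumferential_stress(k * P, R, T) == pytest.approx(k * s, rel=1e-12)
        assert oi.circumferential_stress(P, R, k * T) == pytest.approx(s / k, rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(InvalidParameterError):
            oi.circumferential_stress(10.0, -1.0, 1000.0)
        with pytest.raises(InvalidParameterError):
            oi.circumferential_stress(10.0, 8.4, 0.0)


class TestStrainAndModulus:
    def test_reference_state_strain_is_zero(self):
        assert oi.volumetric_strain(100.0, 100.0) == 0.0

    def test_five_percent_inflation(self):
        assert oi.volumetric_strain(100.0, 105.0) == pytest.approx(0.05)

    def test_strain_from_cap_height_example(self):
        V_ref = oi.cap_volume(3.0, 5.25)
        V = oi.cap_volume(3.195, 5.25)
        assert oi.volumetric_strain(V_ref, V) == pytest.approx(3.195 / 3.0 - 1.0, rel=1e-12)

    def test_modulus_coefficient(self):
        assert oi.tangent_modulus(1.0, 1.0, 0.4) == pytest.approx(1.8)

    def test_modulus_hand_arithmetic(self):
        assert oi.tangent_modulus(8.54, 0.0768, 0.4) == pytest.approx(200.2, abs=0.1)

    def test_modulus_undefined_at_reference(self):
        with pytest.raises(InvalidParameterError):
            oi.tangent_modulus(1.0, 0.0)

    def test_poisson_ratio_range(self):
        with pytest.raises(InvalidParameterError):
            oi.tangent_modulus(1.0, 0.1, 0.6)
        with pytest.raises(InvalidParameterError):
            MechanicsConfig(v=0.5)

    @settings(deadline=None, max_examples=40)
    @given(s=st.floats(0.1, 50), e=st.floats(0.001, 0.5), k=st.floats(1.1, 5))
    def test_modulus_linear_in_stress_at_fixed_strain(self, s, e, k):
        assert oi.tangent_modulus(k * s, e) == pytest.approx(
            k * oi.tangent_modulus(s, e), rel=1e-12
        )


class TestBuildCurves:
    def test_modulus_increases_and_is_nearly_linear_at_high_pressure(self, cycle_states):
        series = GeometrySeries.from_truth(cycle_states)
        _, moduli = oi.build_curves(series)
        loading = [(m.P, m.E_kpa) for m in moduli if m.phase == "loading"]
        P = np.array([p for p, _ in loading])
        E = np.array([e for _, e in loading])
        high = P >= 10
        assert np.all(np.diff(E[high]) > 0)
        lin = P >= 20
        fit = np.polyfit(P[lin], E[lin], 1)
        resid = E[lin] - np.polyval(fit, P[lin])
        ss_res, ss_tot = resid @ resid, np.sum((E[lin] - E[lin].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.98

    def test_reference_step_emits_no_modulus_point(self, cycle_states):
        series = GeometrySeries.from_truth(cycle_states)
        _, moduli = oi.build_curves(series)
        assert not any(m.P == 2.0 and m.phase == "loading" for m in moduli)

    def test_sub_reference_steps_excluded_from_curves(self, cycle_states):
        series = GeometrySeries.from_truth(cycle_states)
        curves, _ = oi.build_curves(series)
        for c in curves:
            assert np.all(c.P >= 2.0)

    def test_missing_reference_raises(self, params):
        schedule = oi.PressureSchedule(
            tuple(oi.PressureStep(p, "loading") for p in (2.0, 5.0, 15.0))
        )
        states = oi.simulate_geometry(schedule, params)
        series = GeometrySeries.from_truth(states)
        series.records = [r for r in series.records if r.P != 2.0]
        with pytest.raises(MissingReferenceError):
            oi.build_curves(series)


class TestHysteresisArea:
    def test_identical_curves_enclose_nothing(self):
        c = curve([0.0, 0.05, 0.1], [1.0, 5.0, 9.0])
        r = oi.hysteresis_area(c, curve([0.0, 0.05, 0.1], [1.0, 5.0, 9.0], "unloading"))
        assert r.area_kpa == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines_give_rectangle_area(self):
        load = curve([0.0, 0.1], [2.0, 6.0])
        unload = curve([0.0, 0.1], [1.0, 5.0], "unloading")
        r = oi.hysteresis_area(load, unload)
        assert r.area_kpa == pytest.approx(0.1, rel=1e-9)
        assert r.area_mmhg == pytest.approx(0.1 / 0.1333224, rel=1e-9)

    def test_loop_of_ten_and_a_half_mmhg_is_1_4_kpa(self):
        """A loop whose area measures 10.5 mmHg reads ~1.4 kPa in stress units."""
        target_kpa = 10.5 * 0.1333224
        span = 0.2
        load = curve([0.0, span], [target_kpa / span, 2 * target_kpa / span])
        unload = curve([0.0, span], [0.0, target_kpa / span], "unloading")
        r = oi.hysteresis_area(load, unload)
        assert r.area_mmhg == pytest.approx(10.5, rel=1e-9)
        assert r.area_kpa == pytest.approx(1.4, abs=0.01)

    def test_symmetric_in_arguments_and_point_order(self):
        rng = np.random.default_rng(1)
        eps = np.sort(rng.uniform(0, 0.3, 9))
        load = curve(eps, rng.uniform(5, 10, 9))
        unload = curve(eps, rng.uniform(0, 5, 9), "unloading")
        a = oi.hysteresis_area(load, unload).area_kpa
        b = oi.hysteresis_area(unload, load).area_kpa
        rev = curve(eps[::-1], load.sigma_kpa[::-1])
        c = oi.hysteresis_area(rev, unload).area_kpa
        assert a == pytest.approx(b, rel=1e-12)
        assert a == pytest.approx(c, rel=1e-12)

    def test_grid_convergence_below_point_one_percent(self, cycle_states):
        series = GeometrySeries.from_truth(cycle_states)
        curves, _ = oi.build_curves(series)
        load = next(c for c in curves if c.phase == "loading")
        unload = next(c for c in curves if c.phase == "unloading")
        a512 = oi.hysteresis_area(load, unload, n_grid=512).area_kpa
        a1024 = oi.hysteresis_area(load, unload, n_grid=1024).area_kpa
        assert abs(a1024 - a512) / a512 < 1e-3

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_matches_shoelace_polygon_oracle_on_piecewise_linear_loops(self, data):
        """Trapezoidal loop area equals the exact polygon (shoelace) area."""
        m = data.draw(st.integers(3, 8))
        sig_hi = data.draw(
            st.lists(st.floats(5.0, 10.0), min_size=m, max_size=m)
        )
        sig_lo = data.draw(
            st.lists(st.floats(0.0, 4.9), min_size=m, max_size=m)
        )
        eps = np.linspace(0.0, 0.4, m)  # breakpoints on the uniform grid
        n_grid = 4 * (m - 1) + 1
        load = curve(eps, sig_hi)
        unload = curve(eps, sig_lo, "unloading")
        area = oi.hysteresis_area(load, unload, n_grid=n_grid).area_kpa
        # shoelace on the closed polygon: loading forward, unloading back
        px = np.concatenate([eps, eps[::-1]])
        py = np.concatenate([sig_hi, sig_lo[::-1]])
        shoelace = 0.5 * abs(np.sum(px * np.roll(py, -1) - py * np.roll(px, -1)))
        assert area == pytest.approx(shoelace, rel=1e-9)

    def test_disjoint_strain_ranges_raise(self):
        load = curve([0.0, 0.1], [1.0, 2.0])
        unload = curve([0.2, 0.3], [1.0, 2.0], "unloading")
        with pytest.raises(DisjointStrainError):
            oi.hysteresis_area(load, unload)

    def test_closed_loop_limit_of_the_generator(self, cycle_schedule):
        """lam = 0 drives the full geometry-level loop area to zero."""
        states = oi.simulate_geometry(cycle_schedule, oi.ForwardModelParams(lam=0.0))
        curves, _ = oi.build_curves(GeometrySeries.from_truth(states))
        hyst = hysteresis_by_hour(curves)[0.0]
        assert isinstance(hyst, HysteresisResult)
        assert hyst.area_kpa < 1e-10
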