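"""Hydraulic circuit model: resistances, capacitances, pressures, QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spherescreen.device import (
    ChannelSegment,
    InvalidGeometryError,
    Reservoir,
    channel_resistance,
    pressure_no_overflow,
    pressure_overflow,
    qc_volume_check,
    reservoir_capacitance,
    simulate_network,
    standard_gradient_device,
)

RHO, G = 1000.0, 9.81


def exact_duct_resistance(w_m, h_m, l_m, mu, n_terms=25):
    """Eigenfunction-series solution for laminar flow in a rectangular duct
    (independent oracle; h <= w)."""
    total = 0.0
    for i in range(n_terms):
        n = 2 * i + 1
        total += math.tanh(n * math.pi * w_m / (2.0 * h_m)) / n**5
    factor = 1.0 - (192.0 * h_m) / (math.pi**5 * w_m) * total
    return 12.0 * mu * l_m / (w_m * h_m**3 * factor)


class TestChannelResistance:
    def test_linear_in_length(self):
        a = ChannelSegment(100.0, 20.0, 1000.0)
        b = ChannelSegment(100.0, 20.0, 2000.0)
        assert channel_resistance(b) == pytest.approx(2.0 * channel_resistance(a))

    @pytest.mark.parametrize("w_um,h_um", [(50.0, 50.0), (100.0, 50.0), (200.0, 20.0)])
    def test_matches_series_solution_within_1pct(self, w_um, h_um):
        seg = ChannelSegment(w_um, h_um, 1000.0)
        mu = 0.7e-3
        approx = channel_resistance(seg, mu)
        exact = exact_duct_resistance(w_um * 1e-6, h_um * 1e-6, 1e-3, mu)
        assert abs(approx - exact) / exact <= 0.01

    def test_shallow_channel_dominates(self):
        deep = ChannelSegment(100.0, 35.0, 1000.0)
        shallow = ChannelSegment(100.0, 7.0, 1000.0)
        assert channel_resistance(shallow) > channel_resistance(deep)

    def test_orientation_convention_swaps(self):
        seg = ChannelSegment(7.0, 100.0, 500.0)
        assert seg.height_um <= seg.width_um
        assert channel_resistance(seg) == pytest.approx(
            channel_resistance(ChannelSegment(100.0, 7.0, 500.0))
        )

    def test_invalid_geometry_raises(self):
        with pytest.raises(InvalidGeometryError):
            ChannelSegment(0.0, 10.0, 100.0)


class TestReservoirCapacitance:
    def test_diameter_ratio(self):
        big = Reservoir("a", 8.0, 1.0)
        small = Reservoir("b", 4.0, 1.0)
        assert reservoir_capacitance(big) == pytest.approx(4.0 * reservoir_capacitance(small))

    def test_identity_recovers_area(self):
        r = Reservoir("a", 5.5, 1.0)
        assert reservoir_capacitance(r, RHO, G) * RHO * G == pytest.approx(r.area_m2)

    def test_4mm_value(self):
        r = Reservoir("a", 4.0, 1.0)
        expected = math.pi * 0.002**2 / (RHO * G)  # = 1.281e-9 m^3/Pa
        assert reservoir_capacitance(r, RHO, G) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.281e-9, rel=1e-3)


class TestClosedFormPressures:
    R_T, C_S = 1.0e14, 5.0e-9
    A_S, A_C = math.pi * 0.004**2, math.pi * 0.002**2

    def test_overflow_initial_and_limit(self):
        h_s, h_c = 4.6e-3, 0.6e-3
        p_cs0, p_cc0 = pressure_overflow(0.0, h_s, h_c, self.R_T, self.C_S)
        assert p_cs0 == pytest.approx(RHO * G * h_s)
        assert p_cs0 - p_cc0 == pytest.approx(RHO * G * (h_s - h_c))
        p_cs_inf, p_cc_inf = pressure_overflow(1e10, h_s, h_c, self.R_T, self.C_S)
        assert p_cs_inf == pytest.approx(RHO * G * h_c, rel=1e-9)
        assert p_cs_inf - p_cc_inf == pytest.approx(0.0, abs=1e-9)

    def test_overflow_central_pressure_constant(self):
        t = np.linspace(0.0, 16 * 3600.0, 50)
        _, p_cc = pressure_overflow(t, 4.6e-3, 0.6e-3, self.R_T, self.C_S)
        assert np.allclose(p_cc, RHO * G * 0.6e-3)

    def test_no_overflow_symmetric_start_is_static(self):
        t = np.linspace(0.0, 1e5, 20)
        p_cs, p_cc = pressure_no_overflow(
            t, 2e-3, 2e-3, self.R_T, self.C_S, self.A_S, self.A_C
        )
        assert np.allclose(p_cs, RHO * G * 2e-3)
        assert np.allclose(p_cc, RHO * G * 2e-3)

    def test_no_overflow_common_limit_is_volume_weighted_mean(self):
        h_s, h_c = 4.6e-3, 0.6e-3
        p_cs, p_cc = pressure_no_overflow(
            1e9, h_s, h_c, self.R_T, self.C_S, self.A_S, self.A_C
        )
        h_eq = (2 * self.A_S * h_s + self.A_C * h_c) / (2 * self.A_S + self.A_C)
        assert p_cs == pytest.approx(RHO * G * h_eq, rel=1e-9)
        assert p_cc == pytest.approx(RHO * G * h_eq, rel=1e-9)

    def test_no_overflow_decays_faster_than_overflow(self):
        t = np.linspace(0.0, 24 * 3600.0, 97)
        h_s, h_c = 4.6e-3, 0.6e-3
        po = pressure_overflow(t, h_s, h_c, self.R_T, self.C_S)
        pn = pressure_no_overflow(t, h_s, h_c, self.R_T, self.C_S, self.A_S, self.A_C)
        dp_ovf = po[0] - po[1]
        dp_no = pn[0] - pn[1]
        assert np.all(dp_no <= dp_ovf + 1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        h_s=st.floats(1e-3, 6e-3),
        frac=st.floats(0.0, 1.0),
        t=st.floats(0.0, 2e5),
        dt=st.floats(1.0, 1e5),
    )
    def test_dp_nonnegative_and_nonincreasing(self, h_s, frac, t, dt):
        h_c = h_s * frac
        for fn in (
            lambda tt: pressure_overflow(tt, h_s, h_c, self.R_T, self.C_S),
            lambda tt: pressure_no_overflow(
                tt, h_s, h_c, self.R_T, self.C_S, self.A_S, self.A_C
            ),
        ):
            p1 = fn(t)
            p2 = fn(t + dt)
            dp1 = p1[0] - p1[1]
            dp2 = p2[0] - p2[1]
            assert dp1 >= -1e-12
            assert dp2 <= dp1 + 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pressure_overflow(-1.0, 2e-3, 1e-3, self.R_T, self.C_S)


class TestSimulateNetwork:
    def test_no_overflow_conserves_volume(self):
        net = standard_gradient_device(overflow_height_mm=None, central_fill_height_mm=0.3)
        trace, state = simulate_network(net, duration_s=8 * 3600.0, step_s=5.0)
        totals = sum(v for v in state.volumes_uL.values())
        assert abs(totals[-1] - totals[0]) / totals[0] <= 1e-3

    def test_overflow_matches_closed_form_within_1pct(self):
        net = standard_gradient_device()
        r_t = net.effective_total_resistance()
        c_s = net.side_capacitance
        trace, _ = simulate_network(net, duration_s=16 * 3600.0, step_s=5.0)
        p_cs_exact, p_cc_exact = pressure_overflow(
            trace.times_s, 4.6e-3, 0.6e-3, r_t, c_s
        )
        rel = np.abs(trace.p_cs_pa - p_cs_exact) / p_cs_exact
        assert rel.max() <= 0.01
        assert np.allclose(trace.p_cc_pa, p_cc_exact, rtol=1e-6)

    def test_no_overflow_matches_closed_form_within_1pct(self):
        net = standard_gradient_device(
            overflow_height_mm=None, central_fill_height_mm=0.6
        )
        r_t = net.effective_total_resistance()
        c_s = net.side_capacitance
        a_s = [r for r in net.reservoirs if r.role == "side_source"][0].area_m2
        a_c = [r for r in net.reservoirs if r.role == "central"][0].area_m2
        trace, _ = simulate_network(net, duration_s=16 * 3600.0, step_s=5.0)
        p_cs_exact, p_cc_exact = pressure_no_overflow(
            trace.times_s, 4.6e-3, 0.6e-3, r_t, c_s, a_s, a_c
        )
        assert (np.abs(trace.p_cs_pa - p_cs_exact) / p_cs_exact).max() <= 0.01
        assert (np.abs(trace.p_cc_pa - p_cc_exact) / p_cc_exact).max() <= 0.01

    def test_overflow_prolongs_pressure_difference(self):
        def halving_time(with_overflow):
            net = standard_gradient_device(
                overflow_height_mm=0.6 if with_overflow else None,
                central_fill_height_mm=0.6,
            )
            trace, _ = simulate_network(net, duration_s=48 * 3600.0, step_s=20.0)
            dp = trace.dp_pa
            below = np.where(dp <= dp[0] / 2.0)[0]
            return trace.times_s[below[0]] if below.size else np.inf

        assert halving_time(True) > halving_time(False)

    def test_overflow_discharge_monotone(self):
        net = standard_gradient_device()
        _, state = simulate_network(net, duration_s=4 * 3600.0, step_s=5.0)
        for label in ("W3", "W4"):
            d = state.overflow_discharged_uL[label]
            assert np.all(np.diff(d) >= -1e-12)


class TestVolumeQC:
    def test_exact_match_accepts(self):
        res = qc_volume_check({"a": 60.0, "b": 10.0}, {"a": 60.0, "b": 10.0})
        assert res.accept
        assert all(d == 0.0 for d in res.deviations.values())

    def test_12_percent_discards(self):
        res = qc_volume_check({"a": 67.2, "b": 10.0}, {"a": 60.0, "b": 10.0})
        assert not res.accept
        assert res.deviations["a"] == pytest.approx(0.12)

    def test_exact_boundary_accepts(self):
        res = qc_volume_check({"a": 66.0}, {"a": 60.0})  # exactly 10 %
        assert res.accept

    def test_zero_expected_with_nonzero_measured_discards(self):
        res = qc_volume_check({"a": 1.0, "b": 60.0}, {"a": 0.0, "b": 60.0})
        assert not res.accept
        assert "a" in res.indeterminate

    def test_permutation_invariance(self, rng):
        labels = [f"w{i}" for i in range(6)]
        expected = {lab: 50.0 + i for i, lab in enumerate(labels)}
        measured = {lab: v * (1.0 + 0.02 * i) for i, (lab, v) in enumerate(expected.items())}
        base = qc_volume_check(measured, expected)
        order = rng.permutation(labels)
        shuffled = qc_volume_check(
            {k: measured[k] for k in order}, {k: expected[k] for k in order}
        )
        assert base.accept == shuffled.accept
        assert base.deviations == shuffled.deviations

    def test_mismatched_labels_raise(self):
        with pytest.raises(ValueError):
            qc_volume_check({"a": 1.0}, {"b": 1.0})
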