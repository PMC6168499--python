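"""Transport solver, diffusivity estimator and row-profile summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from spherescreen.gradient import (
    CALCEIN,
    CompoundProperties,
    DIFFUSIVITY_RANGE,
    estimate_diffusion_coefficient,
    row_concentration_series,
    row_concentrations,
    simulate_transport,
    solve_gradient,
    stability_metrics,
)
from spherescreen.layout import generate_layout

PANEL = {"cisplatin": 300.0, "enzalutamide": 464.0, "calcein": 622.5, "docetaxel": 808.0}


class TestDiffusivityEstimator:
    def test_panel_within_working_window(self):
        lo, hi = DIFFUSIVITY_RANGE
        for mw in PANEL.values():
            assert lo <= estimate_diffusion_coefficient(mw) <= hi

    def test_strictly_decreasing_in_mw(self):
        mws = np.linspace(100.0, 2000.0, 25)
        ds = [estimate_diffusion_coefficient(m) for m in mws]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_override_passthrough(self):
        c = CompoundProperties("x", 5000.0 / 10, diffusion_coefficient=3.3e-10)
        assert c.diffusivity == 3.3e-10

    def test_out_of_range_mw_refused(self):
        with pytest.raises(ValueError, match="explicit"):
            estimate_diffusion_coefficient(5000.0)


def small_solver(initial, v=0.0, D=5e-10, duration=2000.0, bc=None, ny=None):
    ny_, nx = initial.shape
    dx = 25e-6
    if v == 0.0:
        vel = None
    else:
        ux = np.zeros((ny_, nx + 1))
        uy = np.full((ny_ + 1, nx), v)
        vel = lambda t: (ux, uy)  # noqa: E731
    return simulate_transport(
        initial, dx, D, duration, face_velocity=vel, bc=bc, save_interval_s=duration
    )


class TestTransportCore:
    def test_closed_domain_conserves_mass_and_relaxes_to_mean(self, rng):
        c0 = rng.uniform(0.0, 1.0, size=(24, 16))
        times, frames, _ = small_solver(c0, duration=6000.0)
        assert abs(frames[-1].sum() - c0.sum()) / c0.sum() <= 1e-3
        assert frames[-1].std() < 0.05 * c0.std()

    @pytest.mark.parametrize("pe", [0.1, 1.0, 10.0])
    def test_1d_steady_advection_diffusion_profile(self, pe):
        ny, nx = 50, 4
        dx = 25e-6
        length = ny * dx
        D = 5e-10
        v = pe * D / length
        init = np.zeros((ny, nx))
        bc = {"y_lo": ("dirichlet", 0.0), "y_hi": ("dirichlet", 1.0)}
        # run to steady state: a few diffusion times
        duration = 6.0 * length**2 / D
        ux = np.zeros((ny, nx + 1))
        uy = np.full((ny + 1, nx), v)
        times, frames, _ = simulate_transport(
            init, dx, D, duration, face_velocity=lambda t: (ux, uy), bc=bc,
            save_interval_s=duration,
        )
        y = (np.arange(ny) + 0.5) * dx
        exact = (np.exp(pe * y / length) - 1.0) / (np.exp(pe) - 1.0)
        profile = frames[-1][:, nx // 2]
        assert np.max(np.abs(profile - exact)) <= 0.01

    def test_maximum_principle_under_device_flow(self):
        layout = generate_layout(n_rows=4, n_cols=6)
        comp = CompoundProperties("probe", 500.0, 100.0, 0.5e-9)
        field = solve_gradient(layout, 2e-13, comp, duration_s=3600.0)
        assert field.c_uM.min() >= -1e-9
        assert field.c_uM.max() <= comp.source_concentration_uM * (1.0 + 1e-9)

    def test_equal_boundary_concentrations_give_uniform_steady_state(self):
        layout = generate_layout(n_rows=4, n_cols=6)
        comp = CompoundProperties("probe", 500.0, 100.0, 0.8e-9)
        field = solve_gradient(
            layout, 2e-13, comp, duration_s=4 * 3600.0,
            medium_concentration_uM=comp.source_concentration_uM,
        )
        final = field.c_uM[-1]
        assert np.max(np.abs(final - 100.0)) / 100.0 <= 0.005

    def test_deterministic(self):
        layout = generate_layout(n_rows=4, n_cols=6)
        comp = CompoundProperties("probe", 500.0, 100.0, 0.5e-9)
        a = solve_gradient(layout, 2e-13, comp, duration_s=1800.0)
        b = solve_gradient(layout, 2e-13, comp, duration_s=1800.0)
        assert np.array_equal(a.c_uM, b.c_uM)


@pytest.fixture(scope="module")
def short_fields():
    """3 h device-flow gradients at two diffusivities (constant flow)."""
    layout = generate_layout()
    q0 = 3.9e-13  # ~initial flow of the default device
    out = {}
    for d in (0.2e-9, 0.8e-9):
        comp = CompoundProperties("probe", 500.0, 100.0, d)
        out[d] = solve_gradient(layout, q0, comp, duration_s=3 * 3600.0)
    return layout, out


class TestDeviceGradient:
    def test_row_means_strictly_decreasing(self, short_fields):
        layout, fields = short_fields
        for field in fields.values():
            profs = row_concentrations(field, layout, t_s=3 * 3600.0)
            means = [p.mean_uM for p in profs]
            assert all(a > b for a, b in zip(means, means[1:]))

    def test_lower_diffusivity_steepens_gradient(self, short_fields):
        layout, fields = short_fields
        ratios = {}
        for d, field in fields.items():
            profs = row_concentrations(field, layout, t_s=3 * 3600.0)
            ratios[d] = profs[0].mean_uM / profs[-1].mean_uM
        assert ratios[0.2e-9] > ratios[0.8e-9]

    def test_grid_refinement_changes_row_means_below_1pct(self):
        layout = generate_layout()
        comp = CompoundProperties("probe", 500.0, 100.0, 0.6e-9)
        means = {}
        for dx in (50.0, 25.0):
            field = solve_gradient(layout, 3.9e-13, comp, 3 * 3600.0, grid_spacing_um=dx)
            profs = row_concentrations(field, layout, t_s=3 * 3600.0)
            means[dx] = np.array([p.mean_uM for p in profs])
        rel = np.abs(means[50.0] - means[25.0]) / means[25.0]
        assert rel.max() <= 0.01


class TestRowProfiles:
    def _uniform_field(self, layout, value=42.0):
        from spherescreen.gradient import ConcentrationField

        nx = int(layout.channel_length_um / 50.0)
        ny = int(layout.channel_width_um / 50.0)
        c = np.full((2, ny, nx), value)
        return ConcentrationField(np.array([0.0, 3600.0]), c, 50.0, value, 1.0)

    def test_uniform_field_equal_means_zero_spread(self, default_layout):
        field = self._uniform_field(default_layout)
        profs = row_concentrations(field, default_layout, 3600.0)
        assert len(profs) == default_layout.n_rows
        for p in profs:
            assert p.mean_uM == pytest.approx(42.0)
            assert p.spread_frac == pytest.approx(0.0, abs=1e-12)
            assert p.n_wells == default_layout.n_cols - 6

    def test_linear_field_linear_row_means(self, default_layout):
        from spherescreen.gradient import ConcentrationField

        nx = int(default_layout.channel_length_um / 50.0)
        ny = int(default_layout.channel_width_um / 50.0)
        y = (np.arange(ny) + 0.5) / ny
        c = np.broadcast_to((1.0 - y)[None, :, None], (2, ny, nx)).copy() * 100.0
        field = ConcentrationField(np.array([0.0, 3600.0]), c, 50.0, 100.0, 1.0)
        profs = row_concentrations(field, default_layout, 3600.0)
        means = np.array([p.mean_uM for p in profs])
        diffs = np.diff(means)
        assert np.allclose(diffs, diffs[0], rtol=1e-6)

    def test_exclusion_leaving_no_wells_raises(self, default_layout):
        field = self._uniform_field(default_layout)
        with pytest.raises(ValueError):
            row_concentrations(field, default_layout, 3600.0, exclude_edge_columns=15)


class TestStabilityMetrics:
    def _series(self, times_h, means):
        rows = []
        for t, row_vals in zip(times_h, means):
            for i, v in enumerate(row_vals):
                rows.append(
                    {"time_s": t * 3600.0, "row": i + 1, "mean_uM": v,
                     "spread_frac": 0.0, "n_wells": 24}
                )
        return pd.DataFrame(rows)

    def test_constant_profile_is_stable_with_zero_drift(self):
        times = np.arange(0.0, 30.0, 0.5)
        base = [80.0, 60.0, 40.0, 20.0]
        series = self._series(times, [base] * len(times))
        sm = stability_metrics(series)
        assert sm.t_stable_s == pytest.approx((times[-1] - 1.0) * 3600.0)
        assert sm.drift_24h == pytest.approx(0.0, abs=1e-12)

    def test_step_change_at_hour_six_ends_stability_at_five(self):
        times = np.arange(0.0, 12.5, 0.5)
        means = []
        for t in times:
            row = [80.0, 60.0, 40.0, 20.0]
            if t >= 6.0:
                row[2] *= 1.15  # 15 % jump in row 3
            means.append(row)
        sm = stability_metrics(self._series(times, means))
        assert sm.t_stable_s == pytest.approx(5.0 * 3600.0)

    def test_short_series_rejected(self):
        series = self._series([0.0, 0.25], [[10.0, 5.0]] * 2)
        with pytest.raises(ValueError):
            stability_metrics(series, establishment_time_s=3600.0)
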