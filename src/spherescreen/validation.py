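"""Headline validation computations for the simulated device and screen.

These functions recompute, from scratch, the quantities that
characterise the platform: the shape-factor reference point on an ideal
circle, the worst-case 24 h gradient drift over the compound-diffusivity
window, the within-row dose uniformity, the calcein gradient stability
window, and end-to-end EC50 recovery on fully synthetic screens.  They
are used both by the test suite and by the stand-alone acceptance
script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .device import simulate_network, standard_gradient_device
from .doseresp import aggregate_rows, assign_row_doses, fit_concentration_response
from .gradient import (
    CALCEIN,
    CompoundProperties,
    DIFFUSIVITY_RANGE,
    row_concentration_series,
    solve_gradient,
    stability_metrics,
)
from .imaging import SegmentationParams, exclude_edge_columns, measure_timecourse, shape_factor
from .layout import generate_layout
from .synth import _contour_polar, _fill_star, make_ground_truth, render_experiment

__all__ = [
    "circle_shape_factor",
    "rendered_circle_shape_factor",
    "default_device_flow",
    "gradient_drift_24h",
    "calcein_stability",
    "ec50_recovery_errors",
]


def circle_shape_factor(radius_um: float = 50.0) -> float:
    """Evaluate P^2/(4*pi*A) with P = 2*pi*r and A = pi*r^2 (analytic)."""
    p = 2.0 * math.pi * radius_um
    a = math.pi * radius_um**2
    return p**2 / (4.0 * math.pi * a)


def rendered_circle_shape_factor(radius_px: float = 40.0, seed: int = 0) -> float:
    """Shape factor measured by the image pipeline on a rasterised circle.

    The circle centre is jittered by a sub-pixel offset drawn from
    ``seed`` so the measurement is not tied to one pixel phase.
    """
    rng = np.random.default_rng(seed)
    side = int(4 * radius_px)
    center = side / 2.0 + rng.uniform(-0.5, 0.5)
    theta, r = _contour_polar(radius_px, 0.0, 0, 0, 720)
    mask = _fill_star(theta, r, center, (side, side))
    return shape_factor(mask)


def default_device_flow(duration_s: float):
    """Simulate the default device; returns ``(trace, r_t)`` for the solver."""
    network = standard_gradient_device()
    r_t = network.effective_total_resistance()
    trace, _ = simulate_network(network, duration_s, step_s=5.0)
    return trace, r_t


def _row_series(compound: CompoundProperties, hours: float, grid_spacing_um: float = 50.0):
    layout = generate_layout()
    trace, r_t = default_device_flow(hours * 3600.0)
    fieldc = solve_gradient(
        layout, (trace, r_t), compound, hours * 3600.0, grid_spacing_um=grid_spacing_um
    )
    return layout, fieldc, row_concentration_series(fieldc, layout)


def gradient_drift_24h(
    diffusivities=DIFFUSIVITY_RANGE,
    establishment_h: float = 1.0,
    grid_spacing_um: float = 50.0,
) -> float:
    """Worst-case percent drift of any row mean over the 24 h following
    gradient establishment, across the given diffusivity endpoints."""
    worst = 0.0
    hours = establishment_h + 24.0 + 0.5
    for d in diffusivities:
        compound = CompoundProperties("probe", 500.0, 100.0, d)
        _, _, series = _row_series(compound, hours, grid_spacing_um)
        sm = stability_metrics(series, establishment_time_s=establishment_h * 3600.0)
        worst = max(worst, sm.drift_24h)
    return 100.0 * worst


@dataclass(frozen=True)
class CalceinValidation:
    t_stable_h: float
    majority_row_spread_pct: float
    row_spreads_pct: tuple[float, ...]
    row_means_uM: tuple[float, ...]


def calcein_stability(
    hours: float = 17.0,
    establishment_h: float = 1.0,
    grid_spacing_um: float = 50.0,
) -> CalceinValidation:
    """Stability window and within-row uniformity of the calcein gradient.

    ``majority_row_spread_pct`` is the within-row (max-min)/mean spread
    achieved by at least 6 of the 8 rows (i.e. the 6th smallest row
    spread) at the establishment snapshot, edge columns excluded.
    """
    layout, fieldc, series = _row_series(CALCEIN, hours, grid_spacing_um)
    sm = stability_metrics(series, establishment_time_s=establishment_h * 3600.0)
    t_est = series.time_s[series.time_s >= establishment_h * 3600.0].min()
    est = series[series.time_s == t_est].sort_values("row")
    spreads = est.spread_frac.to_numpy() * 100.0
    majority = float(np.sort(spreads)[min(5, spreads.size - 1)])
    return CalceinValidation(
        t_stable_h=sm.t_stable_s / 3600.0,
        majority_row_spread_pct=majority,
        row_spreads_pct=tuple(float(s) for s in spreads),
        row_means_uM=tuple(float(m) for m in est.mean_uM.to_numpy()),
    )


def ec50_recovery_errors(
    n_seeds: int = 20,
    base_seed: int = 1,
    true_ec50_uM: float = 100.0,
    hill: float = 3.0,
) -> list[float]:
    """Relative EC50 recovery errors over independent synthetic screens.

    Each screen renders the full 8 x 30 array (n = 24 per row after edge
    exclusion) in disaggregation mode with default noise, measures it and
    fits the viable-fraction curve.
    """
    errors = []
    for k in range(n_seeds):
        seed = int(base_seed) + k
        gt = make_ground_truth(seed=seed, ec50_uM=true_ec50_uM, hill_slope=hill)
        images = render_experiment(ground_truth=gt, days=(4, 5, 8), drug_day=5, seed=seed)
        table = measure_timecourse(images, params=SegmentationParams(invert=True))
        table = exclude_edge_columns(table, gt.layout)
        table = assign_row_doses(table, gt.row_doses_uM)
        pts = aggregate_rows(table[table.day == 8], "viable_fraction")
        fit = fit_concentration_response(pts)
        if not fit.converged:
            errors.append(float("inf"))
        else:
            errors.append(abs(fit.ec50_uM - true_ec50_uM) / true_ec50_uM)
    return errors
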