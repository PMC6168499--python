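"""Concentration-response aggregation, 4PL fitting and S_F/V_F correlation."""

import numpy as np
import pandas as pd
import pytest

from spherescreen.doseresp import (
    ConcentrationResponsePoint,
    SizeGroup,
    aggregate_rows,
    assign_row_doses,
    correlate_sf_vf,
    fit_concentration_response,
    group_by_size,
)
from spherescreen.imaging import exclude_edge_columns
from spherescreen.synth import make_ground_truth, render_experiment
from spherescreen.imaging import SegmentationParams, measure_timecourse

PRINTED_ROW_DOSES = np.linspace(206.5, 42.2, 8)


def toy_table(n_rows=8, n_cols=4, value=1.0):
    recs = []
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            recs.append(
                {"well_row": r, "well_col": c, "day": 8,
                 "viable_fraction": value, "shape_factor": 1.0,
                 "baseline_area_um2": np.pi * 30.0**2}
            )
    return pd.DataFrame(recs)


class TestAssignRowDoses:
    def test_printed_profile_annotates_exactly(self):
        table = toy_table()
        out = assign_row_doses(table, PRINTED_ROW_DOSES)
        for r in range(1, 9):
            got = out[out.well_row == r]["concentration_uM"].unique()
            assert got == pytest.approx([PRINTED_ROW_DOSES[r - 1]])

    def test_uniform_profile(self):
        out = assign_row_doses(toy_table(), [50.0] * 8)
        assert (out["concentration_uM"] == 50.0).all()

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_row_doses(toy_table(n_rows=5), PRINTED_ROW_DOSES)


class TestSizeGroups:
    def test_bounds_are_inclusive(self):
        table = toy_table(n_rows=2, n_cols=2)
        diams = {(1, 1): 75.0, (1, 2): 76.0, (2, 1): 40.0, (2, 2): 150.0}
        table["baseline_area_um2"] = [
            np.pi * (diams[(r, c)] / 2.0) ** 2 for r, c in zip(table.well_row, table.well_col)
        ]
        groups = group_by_size(table)
        g1 = set(zip(groups["Group 1"].well_row, groups["Group 1"].well_col))
        g2 = set(zip(groups["Group 2"].well_row, groups["Group 2"].well_col))
        assert (1, 1) in g1 and (2, 1) in g1
        assert (1, 2) in g2 and (2, 2) in g2

    def test_cross_patient_filter_excludes_out_of_band(self):
        table = toy_table(n_rows=1, n_cols=4)
        for (r, c), d in zip(zip(table.well_row, table.well_col), [20.0, 30.0, 90.0, 100.0]):
            table.loc[(table.well_row == r) & (table.well_col == c), "baseline_area_um2"] = (
                np.pi * (d / 2.0) ** 2
            )
        groups = group_by_size(table, [SizeGroup("band", 25.0, 95.0)])
        cols = sorted(groups["band"].well_col.unique())
        assert cols == [2, 3]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            group_by_size(toy_table(), [SizeGroup("a", 0, 80), SizeGroup("b", 75, 150)])


class TestAggregateRows:
    def test_identical_values_give_zero_sem(self):
        table = assign_row_doses(toy_table(value=0.7), PRINTED_ROW_DOSES)
        pts = aggregate_rows(table, "viable_fraction")
        assert len(pts) == 8
        for p in pts:
            assert p.mean == pytest.approx(0.7)
            assert p.sem == pytest.approx(0.0)
            assert p.n == 4

    def test_single_spheroid_row_has_undefined_sem(self):
        table = assign_row_doses(toy_table(n_cols=1), PRINTED_ROW_DOSES)
        pts = aggregate_rows(table, "viable_fraction")
        assert all(p.sem is None and p.n == 1 for p in pts)

    def test_ordering_invariance(self, rng):
        table = assign_row_doses(toy_table(), PRINTED_ROW_DOSES)
        table["viable_fraction"] = rng.uniform(0, 1, len(table))
        shuffled = table.sample(frac=1.0, random_state=4)
        a = aggregate_rows(table, "viable_fraction")
        b = aggregate_rows(shuffled, "viable_fraction")
        assert [(p.row, p.n) for p in a] == [(p.row, p.n) for p in b]
        assert [p.mean for p in a] == pytest.approx([p.mean for p in b], rel=1e-12)


def pts_from_4pl(conc, bottom, top, ec50, hill, sem=1e-4):
    y = bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)
    return [
        ConcentrationResponsePoint(i + 1, c, "viable_fraction", v, sem, 24)
        for i, (c, v) in enumerate(zip(conc, y))
    ]


class TestFourParameterFit:
    def test_exact_points_recover_ec50(self):
        pts = pts_from_4pl(PRINTED_ROW_DOSES, 0.05, 1.0, 120.0, 3.0)
        fit = fit_concentration_response(pts)
        assert fit.converged
        assert fit.ec50_uM == pytest.approx(120.0, rel=1e-3)
        assert fit.hill_slope == pytest.approx(3.0, rel=1e-2)

    def test_flat_response_guard(self):
        pts = [
            ConcentrationResponsePoint(i + 1, c, "viable_fraction", 0.8, 0.05, 24)
            for i, c in enumerate(PRINTED_ROW_DOSES)
        ]
        fit = fit_concentration_response(pts)
        assert not fit.converged
        assert fit.ec50_uM is None

    def test_point_order_invariance(self):
        pts = pts_from_4pl(PRINTED_ROW_DOSES, 0.0, 1.0, 90.0, 2.0)
        a = fit_concentration_response(pts)
        b = fit_concentration_response(list(reversed(pts)))
        assert a.ec50_uM == pytest.approx(b.ec50_uM, rel=1e-6)

    def test_concentration_rescaling_rescales_ec50(self):
        pts = pts_from_4pl(PRINTED_ROW_DOSES, 0.0, 1.0, 90.0, 2.0)
        scaled = [
            ConcentrationResponsePoint(p.row, 10.0 * p.concentration_uM, p.readout,
                                       p.mean, p.sem, p.n)
            for p in pts
        ]
        a = fit_concentration_response(pts)
        b = fit_concentration_response(scaled)
        assert b.ec50_uM == pytest.approx(10.0 * a.ec50_uM, rel=1e-3)

    def test_too_few_points_rejected(self):
        pts = pts_from_4pl(PRINTED_ROW_DOSES[:3], 0.0, 1.0, 90.0, 2.0)
        with pytest.raises(ValueError):
            fit_concentration_response(pts)


class TestCorrelation:
    def test_perfect_lines(self):
        x = np.linspace(1.0, 2.0, 10)
        assert correlate_sf_vf(x, -0.5 * x + 3).r == pytest.approx(-1.0)
        assert correlate_sf_vf(x, 2.0 * x).r == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        res = correlate_sf_vf(np.ones(10), np.linspace(0, 1, 10))
        assert not res.defined
        assert np.isnan(res.r)


class TestEndToEnd:
    def test_ec50_recovery_median_within_15pct(self, recovery_errors):
        assert np.median(recovery_errors) <= 0.15

    def test_disaggregation_mode_strong_negative_correlation(self):
        gt = make_ground_truth(seed=1, ec50_uM=100.0, hill_slope=3.0)
        images = render_experiment(ground_truth=gt, days=(4, 5, 8), seed=1)
        table = measure_timecourse(images, params=SegmentationParams(invert=True))
        table = exclude_edge_columns(table, gt.layout)
        res = correlate_sf_vf(table[table.day == 8])
        assert res.defined
        assert res.r <= -0.8

    def test_shrinkage_mode_dissociates_readouts(self):
        gt = make_ground_truth(seed=1, ec50_uM=100.0, hill_slope=3.0,
                               effect_mode="shrinkage")
        images = render_experiment(ground_truth=gt, days=(4, 5, 8), seed=1)
        table = measure_timecourse(images, params=SegmentationParams(invert=True))
        table = exclude_edge_columns(table, gt.layout)
        table = assign_row_doses(table, gt.row_doses_uM)
        final = table[table.day == 8]
        res = correlate_sf_vf(final)
        assert abs(res.r) < 0.5
        # V_F responds to dose, S_F stays flat
        vf_pts = aggregate_rows(final, "viable_fraction")
        sf_pts = aggregate_rows(final, "shape_factor")
        vf_range = max(p.mean for p in vf_pts) - min(p.mean for p in vf_pts)
        sf_range = max(p.mean for p in sf_pts) - min(p.mean for p in sf_pts)
        assert vf_range > 0.4
        assert sf_range < 0.1
        assert fit_concentration_response(vf_pts).converged
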