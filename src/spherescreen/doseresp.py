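"""Concentration-response analysis of per-well readouts.

Each row of the array saw one simulated dose, so averaging a readout over
the retained spheroids of a row yields one point of an 8-point
concentration-response curve per device.  Curves are summarised by a
four-parameter logistic (4PL) fit on log concentration

    y(c) = bottom + (top - bottom) / (1 + (c / EC50)^hill)

whose EC50 is the concentration producing half of the maximal response.
A flat-response guard refuses to report an EC50 when the dynamic range of
the row means does not clear the noise (twice the pooled SEM).

The module also computes the Pearson correlation between the two
readouts, shape factor and viable fraction, across spheroids: strongly
negative when death proceeds by disaggregation, near zero when spheroids
shrink but stay intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gradient import RowConcentrationProfile

__all__ = [
    "SizeGroup",
    "ConcentrationResponsePoint",
    "DoseResponseFit",
    "CorrelationResult",
    "assign_row_doses",
    "group_by_size",
    "aggregate_rows",
    "fit_concentration_response",
    "correlate_sf_vf",
]


@dataclass(frozen=True)
class SizeGroup:
    """Baseline-diameter stratum; both bounds inclusive, in um."""

    label: str
    lower_um: float
    upper_um: float

    def __post_init__(self) -> None:
        if self.lower_um > self.upper_um:
            raise ValueError(f"size group {self.label!r} has inverted bounds")

    def contains(self, diameter_um: float) -> bool:
        return self.lower_um <= diameter_um <= self.upper_um


#: the two strata used for size-dependent response analysis
DEFAULT_SIZE_GROUPS = (SizeGroup("Group 1", 0.0, 75.0), SizeGroup("Group 2", 76.0, 150.0))


@dataclass(frozen=True)
class ConcentrationResponsePoint:
    row: int
    concentration_uM: float
    readout: str  # shape_factor | viable_fraction
    mean: float
    sem: float | None  # undefined for n == 1
    n: int


@dataclass(frozen=True)
class DoseResponseFit:
    ec50_uM: float | None
    hill_slope: float | None
    top: float | None
    bottom: float | None
    converged: bool
    n_points: int
    residual_rms: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    defined: bool = True


def assign_row_doses(table: pd.DataFrame, profile) -> pd.DataFrame:
    """Annotate each measurement with its row's simulated concentration.

    ``profile`` is a list of :class:`RowConcentrationProfile` (one per
    layout row) or a plain sequence of per-row concentrations in uM,
    ordered from row 1.
    """
    if len(profile) == 0:
        raise ValueError("empty dose profile")
    if isinstance(profile[0], RowConcentrationProfile):
        doses = {p.row: p.mean_uM for p in profile}
    else:
        doses = {i + 1: float(c) for i, c in enumerate(profile)}
    rows_present = set(table["well_row"].unique())
    if not rows_present <= set(doses):
        missing = sorted(rows_present - set(doses))
        raise ValueError(f"no dose for rows {missing}")
    if table["well_row"].nunique() != len(doses):
        raise ValueError(
            f"profile has {len(doses)} rows but table covers "
            f"{table['well_row'].nunique()}"
        )
    out = table.copy()
    out["concentration_uM"] = out["well_row"].map(doses)
    return out


def group_by_size(
    table: pd.DataFrame, groups=DEFAULT_SIZE_GROUPS
) -> dict[str, pd.DataFrame]:
    """Partition spheroids by baseline equivalent diameter.

    Groups must not overlap; a spheroid outside every group is dropped.
    Membership is decided once per well from the baseline diameter (the
    pre-drug brightfield frame), then applied to all its time points.
    """
    groups = list(groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if a.lower_um <= b.upper_um and b.lower_um <= a.upper_um:
                raise ValueError(f"size groups {a.label!r} and {b.label!r} overlap")
    base = (
        table.assign(baseline_diam=2.0 * np.sqrt(table["baseline_area_um2"] / math.pi))
        .groupby(["well_row", "well_col"])["baseline_diam"]
        .first()
    )
    out: dict[str, pd.DataFrame] = {}
    for g in groups:
        wells = base[base.apply(g.contains)].index
        sel = table.set_index(["well_row", "well_col"]).loc[
            table.set_index(["well_row", "well_col"]).index.isin(wells)
        ]
        out[g.label] = sel.reset_index()
    return out


def aggregate_rows(table: pd.DataFrame, readout: str) -> list[ConcentrationResponsePoint]:
    """One concentration-response point per row: mean, SEM and n.

    SEM is the across-spheroid standard error sd/sqrt(n) within the
    device; rows left empty by filtering are omitted (with a warning via
    the returned list simply lacking them).
    """
    if readout not in table.columns:
        raise KeyError(f"readout column {readout!r} missing")
    if "concentration_uM" not in table.columns:
        raise ValueError("assign_row_doses must run before aggregation")
    pts = []
    for (row, conc), sub in table.groupby(["well_row", "concentration_uM"]):
        vals = sub[readout].dropna().to_numpy()
        if vals.size == 0:
            continue
        sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else None
        pts.append(
            ConcentrationResponsePoint(
                row=int(row),
                concentration_uM=float(conc),
                readout=readout,
                mean=float(vals.mean()),
                sem=sem,
                n=int(vals.size),
            )
        )
    pts.sort(key=lambda p: p.row)
    return pts


def _logistic4(c, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(c) - log_ec50)))


def fit_concentration_response(points) -> DoseResponseFit:
    """4PL fit of row means against log concentration.

    Initialisation from data quantiles (bottom/top from the extreme
    means, EC50 at the mid-log concentration, Hill slope sign from the
    trend); EC50 is constrained to [min dose / 10, max dose * 10].  The
    fit reports ``converged=False`` (and no EC50) for flat responses —
    dynamic range below twice the pooled SEM — or optimiser failure.
    """
    pts = sorted(points, key=lambda p: p.concentration_uM)
    if len(pts) < 4:
        raise ValueError("a 4-parameter fit needs at least 4 points")
    conc = np.array([p.concentration_uM for p in pts], dtype=float)
    y = np.array([p.mean for p in pts], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    sems = [p.sem for p in pts if p.sem is not None]
    pooled_sem = float(np.mean(sems)) if sems else 0.0
    dynamic_range = float(y.max() - y.min())
    if dynamic_range < 2.0 * pooled_sem or dynamic_range == 0.0:
        return DoseResponseFit(None, None, None, None, False, len(pts))

    slope_sign = 1.0 if stats.linregress(np.log(conc), y).slope < 0 else -1.0
    log_mid = float(np.log(conc).mean())
    p0 = [float(y.min()), float(y.max()), log_mid, slope_sign]
    lo = [y.min() - dynamic_range, y.min() - dynamic_range,
          math.log(conc.min() / 10.0), -20.0]
    hi = [y.max() + dynamic_range, y.max() + dynamic_range,
          math.log(conc.max() * 10.0), 20.0]
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, conc, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError:
        return DoseResponseFit(None, None, None, None, False, len(pts))
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    resid = y - _logistic4(conc, *popt)
    return DoseResponseFit(
        ec50_uM=float(np.exp(log_ec50)),
        hill_slope=hill,
        top=top,
        bottom=bottom,
        converged=True,
        n_points=len(pts),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def correlate_sf_vf(table_or_sf, vf=None) -> CorrelationResult:
    """Pearson correlation between shape factor and viable fraction.

    Accepts either a measurement table (uses the end-point rows where both
    readouts are present) or two aligned arrays.  With fewer than 3 pairs
    or zero variance in either variable the correlation is undefined and
    flagged rather than raised.
    """
    if vf is None:
        tab = table_or_sf
        sub = tab.dropna(subset=["shape_factor", "viable_fraction"])
        sf = sub["shape_factor"].to_numpy(dtype=float)
        vf_arr = sub["viable_fraction"].to_numpy(dtype=float)
    else:
        sf = np.asarray(table_or_sf, dtype=float)
        vf_arr = np.asarray(vf, dtype=float)
        if sf.shape != vf_arr.shape:
            raise ValueError("paired arrays must have the same length")
    n = sf.size
    if n < 3 or np.std(sf) == 0 or np.std(vf_arr) == 0:
        return CorrelationResult(r=float("nan"), n=int(n), defined=False)
    r, _ = stats.pearsonr(sf, vf_arr)
    return CorrelationResult(r=float(r), n=int(n))
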