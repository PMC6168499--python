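"""Compound concentration gradient over the well array.

The side channels hold the compound at its source concentration c0 on one
side of the culture channel and plain medium on the other, refreshed by the
slow hydrostatic flow from the reservoir network.  Depth-averaging the thin
culture channel gives a 2D advection-diffusion problem: fluid enters
uniformly along both long walls (through the connecting-channel arrays),
converges toward the mid-line and leaves axially toward the two central
reservoirs.  The transverse strain of this flow field balances molecular
diffusion and pins a monotone concentration profile across the well rows.

The solver is a conservative finite-volume scheme on a regular grid with a
hybrid advection discretisation (central differencing where the cell Peclet
number is below 2, upwind beyond) and explicit time stepping under a CFL
safety factor.  Face velocities are evaluated analytically from a linear
strain field, so the discrete velocity is exactly divergence free and the
scheme conserves mass to round-off on closed domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import PressureTrace
from .layout import DeviceLayout

__all__ = [
    "CompoundProperties",
    "ConcentrationField",
    "RowConcentrationProfile",
    "StabilityMetrics",
    "estimate_diffusion_coefficient",
    "simulate_transport",
    "solve_gradient",
    "row_concentrations",
    "row_concentration_series",
    "stability_metrics",
]

# D(MW) power-law prefactor, anchored at cisplatin (MW 300, D ~ 0.75e-9
# m^2/s); the screened drug panel then spans ~0.2-0.8e-9 m^2/s, consistent
# with free-solution diffusivities of small-molecule drugs at 37 C.
_DIFFUSION_PREFACTOR = 0.75e-9 * 300.0 ** (1.0 / 3.0)  # m^2/s * (g/mol)^(1/3)
_MW_RANGE = (100.0, 2000.0)
DIFFUSIVITY_RANGE = (0.2e-9, 0.8e-9)  # m^2/s, working window for the drug panel


def estimate_diffusion_coefficient(molecular_weight: float) -> float:
    """Estimate a compound diffusivity (m^2/s) from its molecular weight.

    Stokes-Einstein scaling for a globular solute gives D proportional to
    the inverse hydrodynamic radius, i.e. MW^(-1/3).  The prefactor places
    the screened drug panel (cisplatin 300 to docetaxel 808 g/mol) inside
    the 0.2-0.8e-9 m^2/s window typical of small molecules in aqueous
    medium at 37 C.  Outside 100-2000 g/mol the scaling is not trusted and
    an explicit override should be supplied instead.
    """
    if not (_MW_RANGE[0] <= molecular_weight <= _MW_RANGE[1]):
        raise ValueError(
            f"molecular weight {molecular_weight} g/mol outside the supported "
            f"range {_MW_RANGE}; supply an explicit diffusion coefficient"
        )
    return _DIFFUSION_PREFACTOR * molecular_weight ** (-1.0 / 3.0)


@dataclass(frozen=True)
class CompoundProperties:
    """Compound identity, source concentration and (optional) diffusivity."""

    name: str
    molecular_weight: float  # g/mol
    source_concentration_uM: float = 100.0
    diffusion_coefficient: float | None = None  # m^2/s, overrides the estimate

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.diffusion_coefficient is not None and self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient, if given, must be positive")
        if self.source_concentration_uM < 0:
            raise ValueError("source concentration cannot be negative")

    @property
    def diffusivity(self) -> float:
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        return estimate_diffusion_coefficient(self.molecular_weight)


CALCEIN = CompoundProperties("calcein", 622.5, source_concentration_uM=100.0)


@dataclass
class ConcentrationField:
    """Saved frames of the simulated concentration field.

    ``c_uM`` has shape (n_times, ny, nx); x runs along the channel axis,
    y across it with the drug side at y = 0.
    """

    times_s: np.ndarray
    c_uM: np.ndarray
    dx_um: float
    source_concentration_uM: float
    effective_dt_s: float

    @property
    def x_um(self) -> np.ndarray:
        return (np.arange(self.c_uM.shape[2]) + 0.5) * self.dx_um

    @property
    def y_um(self) -> np.ndarray:
        return (np.arange(self.c_uM.shape[1]) + 0.5) * self.dx_um

    def frame_at(self, t_s: float) -> np.ndarray:
        """Field at time ``t_s``, linearly interpolated between saved frames."""
        t0, t1 = self.times_s[0], self.times_s[-1]
        if not (t0 <= t_s <= t1):
            raise ValueError(f"time {t_s} s outside saved range [{t0}, {t1}] s")
        k = int(np.searchsorted(self.times_s, t_s))
        if k == 0 or self.times_s[k] == t_s:
            return self.c_uM[k]
        w = (t_s - self.times_s[k - 1]) / (self.times_s[k] - self.times_s[k - 1])
        return (1.0 - w) * self.c_uM[k - 1] + w * self.c_uM[k]


def _bc_entry(bc, default=("neumann", 0.0)):
    """Normalise a boundary entry to ``(kind, value, mask)``.

    Entries are ``("dirichlet", value)``, ``("neumann", 0)`` or
    ``("dirichlet", value, mask)`` where ``mask`` selects which boundary
    cells are held at the value (the rest behave as zero-flux wall /
    outflow, depending on the face velocity there).
    """
    entry = bc if bc is not None else default
    kind, value = entry[0], entry[1]
    mask = entry[2] if len(entry) > 2 else None
    if kind not in ("dirichlet", "neumann"):
        raise ValueError(f"unknown boundary condition kind {kind!r}")
    return kind, value, mask


def simulate_transport(
    initial: np.ndarray,
    dx_m: float,
    diffusivity: float,
    duration_s: float,
    face_velocity=None,
    bc: dict | None = None,
    cfl: float = 0.4,
    save_interval_s: float = 900.0,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Integrate d c/dt + div(v c) = D lap(c) on a regular 2D grid.

    Parameters
    ----------
    initial : (ny, nx) starting concentration.
    face_velocity : ``None`` (pure diffusion) or a callable
        ``t -> (ux, uy)`` with ``ux`` on x-faces (ny, nx+1) and ``uy`` on
        y-faces (ny+1, nx), in m/s.
    bc : mapping with keys ``y_lo, y_hi, x_lo, x_hi``; each entry is
        ``("dirichlet", value)`` or ``("neumann", 0)``.  A Neumann face is
        no-flux when the face velocity is zero and an outflow otherwise.

    Returns ``(times, frames, dt)`` with frames of shape (nt, ny, nx).
    The time step is chosen once from the diffusive limit and the maximum
    initial face speed (velocities only decay in this device), then held
    fixed so runs are deterministic.
    """
    c = np.asarray(initial, dtype=float).copy()
    if c.ndim != 2:
        raise ValueError("initial field must be 2D")
    ny, nx = c.shape
    bc = bc or {}
    bcs = {k: _bc_entry(bc.get(k)) for k in ("y_lo", "y_hi", "x_lo", "x_hi")}

    if face_velocity is None:
        ux0 = np.zeros((ny, nx + 1))
        uy0 = np.zeros((ny + 1, nx))
        velocity = lambda t: (ux0, uy0)  # noqa: E731
    else:
        velocity = face_velocity
    ux, uy = velocity(t0_s)
    if ux.shape != (ny, nx + 1) or uy.shape != (ny + 1, nx):
        raise ValueError("face velocity arrays have the wrong shape")
    vmax = max(np.abs(ux).max(), np.abs(uy).max())

    dt_diff = dx_m**2 / (4.0 * diffusivity) if diffusivity > 0 else math.inf
    dt_adv = dx_m / vmax if vmax > 0 else math.inf
    dt = cfl * min(dt_diff, dt_adv)
    if not math.isfinite(dt):
        raise ValueError("both diffusivity and velocity are zero; nothing to integrate")
    n_steps = max(1, int(math.ceil(duration_s / dt)))
    dt = duration_s / n_steps

    save_every = max(1, int(round(save_interval_s / dt)))
    frames = [c.copy()]
    times = [t0_s]

    d_over_dx = diffusivity / dx_m

    def face_concentration(cm, cp, u):
        # hybrid scheme: central average below cell Peclet 2, upwind above
        if diffusivity > 0:
            pe = u * dx_m / diffusivity
            central = np.abs(pe) < 2.0
        else:
            central = np.zeros(u.shape, dtype=bool)
        up = np.where(u >= 0, cm, cp)
        return np.where(central, 0.5 * (cm + cp), up)

    def ghosts(edge_c, kind, value, mask):
        # a ghost equal to the edge cell gives zero diffusive flux and an
        # advective flux of u*c_edge: a no-flux wall where u = 0, an
        # outflow where u points outward
        if kind != "dirichlet":
            return edge_c.copy()
        g = 2.0 * np.asarray(value, dtype=float) - edge_c
        if mask is None:
            return g
        return np.where(mask, g, edge_c)

    for step in range(n_steps):
        t = t0_s + step * dt
        ux, uy = velocity(t)

        gxlo = ghosts(c[:, 0], *bcs["x_lo"])
        gxhi = ghosts(c[:, -1], *bcs["x_hi"])
        gylo = ghosts(c[0, :], *bcs["y_lo"])
        gyhi = ghosts(c[-1, :], *bcs["y_hi"])

        cx = np.concatenate([gxlo[:, None], c, gxhi[:, None]], axis=1)
        cy = np.concatenate([gylo[None, :], c, gyhi[None, :]], axis=0)

        # total face fluxes (per unit face length, depth-averaged)
        fx = ux * face_concentration(cx[:, :-1], cx[:, 1:], ux) - d_over_dx * (
            cx[:, 1:] - cx[:, :-1]
        )
        fy = uy * face_concentration(cy[:-1, :], cy[1:, :], uy) - d_over_dx * (
            cy[1:, :] - cy[:-1, :]
        )

        c = c - (dt / dx_m) * (fx[:, 1:] - fx[:, :-1] + fy[1:, :] - fy[:-1, :])

        if (step + 1) % save_every == 0 or step == n_steps - 1:
            frames.append(c.copy())
            times.append(t0_s + (step + 1) * dt)

    return np.asarray(times), np.asarray(frames), dt


def _inflow_span_faces(layout: DeviceLayout, nx: int, dx_m: float) -> tuple[int, int]:
    """Face indices bracketing the connecting-channel span (the array region)."""
    dx_um = dx_m * 1e6
    i0 = int(round(layout.end_margin_um / dx_um))
    i1 = int(round((layout.channel_length_um - layout.end_margin_um) / dx_um))
    return max(0, i0), min(nx, i1)


def _device_face_velocity(layout: DeviceLayout, nx: int, ny: int, dx_m: float, q_of_t):
    """Linear-strain field scaled to the instantaneous central-channel flow.

    Fluid enters through both long walls along the connecting-channel span
    (the array region) with uniform transverse speed
    v_in(t) = Q(t) / (2 * La * h), converges linearly toward the mid-line
    and accelerates axially toward the two channel ends:

        v_y(y) = v_in * (1 - 2 y / Ly)  inside the span, 0 in the margins
        v_x(x) = (2 v_in / Ly) * (clip(x, span) - Lx/2)

    The span is snapped to grid faces, so the discrete field is exactly
    divergence free cell by cell.
    """
    lx = nx * dx_m
    ly = ny * dx_m
    depth_m = layout.channel_depth_um * 1e-6
    i0, i1 = _inflow_span_faces(layout, nx, dx_m)
    span_len = (i1 - i0) * dx_m
    x_faces = np.arange(nx + 1) * dx_m
    y_faces = np.arange(ny + 1) * dx_m
    ux_unit = np.broadcast_to(
        (2.0 / ly) * (np.clip(x_faces, i0 * dx_m, i1 * dx_m) - lx / 2.0)[None, :],
        (ny, nx + 1),
    )
    col_in_span = (np.arange(nx) >= i0) & (np.arange(nx) < i1)
    uy_unit = (1.0 - 2.0 * y_faces / ly)[:, None] * col_in_span[None, :]
    denom = 2.0 * span_len * depth_m

    def velocity(t: float):
        v_in = q_of_t(t) / denom
        return v_in * ux_unit, v_in * uy_unit

    return velocity


def central_flow(trace: PressureTrace, r_t: float):
    """Interpolant t -> Q_central(t) (m^3/s) from a simulated pressure trace."""
    q = trace.q_central_m3s(r_t)
    times = trace.times_s

    def q_of_t(t: float) -> float:
        return float(np.interp(t, times, q))

    return q_of_t


def solve_gradient(
    layout: DeviceLayout,
    flow,
    compound: CompoundProperties,
    duration_s: float,
    grid_spacing_um: float = 50.0,
    save_interval_s: float = 900.0,
    cfl: float = 0.4,
    medium_concentration_uM: float = 0.0,
) -> ConcentrationField:
    """Simulate the compound field over the culture channel.

    ``flow`` is the central-channel volumetric flow: a constant (m^3/s), a
    callable ``t -> Q``, or a ``(PressureTrace, R_T)`` pair from the device
    model.  Along the array span the drug-side wall is held at the source
    concentration c0 (the side channel is continuously refreshed) and the
    medium-side wall at zero; the end margins are plain walls and the two
    channel ends are outflow boundaries.
    """
    if grid_spacing_um <= 0:
        raise ValueError("grid spacing must be positive")
    if grid_spacing_um > layout.well_size_um / 3.0 + 1e-9:
        raise ValueError(
            f"grid spacing {grid_spacing_um} um does not resolve the well "
            f"pitch (need >= 3 nodes per {layout.well_size_um} um well)"
        )
    dx_m = grid_spacing_um * 1e-6
    nx = int(round(layout.channel_length_um / grid_spacing_um))
    ny = int(round(layout.channel_width_um / grid_spacing_um))

    if isinstance(flow, tuple) and isinstance(flow[0], PressureTrace):
        q_of_t = central_flow(flow[0], flow[1])
    elif callable(flow):
        q_of_t = flow
    else:
        q_const = float(flow)
        q_of_t = lambda t: q_const  # noqa: E731

    velocity = _device_face_velocity(layout, nx, ny, dx_m, q_of_t)
    c0 = compound.source_concentration_uM
    i0, i1 = _inflow_span_faces(layout, nx, dx_m)
    span_mask = (np.arange(nx) >= i0) & (np.arange(nx) < i1)
    bc = {
        "y_lo": ("dirichlet", c0, span_mask),
        "y_hi": ("dirichlet", medium_concentration_uM, span_mask),
        "x_lo": ("neumann", 0.0),
        "x_hi": ("neumann", 0.0),
    }
    times, frames, dt = simulate_transport(
        np.full((ny, nx), medium_concentration_uM),
        dx_m,
        compound.diffusivity,
        duration_s,
        face_velocity=velocity,
        bc=bc,
        cfl=cfl,
        save_interval_s=save_interval_s,
    )
    return ConcentrationField(
        times_s=times,
        c_uM=frames,
        dx_um=grid_spacing_um,
        source_concentration_uM=c0,
        effective_dt_s=dt,
    )


def save_field_tiff(field: ConcentrationField, path) -> None:
    """Write the saved frames as a multi-page float32 TIFF (one page per
    saved time); pair with :func:`row_concentration_series` CSV for the
    per-row summary."""
    import tifffile

    tifffile.imwrite(path, field.c_uM.astype(np.float32))


@dataclass(frozen=True)
class RowConcentrationProfile:
    """Per-row dose summary over the retained (non-edge) wells."""

    row: int  # 1 = drug side
    mean_uM: float
    spread_frac: float  # (max - min) / mean over retained wells
    n_wells: int


def _well_means(frame: np.ndarray, layout: DeviceLayout, dx_um: float) -> np.ndarray:
    """(n_rows, n_cols) mean concentration over each well footprint."""
    ny, nx = frame.shape
    x = (np.arange(nx) + 0.5) * dx_um
    y = (np.arange(ny) + 0.5) * dx_um
    centers = layout.well_centers_um()
    half = layout.well_size_um / 2.0
    out = np.empty((layout.n_rows, layout.n_cols))
    for i in range(layout.n_rows):
        for j in range(layout.n_cols):
            cx, cy = centers[i, j]
            xm = (x >= cx - half) & (x <= cx + half)
            ym = (y >= cy - half) & (y <= cy + half)
            out[i, j] = frame[np.ix_(ym, xm)].mean()
    return out


def row_concentrations(
    field: ConcentrationField,
    layout: DeviceLayout,
    t_s: float,
    exclude_edge_columns: int = 3,
) -> list[RowConcentrationProfile]:
    """Per-row mean dose and within-row spread at time ``t_s``.

    Wells in the first and last ``exclude_edge_columns`` columns are left
    out, mirroring the analysis exclusion used for spheroid readouts.
    """
    k = int(exclude_edge_columns)
    if k < 0:
        raise ValueError("exclude_edge_columns cannot be negative")
    if layout.n_cols - 2 * k < 1:
        raise ValueError("edge-column exclusion leaves no wells per row")
    frame = field.frame_at(t_s)
    wm = _well_means(frame, layout, field.dx_um)
    kept = wm[:, k : layout.n_cols - k] if k else wm
    profiles = []
    for i in range(layout.n_rows):
        vals = kept[i]
        mean = float(vals.mean())
        spread = float((vals.max() - vals.min()) / mean) if mean > 0 else math.inf
        profiles.append(
            RowConcentrationProfile(row=i + 1, mean_uM=mean, spread_frac=spread, n_wells=vals.size)
        )
    return profiles


def row_concentration_series(
    field: ConcentrationField,
    layout: DeviceLayout,
    exclude_edge_columns: int = 3,
) -> pd.DataFrame:
    """Tidy per-row profile at every saved frame.

    Columns: time_s, row, mean_uM, spread_frac, n_wells.
    """
    rows = []
    for t in field.times_s:
        for p in row_concentrations(field, layout, float(t), exclude_edge_columns):
            rows.append(
                {
                    "time_s": float(t),
                    "row": p.row,
                    "mean_uM": p.mean_uM,
                    "spread_frac": p.spread_frac,
                    "n_wells": p.n_wells,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StabilityMetrics:
    """How long the established gradient holds and how much it drifts."""

    t_stable_s: float
    drift_24h: float  # max over rows of |c(t_est+24h) - c(t_est)| / c(t_est)
    per_row_drift: tuple[float, ...]
    establishment_time_s: float


def stability_metrics(
    profile_series: pd.DataFrame,
    establishment_time_s: float = 3600.0,
    drift_tolerance: float = 0.10,
) -> StabilityMetrics:
    """Gradient stability from a row-profile time series.

    The gradient counts as stable while (a) the row means remain strictly
    ordered, highest dose in row 1, and (b) every row mean stays within
    ``drift_tolerance`` (fractional) of its value at the establishment
    snapshot.  ``t_stable`` is the length of the longest such interval
    starting at establishment; ``drift_24h`` is the largest per-row
    fractional change 24 h after establishment (or at the end of a shorter
    series).
    """
    pivot = profile_series.pivot_table(index="time_s", columns="row", values="mean_uM").sort_index()
    times = pivot.index.to_numpy(dtype=float)
    means = pivot.to_numpy()  # (nt, n_rows) ordered row 1..n
    if times[-1] < establishment_time_s:
        raise ValueError("profile series shorter than the establishment window")

    k_est = int(np.searchsorted(times, establishment_time_s))
    ref = np.array(
        [np.interp(establishment_time_s, times, means[:, j]) for j in range(means.shape[1])]
    )
    if np.any(ref <= 0):
        raise ValueError("row means at establishment must be positive")

    t_stable = times[-1] - establishment_time_s
    for k in range(k_est, len(times)):
        if times[k] < establishment_time_s:
            continue
        row = means[k]
        ordered = bool(np.all(np.diff(row) < 0))
        within = bool(np.all(np.abs(row - ref) / ref <= drift_tolerance))
        if not (ordered and within):
            t_stable = max(0.0, times[k] - establishment_time_s)
            break

    t_24 = min(establishment_time_s + 24 * 3600.0, times[-1])
    at_24 = np.array([np.interp(t_24, times, means[:, j]) for j in range(means.shape[1])])
    per_row = np.abs(at_24 - ref) / ref
    return StabilityMetrics(
        t_stable_s=float(t_stable),
        drift_24h=float(per_row.max()),
        per_row_drift=tuple(float(v) for v in per_row),
        establishment_time_s=establishment_time_s,
    )
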