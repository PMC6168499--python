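"""End-to-end orchestration: device -> gradient -> screen -> curves.

A single YAML config drives the whole synthetic screen: the hydraulic
network is simulated to get the central-channel flow and the expected
end-of-run reservoir volumes (the QC reference), the transport solver
turns the flow into per-row doses and stability metrics, the generator
renders a ground-truthed image set at those doses, the image pipeline
measures it, and the dose-response stage fits EC50s and the S_F/V_F
correlation.  Every stage writes tidy artifacts into the run directory
and the report records seeds and a config hash so runs are reproducible
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import device as dev
from . import gradient as grad
from .doseresp import (
    DEFAULT_SIZE_GROUPS,
    aggregate_rows,
    assign_row_doses,
    correlate_sf_vf,
    fit_concentration_response,
    group_by_size,
)
from .imaging import SegmentationParams, exclude_edge_columns, measure_timecourse
from .layout import generate_layout
from .synth import make_ground_truth, render_experiment

__all__ = ["ConfigError", "RunConfig", "RunReport", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration is invalid or incomplete."""


@dataclass(frozen=True)
class ApplicationWindow:
    day: int
    duration_h: float
    scale: float = 1.0  # source-concentration multiplier vs the first window


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic screen."""

    seed: int = 1
    device: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)
    compound: dict = field(
        default_factory=lambda: {
            "name": "cisplatin",
            "molecular_weight": 300.0,
            "source_concentration_uM": 250.0,
        }
    )
    days: tuple[int, ...] = (4, 5, 6, 7, 8)
    drug_day: int = 5
    incubation_h: float = 12.0
    establishment_h: float = 1.0
    effect_mode: str = "disaggregation"
    true_ec50_uM: float = 100.0
    hill_slope: float = 3.0
    second_application: ApplicationWindow | None = None
    exclude_edge_columns: int = 3
    grid_spacing_um: float = 50.0
    pixel_scale_um: float = 1.0

    def __post_init__(self) -> None:
        if self.drug_day not in self.days:
            raise ConfigError("experiment.drug_day must be one of experiment.days")
        if self.incubation_h <= 0 or self.establishment_h < 0:
            raise ConfigError("incubation and establishment durations must be positive")
        if self.effect_mode not in ("disaggregation", "shrinkage"):
            raise ConfigError(f"unknown effect mode {self.effect_mode!r}")
        mw = self.compound.get("molecular_weight")
        if mw is None or mw <= 0:
            raise ConfigError("compound.molecular_weight must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        exp = dict(raw.pop("experiment", {}))
        ana = dict(raw.pop("analysis", {}))
        second = exp.pop("second_application", None)
        try:
            return cls(
                seed=int(raw.pop("seed", 1)),
                device=dict(raw.pop("device", {})),
                layout=dict(raw.pop("layout", {})),
                compound=dict(raw.pop("compound", cls().compound)),
                days=tuple(exp.pop("days", (4, 5, 6, 7, 8))),
                drug_day=int(exp.pop("drug_day", 5)),
                incubation_h=float(exp.pop("incubation_h", 12.0)),
                establishment_h=float(exp.pop("establishment_h", 1.0)),
                effect_mode=exp.pop("effect_mode", "disaggregation"),
                true_ec50_uM=float(exp.pop("true_ec50_uM", 100.0)),
                hill_slope=float(exp.pop("hill_slope", 3.0)),
                second_application=(
                    ApplicationWindow(**second) if second else None
                ),
                exclude_edge_columns=int(ana.pop("exclude_edge_columns", 3)),
                grid_spacing_um=float(ana.pop("grid_spacing_um", 50.0)),
                pixel_scale_um=float(ana.pop("pixel_scale_um", 1.0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summaries with full provenance."""

    config_hash: str
    seed: int
    stages: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages},
                fh,
                indent=2,
                default=_jsonify,
            )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def simulate_device_stage(config: RunConfig, duration_s: float):
    network = dev.standard_gradient_device(**config.device)
    r_t = network.effective_total_resistance()
    trace, state = dev.simulate_network(network, duration_s, step_s=5.0)
    return network, r_t, trace, state


def simulate_gradient_stage(config: RunConfig, trace, r_t, duration_s: float):
    layout = generate_layout(**config.layout)
    compound = grad.CompoundProperties(
        name=config.compound.get("name", "compound"),
        molecular_weight=float(config.compound["molecular_weight"]),
        source_concentration_uM=float(config.compound.get("source_concentration_uM", 100.0)),
        diffusion_coefficient=config.compound.get("diffusion_coefficient"),
    )
    fieldc = grad.solve_gradient(
        layout, (trace, r_t), compound, duration_s, grid_spacing_um=config.grid_spacing_um
    )
    series = grad.row_concentration_series(fieldc, layout, config.exclude_edge_columns)
    stability = grad.stability_metrics(
        series, establishment_time_s=config.establishment_h * 3600.0
    )
    # dose assigned to each row: mean over the incubation window
    t_lo = config.establishment_h * 3600.0
    t_hi = min(t_lo + config.incubation_h * 3600.0, float(series["time_s"].max()))
    window = series[(series.time_s >= t_lo) & (series.time_s <= t_hi)]
    doses = window.groupby("row")["mean_uM"].mean().sort_index()
    profile = [
        grad.RowConcentrationProfile(
            row=int(r),
            mean_uM=float(m),
            spread_frac=float(
                window[window.row == r]["spread_frac"].mean()
            ),
            n_wells=int(window[window.row == r]["n_wells"].iloc[0]),
        )
        for r, m in doses.items()
    ]
    return layout, compound, fieldc, series, stability, profile


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute the full synthetic screen and write artifacts to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    duration_s = (config.establishment_h + config.incubation_h) * 3600.0

    # --- device hydraulics -------------------------------------------------
    network, r_t, trace, state = simulate_device_stage(config, duration_s)
    expected = state.expected_final_volumes_uL()
    stride = max(1, len(state.times_s) // 400)  # keep the CSV compact
    thin_state = dev.ReservoirState(
        state.times_s[::stride],
        {k: v[::stride] for k, v in state.volumes_uL.items()},
        {k: v[::stride] for k, v in state.overflow_discharged_uL.items()},
    )
    thin_trace = dev.PressureTrace(
        trace.times_s[::stride], trace.p_cs_pa[::stride], trace.p_cc_pa[::stride]
    )
    thin_state.to_frame(thin_trace, r_t).to_csv(out / "reservoirs.csv", index=False)
    pd.DataFrame(
        {"reservoir": list(expected), "expected_volume_uL": list(expected.values())}
    ).to_csv(out / "volumes_expected.csv", index=False)
    stages["device"] = {
        "total_resistance_Pa_s_m3": r_t,
        "dP0_Pa": float(trace.dp_pa[0]),
        "dP_end_Pa": float(trace.dp_pa[-1]),
        "expected_volumes_uL": expected,
    }

    # --- gradient ----------------------------------------------------------
    layout, compound, fieldc, series, stability, profile = simulate_gradient_stage(
        config, trace, r_t, duration_s
    )
    series.to_csv(out / "row_profile.csv", index=False)
    stages["gradient"] = {
        "diffusivity_m2s": compound.diffusivity,
        "effective_dt_s": fieldc.effective_dt_s,
        "t_stable_h": stability.t_stable_s / 3600.0,
        "drift_24h_frac": stability.drift_24h,
        "row_doses_uM": [p.mean_uM for p in profile],
    }

    # --- application windows ----------------------------------------------
    windows = [ApplicationWindow(config.drug_day, config.incubation_h, 1.0)]
    if config.second_application is not None:
        windows.append(config.second_application)
    stages["applications"] = [dataclasses.asdict(w) for w in windows]
    dose_scale = windows[-1].scale

    # --- synthetic screen --------------------------------------------------
    row_doses = tuple(p.mean_uM * dose_scale for p in profile)
    gt = make_ground_truth(
        layout,
        seed=config.seed,
        ec50_uM=config.true_ec50_uM,
        hill_slope=config.hill_slope,
        effect_mode=config.effect_mode,
        row_doses_uM=row_doses,
    )
    images = render_experiment(
        ground_truth=gt,
        days=config.days,
        drug_day=config.drug_day,
        pixel_scale_um=config.pixel_scale_um,
        seed=config.seed,
    )
    images.manifest.to_csv(out / "manifest.csv", index=False)
    stages["synthetic"] = {
        "n_wells": layout.n_wells,
        "true_ec50_uM": gt.ec50_uM,
        "effect_mode": gt.effect_mode,
        "row_doses_uM": list(row_doses),
    }

    # --- QC (synthetic runs measure exactly the expected volumes) ----------
    qc = dev.qc_volume_check(expected, expected)
    stages["qc"] = {"verdict": qc.verdict, "deviations": qc.deviations}

    # --- image analysis ----------------------------------------------------
    table = measure_timecourse(images, layout, SegmentationParams(invert=True))
    table.to_csv(out / "measurements.csv", index=False)
    retained = exclude_edge_columns(table, layout, config.exclude_edge_columns)
    retained = assign_row_doses(retained, row_doses)
    retained.to_csv(out / "measurements_retained.csv", index=False)
    stages["image_analysis"] = {
        "n_measurements": int(len(table)),
        "n_retained": int(len(retained)),
        "n_no_detection": int((table["flags"].str.contains("no_detection")).sum()),
    }

    # --- dose-response -----------------------------------------------------
    final = retained[retained.day == max(config.days)]
    fits = {}
    curves = []
    for readout in ("viable_fraction", "shape_factor"):
        pts = aggregate_rows(final, readout)
        curves.extend(
            {
                "row": p.row,
                "conc_uM": p.concentration_uM,
                "readout": p.readout,
                "mean": p.mean,
                "sem": p.sem,
                "n": p.n,
            }
            for p in pts
        )
        fit = fit_concentration_response(pts)
        fits[readout] = {
            "ec50_uM": fit.ec50_uM,
            "hill": fit.hill_slope,
            "top": fit.top,
            "bottom": fit.bottom,
            "converged": fit.converged,
            "n_points": fit.n_points,
        }
    groups = group_by_size(final, DEFAULT_SIZE_GROUPS)
    for label, sub in groups.items():
        pts = aggregate_rows(sub, "viable_fraction")
        if len(pts) >= 4:
            gfit = fit_concentration_response(pts)
            fits[f"viable_fraction[{label}]"] = {
                "ec50_uM": gfit.ec50_uM,
                "converged": gfit.converged,
                "n_points": gfit.n_points,
            }
    corr = correlate_sf_vf(final)
    pd.DataFrame(curves).to_csv(out / "curves.csv", index=False)
    stages["dose_response"] = {
        "fits": fits,
        "pearson_sf_vf": {"r": corr.r, "n": corr.n, "defined": corr.defined},
        "n_curve_points": int(final["well_row"].nunique()),
    }

    report = RunReport(config_hash=config.config_hash(), seed=config.seed, stages=stages)
    report.to_json(out / "report.json")
    return report
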