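"""End-to-end six-catheter comparison: phantom -> catheters -> solves -> report.

Per design the pipeline finds the per-vector current reaching 90%
transmurality of the target band, then evaluates the power efficiency, the
electrode current density (ECD) and the lesion volume at that current, and
assembles a Table-1-style report.

Only counted (near-target) deliveries are solved: off-target deliveries of
a rotated application neither reach the band nor enter the accounting, so
they are omitted from the field computation.  With linear tissue response
one unit-drive solve per delivery determines every metric exactly by
scaling; with the field-dependent conductivity enabled each bisection probe
re-solves the deliveries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .anatomy import (
    AnatomyGrid,
    ConductivityField,
    TargetRegion,
    assign_conductivity,
    build_phantom,
    default_conductivity_table,
    define_target,
)
from .catheters import (
    DESIGNS,
    DOSE_SCHEDULES,
    N_VECTORS_ON_TARGET,
    build_catheter,
    electrode_metal_area,
    make_vector_scheme,
)
from .metrics import (
    MetricsReport,
    current_for_transmurality,
    electrode_current_density,
    lesion_volume_mm3,
    power_fraction_in_target,
    total_delivery_duration,
    transmural_fraction,
)
from .solver import SolverOptions, solve_delivery

__all__ = [
    "RunConfig",
    "CatheterCase",
    "run_catheter_case",
    "run_comparison",
    "PAPER_EFFICIENCY_ORDER",
]

log = logging.getLogger("pfa_fieldsim")

#: Ascending published efficiency ordering (least to most efficient).
PAPER_EFFICIENCY_ORDER = (
    "oneshot_sphere",
    "focal_sphere_9mm",
    "penta_spline",
    "circular",
    "flex_splines",
    "balloon",
)


@dataclass
class RunConfig:
    """Configuration of a comparison run (YAML-serializable)."""

    phantom_kind: str = "antrum"
    phantom_params: dict = dc_field(default_factory=dict)
    spacing_mm: float = 1.0
    band_length_mm: float = 47.0
    band_width_mm: float = 6.0
    nonlinear_conductivity: bool = False
    conductivity_fold_change: float = 2.0
    designs: tuple = DESIGNS
    design_params: dict = dc_field(default_factory=dict)
    solver: SolverOptions = dc_field(default_factory=SolverOptions)
    threshold_v_per_cm: float = 600.0
    transmurality_level: float = 0.9
    current_range_a: tuple = (2.0, 70.0)
    reference_current_a: float = 10.0
    output_dir: str | None = None
    save_fields: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs requested: {sorted(unknown)}")
        if not isinstance(self.solver, SolverOptions):
            self.solver = SolverOptions(**self.solver)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "designs" in data:
            data["designs"] = tuple(data["designs"])
        if "current_range_a" in data:
            data["current_range_a"] = tuple(data["current_range_a"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "solver"
        }
        data["solver"] = dict(self.solver.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _prepare(config: RunConfig) -> tuple[AnatomyGrid, ConductivityField, TargetRegion]:
    grid = build_phantom(config.phantom_kind, config.phantom_params, config.spacing_mm)
    table = default_conductivity_table(
        nonlinear=config.nonlinear_conductivity,
        fold_change=config.conductivity_fold_change,
    )
    cond = assign_conductivity(grid, table)
    target = define_target(grid, config.band_length_mm, config.band_width_mm)
    return grid, cond, target


@dataclass
class CatheterCase:
    """One design on one phantom, with lazily solved counted deliveries."""

    config: RunConfig
    design: str
    grid: AnatomyGrid
    cond: ConductivityField
    target: TargetRegion

    def __post_init__(self) -> None:
        params = self.config.design_params.get(self.design)
        self.electrodes = build_catheter(self.design, self.grid, self.target, params)
        self.scheme = make_vector_scheme(
            self.electrodes, self.config.band_length_mm, self.config.band_width_mm
        )
        self._ref_solutions = None

    @property
    def counted(self):
        return self.scheme.counted_deliveries

    def solve_counted(self, per_vector_current_a: float):
        """Solve every counted delivery at the given per-vector current."""
        sols = []
        for d in self.counted:
            t0 = time.perf_counter()
            sol = solve_delivery(
                self.grid,
                self.cond,
                self.electrodes,
                d,
                per_vector_current_a * d.n_positive,
                self.config.solver,
            )
            log.info(
                json.dumps(
                    {
                        "design": self.design,
                        "delivery": d.label,
                        "per_vector_current_a": per_vector_current_a,
                        "applied_voltage_v": round(sol.applied_voltage, 3),
                        "achieved_current_a": round(sol.achieved_current, 4),
                        "linear_solves": sol.iterations,
                        "wall_s": round(time.perf_counter() - t0, 2),
                    }
                )
            )
            sols.append(sol)
        return sols

    def reference_solutions(self):
        if self._ref_solutions is None:
            self._ref_solutions = self.solve_counted(self.config.reference_current_a)
        return self._ref_solutions

    def fields_at(self, per_vector_current_a: float):
        """Combined per-delivery field maps at a per-vector current."""
        if self.cond.is_linear:
            scale = per_vector_current_a / self.config.reference_current_a
            return [s.e_mag * scale for s in self.reference_solutions()]
        return [s.e_mag for s in self.solve_counted(per_vector_current_a)]

    def transmural_fraction_at(self, per_vector_current_a: float) -> float:
        return transmural_fraction(
            self.fields_at(per_vector_current_a),
            self.target,
            self.config.threshold_v_per_cm,
        )

    @property
    def power_weights(self):
        return [d.n_vectors / d.n_positive for d in self.counted]


def run_catheter_case(config: RunConfig, design: str, _shared=None) -> dict:
    """Compute the full metrics record for one design.

    Returns a dict with the dose current, efficiency, ECD, ECD x N, vector
    count and lesion volume.  ``_shared`` may carry a pre-built
    (grid, cond, target) triple so a comparison reuses one phantom.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    grid, cond, target = _shared if _shared is not None else _prepare(config)
    case = CatheterCase(config, design, grid, cond, target)

    result = current_for_transmurality(
        case.transmural_fraction_at,
        level=config.transmurality_level,
        current_range_a=tuple(config.current_range_a),
    )
    i90 = result.current_a
    if cond.is_linear:
        sols = case.reference_solutions()
        fields_i90 = case.fields_at(i90)
    else:
        sols = case.solve_counted(i90)
        fields_i90 = [s.e_mag for s in sols]

    efficiency = power_fraction_in_target(sols, target, weights=case.power_weights)
    area = electrode_metal_area(design, case.electrodes)
    ecd = electrode_current_density(i90, area)
    n_vec = case.scheme.n_vectors_on_target
    record = {
        "design": design,
        "current_for_90_transmurality_a": float(i90),
        "transmurality_achieved": bool(result.achieved),
        "electrode_area_cm2": float(area),
        "ecd_a_per_cm2": float(ecd),
        "n_vectors_on_target": int(n_vec),
        "ecd_times_n": float(ecd * n_vec),
        "efficiency_percent": float(efficiency),
        "lesion_volume_mm3": lesion_volume_mm3(
            fields_i90, grid, config.threshold_v_per_cm
        ),
    }
    if design in DOSE_SCHEDULES:
        record["total_delivery_duration_ms"] = total_delivery_duration(
            DOSE_SCHEDULES[design]
        )
    if config.save_fields and config.output_dir:
        from . import io as fio

        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.save_fields(out / f"fields_{design}.h5", grid, case.counted, sols)
    return record


def run_comparison(config: RunConfig) -> MetricsReport:
    """Run every requested design on a shared phantom and emit the report."""
    if len(config.designs) < 2:
        raise ValueError("a comparison needs at least two designs")
    shared = _prepare(config)
    records = []
    for design in config.designs:
        try:
            records.append(run_catheter_case(config, design, _shared=shared))
        except Exception as exc:  # noqa: BLE001 - partial failures are recorded
            log.error("design %s failed: %s", design, exc)
            records.append({"design": design, "error": str(exc)})
    report = MetricsReport(records=records)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.rounded_frame().to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(records, fh, indent=2)
    return report


def efficiency_rank_correlation(report: MetricsReport) -> float:
    """Spearman correlation of computed efficiency against the published order."""
    from scipy.stats import spearmanr

    df = report.to_frame().set_index("design")
    designs = [d for d in PAPER_EFFICIENCY_ORDER if d in df.index]
    eff = df.loc[designs, "efficiency_percent"].to_numpy(dtype=float)
    expected = np.arange(len(designs), dtype=float)
    rho = spearmanr(expected, eff).statistic
    return float(rho)


def current_rank_correlation(report: MetricsReport) -> float:
    """Spearman correlation of dose current against the inverse published order."""
    from scipy.stats import spearmanr

    df = report.to_frame().set_index("design")
    designs = [d for d in PAPER_EFFICIENCY_ORDER if d in df.index]
    cur = df.loc[designs, "current_for_90_transmurality_a"].to_numpy(dtype=float)
    expected = np.arange(len(designs), dtype=float)
    rho = spearmanr(expected, cur).statistic
    return float(rho)
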