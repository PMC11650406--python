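"""Persistence: phantoms and field maps as HDF5, conductivity tables as YAML,
and an NRRD-compatible raw+header label export for visual inspection."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .anatomy import (
    AnatomyGrid,
    ConductivityTable,
    NonlinearConductivityModel,
    TissueConductivity,
)

__all__ = [
    "save_grid",
    "load_grid",
    "save_fields",
    "save_conductivity_table",
    "load_conductivity_table",
    "export_labels_nrrd",
]


def save_grid(path: str | Path, grid: AnatomyGrid) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=grid.labels, compression="gzip")
        ds.attrs["spacing_mm"] = grid.spacing_mm
        ds.attrs["origin_mm"] = grid.origin_mm
        ds.attrs["kind"] = grid.kind
        ds.attrs["meta_yaml"] = yaml.safe_dump(_plain(grid.meta))


def load_grid(path: str | Path) -> AnatomyGrid:
    with h5py.File(path, "r") as f:
        ds = f["labels"]
        return AnatomyGrid(
            labels=ds[...],
            spacing_mm=float(ds.attrs["spacing_mm"]),
            origin_mm=np.asarray(ds.attrs["origin_mm"]),
            kind=str(ds.attrs["kind"]),
            meta=yaml.safe_load(ds.attrs["meta_yaml"]),
        )


def save_fields(path: str | Path, grid: AnatomyGrid, deliveries, solutions) -> None:
    """Converged potential / field / power maps for a list of deliveries."""
    with h5py.File(path, "w") as f:
        f.attrs["spacing_mm"] = grid.spacing_mm
        f.attrs["origin_mm"] = grid.origin_mm
        for d, sol in zip(deliveries, solutions, strict=True):
            g = f.create_group(d.label or f"delivery{len(f)}")
            for name in ("potential", "e_mag", "power_density"):
                g.create_dataset(name, data=getattr(sol, name).astype(np.float32),
                                 compression="gzip")
            g.attrs["applied_voltage_v"] = sol.applied_voltage
            g.attrs["achieved_current_a"] = sol.achieved_current
            g.attrs["iterations"] = sol.iterations
            g.attrs["residual"] = sol.residual


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_conductivity_table(path: str | Path, table: ConductivityTable) -> None:
    data = {}
    for name, tc in table.entries.items():
        entry: dict = {"sigma0_s_per_m": tc.sigma0}
        if tc.nonlinear is not None:
            nl = tc.nonlinear
            entry["nonlinear"] = {
                "fold_change": nl.fold_change,
                "e_mid_v_per_cm": nl.e_mid_v_per_cm,
                "width_v_per_cm": nl.width_v_per_cm,
            }
        data[name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_conductivity_table(path: str | Path) -> ConductivityTable:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = {}
    for name, entry in data.items():
        sigma0 = float(entry["sigma0_s_per_m"])
        nl = None
        if "nonlinear" in entry:
            nl = NonlinearConductivityModel(sigma0=sigma0, **entry["nonlinear"])
        entries[name] = TissueConductivity(sigma0=sigma0, nonlinear=nl)
    return ConductivityTable(entries=entries)


def export_labels_nrrd(path_stem: str | Path, grid: AnatomyGrid) -> None:
    """Detached NRRD header + raw volume, loadable by standard viewers."""
    stem = Path(path_stem)
    raw = stem.with_suffix(".raw")
    grid.labels.astype(np.uint8).tofile(raw)
    h = grid.spacing_mm
    header = "\n".join(
        [
            "NRRD0004",
            "type: uint8",
            "dimension: 3",
            f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}",
            "encoding: raw",
            "endian: little",
            "space: left-posterior-superior",
            f"space directions: ({h},0,0) (0,{h},0) (0,0,{h})",
            f"space origin: ({grid.origin_mm[0]},{grid.origin_mm[1]},{grid.origin_mm[2]})",
            f"data file: {raw.name}",
            "",
        ]
    )
    stem.with_suffix(".nhdr").write_text(header)
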