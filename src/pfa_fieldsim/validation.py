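"""Closed-form validation problems for the volume-conductor solver.

Three classic configurations with analytic solutions:

* parallel plate — uniform medium between full-face plate electrodes; the
  interior field is V/d and the current sigma*A*V/d, both reproduced to
  solver precision by the finite-volume scheme.
* spreading resistance — a small spherical electrode of radius a inside a
  concentric grounded shell of radius b in a uniform medium; the access
  resistance is (1/a - 1/b)/(4*pi*sigma), approaching the classic
  1/(4*pi*sigma*a) as b grows.  Discretization error shrinks under grid
  refinement.
* conservation — net current over all electrodes vanishes and Joule power
  equals the sum of I*V over the driven electrodes.
"""

from __future__ import annotations

import math

import numpy as np

from .anatomy import (
    LABELS,
    AnatomyGrid,
    assign_conductivity,
    build_phantom,
    default_conductivity_table,
    define_target,
)
from .catheters import Delivery, Electrode, ElectrodeSet, build_catheter, make_vector_scheme
from .solver import compute_current, solve_delivery

__all__ = [
    "uniform_grid",
    "parallel_plate_case",
    "spreading_resistance_case",
    "conservation_case",
    "run_validation",
]


def uniform_grid(shape, spacing_mm: float, label: str = "myocardium") -> AnatomyGrid:
    labels = np.full(shape, LABELS[label], dtype=np.int8)
    return AnatomyGrid(labels, spacing_mm, np.zeros(3), kind="custom")


def _custom_set(electrodes: list[Electrode]) -> ElectrodeSet:
    return ElectrodeSet(design="custom", electrodes=electrodes)


def parallel_plate_case(spacing_mm: float = 0.5, shape=(24, 24, 17), current_a: float = 1.0):
    """Uniform slab between two full-face plates; returns (solution, context)."""
    grid = uniform_grid(shape, spacing_mm)
    cond = assign_conductivity(grid, default_conductivity_table())
    plate_a = np.zeros(shape, dtype=bool)
    plate_b = np.zeros(shape, dtype=bool)
    plate_a[:, :, 0] = True
    plate_b[:, :, -1] = True
    els = _custom_set(
        [
            Electrode("plate_a", plate_a, 1.0),
            Electrode("plate_b", plate_b, 1.0),
        ]
    )
    delivery = Delivery({"plate_a": 1, "plate_b": -1}, True, 1, 1, label="plate")
    sol = solve_delivery(grid, cond, els, delivery, current_a)
    d_m = (shape[2] - 1) * spacing_mm * 1e-3
    area_m2 = shape[0] * shape[1] * (spacing_mm * 1e-3) ** 2
    sigma = float(cond.sigma0[0, 0, 0])
    return sol, dict(grid=grid, electrodes=els, d_m=d_m, area_m2=area_m2, sigma=sigma)


def spreading_resistance_case(
    spacing_mm: float = 0.5,
    electrode_radius_mm: float = 2.5,
    shell_radius_mm: float = 12.0,
    extent_mm: float = 28.0,
):
    """Sphere-in-shell access resistance; returns (V/I, closed forms)."""
    n = int(round(extent_mm / spacing_mm))
    grid = uniform_grid((n, n, n), spacing_mm)
    cond = assign_conductivity(grid, default_conductivity_table())
    c = np.arange(n) * spacing_mm + spacing_mm / 2.0 - extent_mm / 2.0
    X = c[:, None, None]
    Y = c[None, :, None]
    Z = c[None, None, :]
    r = np.sqrt(X**2 + Y**2 + Z**2)
    inner = r <= electrode_radius_mm
    shell = np.abs(r - shell_radius_mm) <= 0.6 * spacing_mm
    els = _custom_set(
        [Electrode("sphere", inner, 1.0), Electrode("shell", shell, 1.0)]
    )
    delivery = Delivery({"sphere": 1, "shell": -1}, True, 1, 1, label="spread")
    sol = solve_delivery(grid, cond, els, delivery, 1.0)
    r_num = sol.applied_voltage / sol.achieved_current
    sigma = float(cond.sigma0[0, 0, 0])
    a = electrode_radius_mm * 1e-3
    b = shell_radius_mm * 1e-3
    r_two_sphere = (1.0 / a - 1.0 / b) / (4.0 * math.pi * sigma)
    r_infinite = 1.0 / (4.0 * math.pi * sigma * a)
    return r_num, r_two_sphere, r_infinite, sol


def conservation_case(spacing_mm: float = 0.5, current_a: float = 10.0):
    """Circular catheter on a slab: current balance and power conservation."""
    grid = build_phantom("slab", {"extent_mm": (72.0, 24.0, 16.0)}, spacing_mm)
    target = define_target(grid, band_length_mm=60.0, band_width_mm=6.0)
    els = build_catheter("circular", grid, target)
    scheme = make_vector_scheme(els, band_length_mm=60.0, band_width_mm=6.0)
    delivery = scheme.deliveries[0]
    sol = solve_delivery(grid, cond := assign_conductivity(grid, default_conductivity_table()), els, delivery, current_a)
    net = sum(compute_current(sol, els, el.name, grid) for el in els.electrodes)
    joule = float(sol.power_density.sum())
    return sol, net, joule, els, grid


def run_validation(spacing_mm: float = 0.5) -> dict:
    """Run all closed-form checks; returns named relative errors."""
    out: dict[str, float] = {}

    sol, ctx = parallel_plate_case(spacing_mm)
    e_expect = sol.applied_voltage / ctx["d_m"] / 100.0  # V/cm
    interior = sol.e_mag[:, :, 1:-1]
    out["parallel_plate_e_rel_err"] = float(
        np.max(np.abs(interior - e_expect) / e_expect)
    )
    i_expect = ctx["sigma"] * ctx["area_m2"] * sol.applied_voltage / ctx["d_m"]
    out["parallel_plate_current_rel_err"] = float(
        abs(sol.achieved_current - i_expect) / i_expect
    )

    r_num, r_two, r_inf, _ = spreading_resistance_case(spacing_mm)
    out["spreading_resistance_rel_err"] = float((r_num - r_two) / r_two)
    out["spreading_resistance_vs_infinite_rel_err"] = float((r_num - r_inf) / r_inf)

    sol, net, joule, els, grid = conservation_case(spacing_mm)
    out["current_balance_rel_err"] = float(abs(net) / sol.achieved_current)
    out["power_conservation_rel_err"] = float(
        abs(joule - sol.total_power) / sol.total_power
    )
    return out
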