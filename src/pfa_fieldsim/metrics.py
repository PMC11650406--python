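"""Outcome metrics: transmurality, dose current, power efficiency, ECD.

The lesion produced by a sequence of deliveries is the union rule: a voxel
is electroporated when the field magnitude of *any* delivery exceeds the
lethal threshold (default 600 V/cm), the standard dose assumption for
sequential identical pulses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .anatomy import AnatomyGrid, TargetRegion
from .catheters import DoseSchedule
from .solver import FieldSolution

__all__ = [
    "E_THRESHOLD_V_PER_CM",
    "combined_field",
    "transmural_fraction",
    "TransmuralityCurrent",
    "current_for_transmurality",
    "linear_current_for_transmurality",
    "power_fraction_in_target",
    "electrode_current_density",
    "total_delivery_duration",
    "lesion_volume_mm3",
    "MetricsReport",
]

#: Conservative lethal electroporation threshold for myocardium, V/cm.
E_THRESHOLD_V_PER_CM = 600.0


def combined_field(solutions: Sequence[FieldSolution | np.ndarray]) -> np.ndarray:
    """Per-voxel maximum field magnitude (V/cm) across deliveries."""
    if len(solutions) == 0:
        raise ValueError("no solutions supplied")
    fields = [s.e_mag if isinstance(s, FieldSolution) else np.asarray(s) for s in solutions]
    out = fields[0].copy()
    for f in fields[1:]:
        np.maximum(out, f, out=out)
    return out


def transmural_fraction(
    solutions: Sequence[FieldSolution | np.ndarray],
    target: TargetRegion,
    threshold: float = E_THRESHOLD_V_PER_CM,
) -> float:
    """Fraction of target-wall volume above the electroporation threshold."""
    if target.n_voxels == 0:
        raise ValueError("target region is empty")
    e = combined_field(solutions)[target.mask]
    return float(np.mean(e > threshold))


@dataclass(frozen=True)
class TransmuralityCurrent:
    """Per-vector current needed for a transmurality level, or the failure flag."""

    current_a: float
    achieved: bool
    level: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.achieved:
            return f"{self.current_a:.1f} A"
        return f"not achieved at {self.current_a:.0f} A"


def current_for_transmurality(
    fraction_at_current: Callable[[float], float],
    level: float = 0.9,
    current_range_a: tuple[float, float] = (2.0, 70.0),
    rel_tol: float = 0.01,
) -> TransmuralityCurrent:
    """Smallest per-vector current reaching the transmurality level.

    ``fraction_at_current`` evaluates the (non-decreasing) transmural
    fraction at a given per-vector current; bisection narrows the bracket to
    the requested relative width.  A level that is not reached at the upper
    search bound is reported as not achieved rather than raised.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must lie in (0, 1]")
    lo, hi = current_range_a
    if fraction_at_current(hi) < level:
        return TransmuralityCurrent(current_a=hi, achieved=False, level=level)
    if fraction_at_current(lo) >= level:
        return TransmuralityCurrent(current_a=lo, achieved=True, level=level)
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if fraction_at_current(mid) >= level:
            hi = mid
        else:
            lo = mid
    return TransmuralityCurrent(current_a=hi, achieved=True, level=level)


def linear_current_for_transmurality(
    e_mag_per_ref: Sequence[np.ndarray],
    target: TargetRegion,
    reference_current_a: float,
    level: float = 0.9,
    threshold: float = E_THRESHOLD_V_PER_CM,
) -> float:
    """Closed-form dose current for linear conductivity (quantile scaling).

    With linear tissue response every field map scales with the drive, so
    the current reaching the level is I_ref * threshold / q, where q is the
    (1 - level) quantile of the combined field over the target at I_ref.
    """
    e = combined_field(e_mag_per_ref)[target.mask]
    q = float(np.quantile(e, 1.0 - level))
    if q <= 0:
        raise ValueError("field is zero at the target quantile; level unreachable")
    return reference_current_a * threshold / q


def power_fraction_in_target(
    solutions: Sequence[FieldSolution],
    target: TargetRegion,
    weights: Sequence[float] | None = None,
) -> float:
    """Percent of delivered power dissipated inside the target band.

    Numerator: Joule power inside the target, summed over the counted
    deliveries (face-flux attribution, so partitions over disjoint regions
    are exactly conservative).  Denominator: the corresponding sum of I*V.
    ``weights`` apportions a delivery's generator power when only a subset
    of its simultaneous vectors faces the target (weight = on-target
    vectors / positive electrodes).
    """
    if weights is None:
        weights = [1.0] * len(solutions)
    num = 0.0
    den = 0.0
    for sol, w in zip(solutions, weights, strict=True):
        num += float(sol.power_density[target.mask].sum())
        den += sol.total_power * w
    if den <= 0:
        raise ValueError("zero delivered power")
    return 100.0 * num / den


def electrode_current_density(current_a: float, area_cm2: float) -> float:
    """Per-vector current divided by the electrode metal area (A/cm^2)."""
    if area_cm2 <= 0:
        raise ValueError("electrode area must be positive")
    return current_a / area_cm2


def total_delivery_duration(schedule: DoseSchedule) -> float:
    """Total energized time per PV (ms): applications x deliveries x duration."""
    return (
        schedule.n_applications
        * schedule.n_deliveries_per_application
        * schedule.delivery_duration_ms
    )


def lesion_volume_mm3(
    solutions: Sequence[FieldSolution | np.ndarray],
    grid: AnatomyGrid,
    threshold: float = E_THRESHOLD_V_PER_CM,
) -> float:
    """Volume of myocardium (target or not) above threshold, union rule."""
    e = combined_field(solutions)
    myo = grid.mask("myocardium")
    return float(np.count_nonzero(myo & (e > threshold)) * grid.voxel_volume_mm3)


@dataclass
class MetricsReport:
    """Per-design outcome records, exportable in Table-1-like layout."""

    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "design",
            "current_for_90_transmurality_a",
            "transmurality_achieved",
            "electrode_area_cm2",
            "ecd_a_per_cm2",
            "n_vectors_on_target",
            "ecd_times_n",
            "efficiency_percent",
            "lesion_volume_mm3",
        ]
        df = pd.DataFrame(self.records)
        return df[[c for c in cols if c in df.columns]]

    def rounded_frame(self) -> pd.DataFrame:
        """Table-style rounding: currents to 0.1 A, ECD columns to integers."""
        df = self.to_frame().copy()
        if "current_for_90_transmurality_a" in df:
            df["current_for_90_transmurality_a"] = df[
                "current_for_90_transmurality_a"
            ].round(1)
        for c in ("ecd_a_per_cm2", "ecd_times_n"):
            if c in df:
                df[c] = df[c].round().astype("Int64")
        return df
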