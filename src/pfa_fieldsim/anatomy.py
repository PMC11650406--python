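"""Synthetic voxel phantoms of the ablation anatomy.

Two phantom kinds stand in for a CT-derived thorax model:

* ``slab`` — a flat myocardial plate over connective background with a blood
  pool above.  Used for solver validation against closed forms and for
  single-panel field-structure experiments.
* ``antrum`` — an idealized left-pulmonary-vein antrum: a blood-filled
  cylindrical vein opening through a funnel into a larger blood chamber,
  wrapped everywhere by a myocardial shell of uniform 2.5 mm thickness,
  embedded in connective background.

Coordinates are voxel-centered: physical position = origin + (index + 0.5) *
spacing, with array axes (x, y, z) and the antrum's axis of revolution along
z through the domain center.  All lengths are millimetres unless suffixed
otherwise; conductivities are S/m and field magnitudes V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "AnatomyGrid",
    "TargetRegion",
    "NonlinearConductivityModel",
    "TissueConductivity",
    "ConductivityTable",
    "ConductivityField",
    "default_conductivity_table",
    "build_phantom",
    "define_target",
    "assign_conductivity",
    "probe_wall_thickness",
]

#: Integer code per tissue class.
LABELS = {
    "connective_background": 0,
    "blood": 1,
    "myocardium": 2,
    "balloon_insulator": 3,
    "electrode_metal": 4,
    "domain_boundary_patch": 5,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

WALL_THICKNESS_MM = 2.5  # atrial wall thickness used throughout


@dataclass
class AnatomyGrid:
    """Labeled voxel volume with physical spacing.

    Attributes
    ----------
    labels : (nx, ny, nz) int8 array of tissue-class codes (see ``LABELS``).
    spacing_mm : isotropic voxel edge length.
    origin_mm : physical position of the grid corner (not the first voxel
        center).
    kind : "slab" or "antrum".
    meta : geometry parameters the phantom was built from (lumen radius,
        wall thickness, band surface frame, ...), used by catheter placement.
    """

    labels: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    kind: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        present = set(np.unique(self.labels).tolist())
        if not present <= set(LABEL_NAMES):
            raise ValueError(f"unknown label codes present: {present - set(LABEL_NAMES)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.spacing_mm

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates as three broadcastable 1D axes."""
        axes = []
        for ax in range(3):
            n = self.shape[ax]
            c = self.origin_mm[ax] + (np.arange(n) + 0.5) * self.spacing_mm
            shape = [1, 1, 1]
            shape[ax] = n
            axes.append(c.reshape(shape))
        return tuple(axes)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm**3)


@dataclass
class TargetRegion:
    """Full-thickness wall band the catheters are scored against."""

    mask: np.ndarray
    nominal_dims_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self, grid: AnatomyGrid) -> float:
        return self.n_voxels * grid.voxel_volume_mm3


@dataclass(frozen=True)
class NonlinearConductivityModel:
    """Field-dependent conductivity: a monotone sigmoid in |E|.

    sigma(E) = sigma0 * (1 + A / (1 + exp(-(E - E_mid) / k)))

    so sigma(0) ~= sigma0 and sigma(inf) = sigma0 * (1 + A).  ``A`` is the
    signed fold change induced by membrane permeabilization; positive A
    (a conductivity increase at high field) is the default, matching the
    bulk-tissue electroporation literature, but the sign is configurable.

    Parameters are user-facing: E_mid and k in V/cm, sigma0 in S/m.
    """

    sigma0: float
    fold_change: float = 2.0
    e_mid_v_per_cm: float = 500.0
    width_v_per_cm: float = 80.0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.width_v_per_cm <= 0:
            raise ValueError("sigmoid width must be positive")


@dataclass(frozen=True)
class TissueConductivity:
    sigma0: float
    nonlinear: NonlinearConductivityModel | None = None


@dataclass
class ConductivityTable:
    """Per-tissue-class electrical properties."""

    entries: Mapping[str, TissueConductivity]

    def __post_init__(self) -> None:
        for name, tc in self.entries.items():
            if name not in LABELS:
                raise ValueError(f"unknown tissue class {name!r}")
            floor_ok = name == "balloon_insulator" and tc.sigma0 >= 0
            if tc.sigma0 <= 0 and not floor_ok:
                raise ValueError(f"sigma0 for {name!r} must be positive")


#: Insulator conductivity floor: keeps the discrete system non-singular while
#: making balloon-body current negligible.
INSULATOR_SIGMA = 1e-5


def default_conductivity_table(
    nonlinear: bool = False, fold_change: float = 2.0
) -> ConductivityTable:
    """Default tissue conductivities (S/m).

    Baselines follow the standard tissue-property compilations: blood 0.70,
    myocardium 0.20, connective background 0.10.  Only the ratios matter for
    the catheter comparison.  With ``nonlinear=True`` the myocardium gets the
    sigmoid field dependence (midpoint 500 V/cm, width 80 V/cm); blood and
    background stay linear.
    """
    myo_nl = (
        NonlinearConductivityModel(sigma0=0.20, fold_change=fold_change)
        if nonlinear
        else None
    )
    return ConductivityTable(
        entries={
            "blood": TissueConductivity(0.70),
            "myocardium": TissueConductivity(0.20, nonlinear=myo_nl),
            "connective_background": TissueConductivity(0.10),
            "balloon_insulator": TissueConductivity(INSULATOR_SIGMA),
        }
    )


@dataclass
class ConductivityField:
    """Per-voxel baseline conductivity and sigmoid nonlinearity parameters.

    ``fold_change`` is zero wherever the tissue is linear, so ``sigma0`` alone
    describes the linear case.
    """

    sigma0: np.ndarray
    fold_change: np.ndarray
    e_mid_v_per_cm: np.ndarray
    width_v_per_cm: np.ndarray

    @property
    def is_linear(self) -> bool:
        return bool(np.all(self.fold_change == 0.0))


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

_ANTRUM_DEFAULTS = dict(
    extent_mm=64.0,          # cubic domain edge
    vein_radius_mm=10.0,     # lumen radius of the cylindrical vein section
    chamber_radius_mm=22.0,  # lumen radius of the blood chamber
    funnel_top_z_mm=-12.0,   # vein is cylindrical above this z
    funnel_bottom_z_mm=-24.0,  # chamber radius reached below this z
    chamber_floor_z_mm=-28.0,  # lumen ends (wall cap) below this z
    wall_thickness_mm=WALL_THICKNESS_MM,
)

_SLAB_DEFAULTS = dict(
    extent_mm=(40.0, 40.0, 20.0),
    wall_thickness_mm=WALL_THICKNESS_MM,
    background_thickness_mm=5.0,
)


def _antrum_lumen_radius(z: np.ndarray, p: dict) -> np.ndarray:
    """Radius of the revolved lumen profile at height z (smooth funnel)."""
    rv, rc = p["vein_radius_mm"], p["chamber_radius_mm"]
    zt, zb = p["funnel_top_z_mm"], p["funnel_bottom_z_mm"]
    r = np.full_like(z, rv, dtype=float)
    in_funnel = (z < zt) & (z >= zb)
    frac = (zt - z[in_funnel]) / (zt - zb)
    r[in_funnel] = rv + (rc - rv) * 0.5 * (1.0 - np.cos(np.pi * frac))
    r[z < zb] = rc
    return r


def build_phantom(kind: str, params: dict | None = None, spacing_mm: float = 0.5) -> AnatomyGrid:
    """Generate a labeled voxel phantom.

    Parameters
    ----------
    kind : "slab" or "antrum".
    params : geometry overrides merged over the kind's defaults.
    spacing_mm : isotropic voxel size, in [0.1, 1.0]; must resolve the wall
        with at least two voxels.

    Returns
    -------
    AnatomyGrid with blood / myocardium / connective_background labels and the
    construction parameters recorded in ``meta``.
    """
    if not (0.1 <= spacing_mm <= 1.0):
        raise ValueError("spacing_mm must lie in [0.1, 1.0] mm")
    params = dict(params or {})

    if kind == "slab":
        p = {**_SLAB_DEFAULTS, **params}
        th = float(p["wall_thickness_mm"])
        if th / spacing_mm < 2:
            raise ValueError("spacing too coarse: wall must span >= 2 voxels")
        ext = np.asarray(p["extent_mm"], dtype=float)
        shape = np.round(ext / spacing_mm).astype(int)
        if not np.allclose(shape * spacing_mm, ext, atol=1e-9):
            raise ValueError("extent must be an integer number of voxels")
        labels = np.full(shape, LABELS["blood"], dtype=np.int8)
        origin = np.array([0.0, 0.0, 0.0])
        z = origin[2] + (np.arange(shape[2]) + 0.5) * spacing_mm
        bg_top = float(p["background_thickness_mm"])
        wall_top = bg_top + th
        labels[:, :, z < wall_top] = LABELS["myocardium"]
        labels[:, :, z < bg_top] = LABELS["connective_background"]
        meta = {**p, "wall_z_range_mm": (bg_top, wall_top)}
        return AnatomyGrid(labels, spacing_mm, origin, kind="slab", meta=meta)

    if kind == "antrum":
        p = {**_ANTRUM_DEFAULTS, **params}
        th = float(p["wall_thickness_mm"])
        if th / spacing_mm < 2:
            raise ValueError("spacing too coarse: wall must span >= 2 voxels")
        ext = float(p["extent_mm"])
        if ext < 60.0:
            raise ValueError("antrum phantom extent must be >= 60 mm per axis")
        n = int(round(ext / spacing_mm))
        shape = (n, n, n)
        origin = np.array([-ext / 2, -ext / 2, -ext / 2])
        cx = origin[0] + (np.arange(n) + 0.5) * spacing_mm
        x = cx[:, None, None]
        y = cx[None, :, None]
        z = cx[None, None, :]
        rho = np.sqrt(x**2 + y**2)
        r_lumen = _antrum_lumen_radius(np.broadcast_to(z, shape).reshape(-1), p).reshape(shape)
        blood = (rho <= r_lumen) & (z >= p["chamber_floor_z_mm"])
        # Uniform-thickness shell along surface normals via a Euclidean
        # distance transform of the blood pool.  The transform measures to
        # blood voxel centers; the endocardial surface sits half a voxel
        # beyond them, hence the half-spacing offset.
        dist = ndimage.distance_transform_edt(~blood, sampling=spacing_mm)
        labels = np.full(shape, LABELS["connective_background"], dtype=np.int8)
        labels[dist <= th + 0.49 * spacing_mm] = LABELS["myocardium"]
        labels[blood] = LABELS["blood"]
        meta = dict(p)
        return AnatomyGrid(labels, spacing_mm, origin, kind="antrum", meta=meta)

    raise ValueError(f"unknown phantom kind {kind!r}")


def define_target(
    grid: AnatomyGrid,
    band_length_mm: float = 47.0,
    band_width_mm: float = 6.0,
    center_z_mm: float = 0.0,
    center_angle_rad: float = 0.0,
) -> TargetRegion:
    """Mark the full-thickness wall band the metrics are computed over.

    On the antrum phantom the band is circumferential: ``band_length_mm`` of
    arc measured on the mid-wall circle, ``band_width_mm`` along the vein
    axis, centered on ``center_angle_rad`` (from +x).  On the slab it is an
    axis-aligned rectangle through the plate thickness.
    """
    if band_length_mm <= 0 or band_width_mm <= 0:
        raise ValueError("band dimensions must be positive")
    th = float(grid.meta.get("wall_thickness_mm", WALL_THICKNESS_MM))
    myo = grid.mask("myocardium")
    x, y, z = grid.voxel_centers()

    if grid.kind == "antrum":
        r_mid = grid.meta["vein_radius_mm"] + th / 2.0
        circumference = 2.0 * np.pi * r_mid
        if band_length_mm > circumference:
            raise ValueError(
                f"band length {band_length_mm} mm exceeds mid-wall "
                f"circumference {circumference:.1f} mm"
            )
        half_arc = band_length_mm / (2.0 * r_mid)
        theta = np.arctan2(np.broadcast_to(y, grid.shape), np.broadcast_to(x, grid.shape))
        dtheta = np.angle(np.exp(1j * (theta - center_angle_rad)))
        in_band = (np.abs(dtheta) <= half_arc) & (
            np.abs(np.broadcast_to(z, grid.shape) - center_z_mm) <= band_width_mm / 2.0
        )
        mask = myo & in_band
    elif grid.kind == "slab":
        ext = grid.extent_mm
        cx, cy = ext[0] / 2.0, ext[1] / 2.0
        if band_length_mm > ext[0] or band_width_mm > ext[1]:
            raise ValueError("band exceeds slab extent")
        in_band = (np.abs(np.broadcast_to(x, grid.shape) - cx) <= band_length_mm / 2.0) & (
            np.abs(np.broadcast_to(y, grid.shape) - cy) <= band_width_mm / 2.0
        )
        mask = myo & in_band
    else:
        raise ValueError(f"cannot place a target band on phantom kind {grid.kind!r}")

    if not mask.any():
        raise ValueError("target band contains no wall voxels")
    return TargetRegion(mask=mask, nominal_dims_mm=(band_width_mm, band_length_mm, th))


def assign_conductivity(grid: AnatomyGrid, table: ConductivityTable) -> ConductivityField:
    """Map the conductivity table onto the voxel grid.

    Every label present in the grid must have a table entry; the balloon
    insulator receives its configured floor conductivity like any other class.
    """
    present = np.unique(grid.labels)
    sigma0 = np.zeros(grid.shape, dtype=np.float64)
    A = np.zeros(grid.shape, dtype=np.float64)
    e_mid = np.full(grid.shape, 1.0, dtype=np.float64)
    width = np.full(grid.shape, 1.0, dtype=np.float64)
    for code in present:
        name = LABEL_NAMES[int(code)]
        if name not in table.entries:
            raise KeyError(f"conductivity table has no entry for present label {name!r}")
        tc = table.entries[name]
        sel = grid.labels == code
        sigma0[sel] = tc.sigma0
        if tc.nonlinear is not None:
            A[sel] = tc.nonlinear.fold_change
            e_mid[sel] = tc.nonlinear.e_mid_v_per_cm
            width[sel] = tc.nonlinear.width_v_per_cm
    return ConductivityField(sigma0=sigma0, fold_change=A, e_mid_v_per_cm=e_mid, width_v_per_cm=width)


def probe_wall_thickness(
    grid: AnatomyGrid, n_angles: int = 24, z_values_mm: tuple[float, ...] = (-3.0, 0.0, 3.0)
) -> np.ndarray:
    """Wall thickness (mm) sampled along radial normals of the antrum shell.

    Casts rays outward from the axis at the given heights/angles and counts
    contiguous myocardium voxels crossed.  Used by validation tests.
    """
    if grid.kind != "antrum":
        raise ValueError("wall probing is defined for the antrum phantom")
    h = grid.spacing_mm
    out = []
    r_max = grid.extent_mm[0] / 2.0
    radii = np.arange(0.0, r_max, h / 3.0)
    for z in z_values_mm:
        for ang in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            px = radii * np.cos(ang)
            py = radii * np.sin(ang)
            ix = np.floor((px - grid.origin_mm[0]) / h).astype(int)
            iy = np.floor((py - grid.origin_mm[1]) / h).astype(int)
            iz = int((z - grid.origin_mm[2]) / h)
            ok = (ix >= 0) & (ix < grid.shape[0]) & (iy >= 0) & (iy < grid.shape[1])
            lab = grid.labels[ix[ok], iy[ok], np.full(ok.sum(), iz)]
            is_myo = lab == LABELS["myocardium"]
            if not is_myo.any():
                continue
            # contiguous run length along the ray, converted to mm
            first = np.argmax(is_myo)
            run = np.argmin(is_myo[first:]) if not is_myo[first:].all() else is_myo[first:].size
            out.append(run * (h / 3.0))
    return np.asarray(out)
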