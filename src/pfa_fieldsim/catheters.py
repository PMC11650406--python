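"""Voxelized electrode sets and vectoring schemes for the six catheter designs.

Designs
-------
circular
    Decapolar loop: ten 3 mm x 1.6 mm ring electrodes along the band
    circumference, energized once in an interlaced bipolar pattern
    (alternating +/- around the loop).
penta_spline
    Elongated basket of five splines, four 1.3 mm x 3 mm rings each, all
    rings of a spline one electrical node.  Bipolar spline-to-adjacent-spline
    deliveries rotating five times per application; two applications with an
    intervening rotation.
flex_splines / balloon
    Flat-circuit splines (4 mm wide) carrying 3.6 x 3.6 mm plate electrodes
    every 6 mm along the spline, wide-interlaced vectoring (alternating +/-
    with inactive electrodes between), two applications with a rotation.
    The balloon is structurally identical but fills the lumen behind the
    electrode shell with an insulating body.
focal_sphere_9mm
    9 mm Nitinol mesh sphere, flattened to a 6 mm contact disc against the
    wall, monopolar to a distant return patch; applied seven times every
    6 mm along the band.
oneshot_sphere
    Large sphere of six diamond-latticed Nitinol panels in conforming wall
    contact; each panel energized sequentially, monopolar to the patch.

Geometry is rasterized in a band-surface chart: s = circumferential arc
along the endocardial surface, t = position along the vein axis, d = depth
from the endocardial surface into the blood pool (d < 0 is inside the
wall).  On the slab phantom the chart is Cartesian.  Electrode masks are
clipped to blood voxels, which realizes ideal tangential contact with no
tissue displacement.

Multi-placement designs (focal sphere x7; the second, rotated application
of the penta-spline and flex/balloon) are stored in one ElectrodeSet with a
placement index per electrode; masks of different placements may overlap in
space because they are never energized together (each delivery activates a
single placement; all other metal is absent from the solve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import AnatomyGrid, TargetRegion

__all__ = [
    "DESIGNS",
    "MONOPOLAR_DESIGNS",
    "Electrode",
    "ElectrodeSet",
    "Delivery",
    "VectorScheme",
    "DoseSchedule",
    "DOSE_SCHEDULES",
    "build_catheter",
    "make_vector_scheme",
    "electrode_metal_area",
    "default_design_params",
    "oneshot_panel_probe_points",
]

DESIGNS = (
    "circular",
    "penta_spline",
    "flex_splines",
    "balloon",
    "focal_sphere_9mm",
    "oneshot_sphere",
)
MONOPOLAR_DESIGNS = ("focal_sphere_9mm", "oneshot_sphere")

#: Fig-2 deployment accounting: number of on-target vectors per design.
N_VECTORS_ON_TARGET = {
    "oneshot_sphere": 3,
    "focal_sphere_9mm": 7,
    "penta_spline": 6,
    "circular": 3,
    "flex_splines": 8,
    "balloon": 8,
}


@dataclass
class Electrode:
    name: str
    mask: np.ndarray
    metal_area_cm2: float
    center_s_mm: float = 0.0
    center_t_mm: float = 0.0
    placement: int = 0


@dataclass
class ElectrodeSet:
    design: str
    electrodes: list[Electrode]
    return_patch: Electrode | None = None
    insulator_masks: list[np.ndarray] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    frame: "BandFrame | None" = None

    def all_electrodes(self) -> list[Electrode]:
        out = list(self.electrodes)
        if self.return_patch is not None:
            out.append(self.return_patch)
        return out

    def get(self, name: str) -> Electrode:
        for el in self.all_electrodes():
            if el.name == name:
                return el
        raise KeyError(f"no electrode named {name!r}")

    def placements(self) -> list[int]:
        return sorted({el.placement for el in self.electrodes})


@dataclass
class Delivery:
    """One energization: polarity per electrode name, with target accounting."""

    polarity: dict[str, int]
    counted_on_target: bool
    n_vectors: int          # positive electrodes whose center lies on the band
    n_positive: int         # positive electrodes energized simultaneously
    placement: int = 0
    label: str = ""


@dataclass
class VectorScheme:
    design: str
    deliveries: list[Delivery]

    def __post_init__(self) -> None:
        for d in self.deliveries:
            pols = set(d.polarity.values())
            if 1 not in pols or -1 not in pols:
                raise ValueError("each delivery needs both a positive and a negative pole")

    @property
    def counted_deliveries(self) -> list[Delivery]:
        return [d for d in self.deliveries if d.counted_on_target]

    @property
    def n_vectors_on_target(self) -> int:
        return sum(d.n_vectors for d in self.counted_deliveries)


@dataclass(frozen=True)
class DoseSchedule:
    """Clinical dose bookkeeping (applications x deliveries x duration)."""

    n_applications: int
    n_deliveries_per_application: int
    delivery_duration_ms: float

    def __post_init__(self) -> None:
        if min(self.n_applications, self.n_deliveries_per_application) < 0:
            raise ValueError("counts must be non-negative")
        if self.delivery_duration_ms < 0:
            raise ValueError("duration must be non-negative")


#: Published per-PV dose schedules (pivotal-study protocols / live cases).
DOSE_SCHEDULES = {
    "oneshot_sphere": DoseSchedule(4, 30, 150.0),
    "focal_sphere_9mm": DoseSchedule(7, 12, 150.0),
    "penta_spline": DoseSchedule(8, 5, 200.0),
    "circular": DoseSchedule(12, 4, 130.0),
}


# ---------------------------------------------------------------------------
# Band-surface chart
# ---------------------------------------------------------------------------

class BandFrame:
    """Maps voxel centers to band-surface coordinates (s, t, d) in mm."""

    def __init__(self, grid: AnatomyGrid, center_angle_rad: float = 0.0, center_z_mm: float = 0.0):
        self.grid = grid
        self.kind = grid.kind
        x, y, z = grid.voxel_centers()
        if grid.kind == "antrum":
            self.r_surface = float(grid.meta["vein_radius_mm"])
            self.wrap_length = 2.0 * math.pi * self.r_surface
            X = np.broadcast_to(x, grid.shape)
            Y = np.broadcast_to(y, grid.shape)
            Z = np.broadcast_to(z, grid.shape)
            rho = np.sqrt(X**2 + Y**2)
            theta = np.arctan2(Y, X)
            dtheta = np.angle(np.exp(1j * (theta - center_angle_rad)))
            self.S = self.r_surface * dtheta
            self.T = Z - center_z_mm
            self.D = self.r_surface - rho
        elif grid.kind == "slab":
            self.r_surface = None
            self.wrap_length = None
            ext = grid.extent_mm
            wall_top = grid.meta["wall_z_range_mm"][1]
            self.S = np.broadcast_to(x, grid.shape) - ext[0] / 2.0
            self.T = np.broadcast_to(y, grid.shape) - ext[1] / 2.0
            self.D = np.broadcast_to(z, grid.shape) - wall_top
        else:
            raise ValueError(f"no band chart for phantom kind {grid.kind!r}")
        self.blood = grid.mask("blood")

    def ds(self, s_c: float) -> np.ndarray:
        """Signed chart distance along s, wrapped on the antrum."""
        d = self.S - s_c
        if self.wrap_length is not None:
            L = self.wrap_length
            d = (d + L / 2.0) % L - L / 2.0
        return d

    def arc(self, angle_deg: float) -> float:
        """Arc length (mm) at the endocardial surface for an angle, or the
        identity on the slab (angle interpreted at a 10 mm reference radius)."""
        r = self.r_surface if self.r_surface is not None else 10.0
        return math.radians(angle_deg) * r


# ---------------------------------------------------------------------------
# Default design parameters
# ---------------------------------------------------------------------------

def default_design_params(design: str) -> dict:
    """Published dimensions (mm) and layout defaults per design."""
    common = {"patch_size_mm": 50.0}
    per_design = {
        "circular": dict(
            n_electrodes=10, electrode_length_mm=3.0, electrode_diameter_mm=1.6,
            gap_mm=3.7,
        ),
        "penta_spline": dict(
            n_splines=5, rings_per_spline=4, ring_diameter_mm=1.3,
            ring_length_mm=3.0, ring_gaps_mm=(3.0, 3.0, 4.0),
            app_offsets_deg=(12.0, 48.0),
        ),
        "flex_splines": dict(
            n_splines=4, electrode_mm=3.6, electrode_pitch_mm=6.0,
            spline_width_mm=4.0, spline_angles_deg=(-90.0, -30.0, 30.0, 90.0),
            app_rotation_deg=15.0, electrodes_per_spline=5,
        ),
        "balloon": dict(
            n_splines=4, electrode_mm=3.6, electrode_pitch_mm=6.0,
            spline_width_mm=4.0, spline_angles_deg=(-90.0, -30.0, 30.0, 90.0),
            app_rotation_deg=15.0, electrodes_per_spline=5,
            balloon_half_length_mm=10.0,
        ),
        "focal_sphere_9mm": dict(
            sphere_diameter_mm=9.0, flat_cap_diameter_mm=6.0,
            strut_diameter_mm=0.127, n_meridians=8, n_parallels=3,
            n_placements=7, placement_step_mm=6.0,
        ),
        "oneshot_sphere": dict(
            sphere_diameter_mm=30.0, n_panels=6, panel_height_mm=20.0,
            lattice_pitch_mm=5.0, strut_width_mm=0.6, panel_gap_mm=2.0,
        ),
    }
    if design not in per_design:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    return {**common, **per_design[design]}


# ---------------------------------------------------------------------------
# Rasterization primitives (chart coordinates)
# ---------------------------------------------------------------------------

def _clip(frame: BandFrame, member: np.ndarray) -> np.ndarray:
    return member & frame.blood


def _ring_along_s(frame, s_c, t_c, length, dia, h):
    """Ring electrode whose shaft axis runs along s, resting on the wall."""
    r_sh = dia / 2.0
    r_eff = max(r_sh, 0.75 * h)
    ds = frame.ds(s_c)
    member = (np.abs(ds) <= length / 2.0) & (
        (frame.T - t_c) ** 2 + (frame.D - r_sh) ** 2 <= r_eff**2
    )
    return _clip(frame, member)


def _ring_along_t(frame, s_c, t_c, length, dia, h):
    """Ring electrode whose shaft axis runs along t (a basket spline segment)."""
    r_sh = dia / 2.0
    r_eff = max(r_sh, 0.75 * h)
    ds = frame.ds(s_c)
    member = (np.abs(frame.T - t_c) <= length / 2.0) & (
        ds**2 + (frame.D - r_sh) ** 2 <= r_eff**2
    )
    return _clip(frame, member)


def _plate(frame, s_c, t_c, w_s, w_t, h):
    """Flat plate electrode in wall contact, one voxel layer thick."""
    ds = frame.ds(s_c)
    member = (
        (np.abs(ds) <= w_s / 2.0)
        & (np.abs(frame.T - t_c) <= w_t / 2.0)
        & (frame.D >= -0.75 * h)
        & (frame.D <= 0.8 * h)
    )
    return _clip(frame, member)


def _surface_layer(frame, h):
    return (frame.D >= -0.75 * h) & (frame.D <= 0.8 * h)


def _focal_sphere_masks(frame, s_c, t_c, p, h):
    """Flattened mesh sphere: contact disc plus meridian/parallel strut shell."""
    R = p["sphere_diameter_mm"] / 2.0
    a = p["flat_cap_diameter_mm"] / 2.0
    d0 = math.sqrt(max(R**2 - a**2, 0.0))
    ds = frame.ds(s_c)
    dt = frame.T - t_c
    rad2 = ds**2 + dt**2
    cap = (rad2 <= a**2) & _surface_layer(frame, h)

    dist = np.sqrt(rad2 + (frame.D - d0) ** 2)
    w = max(p["strut_diameter_mm"] / 2.0, 0.6 * h)
    shell = (np.abs(dist - R) <= w) & (frame.D > 0.8 * h)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.arccos(np.clip((d0 - frame.D) / np.maximum(dist, 1e-9), -1, 1))
        beta = np.arctan2(dt, ds)
    alpha = math.asin(min(a / R, 1.0))
    n_mer = p["n_meridians"]
    mer_step = 2.0 * math.pi / n_mer
    mer_off = np.abs((beta + mer_step / 2.0) % mer_step - mer_step / 2.0)
    sin_psi = np.maximum(np.sin(psi), 1e-3)
    meridians = mer_off * R * sin_psi <= w
    psi_levels = np.linspace(alpha, 0.85 * math.pi, p["n_parallels"] + 2)[1:-1]
    parallels = np.zeros_like(shell)
    for pl in psi_levels:
        parallels |= np.abs(psi - pl) * R <= w
    mesh = _clip(frame, shell & (meridians | parallels))
    return cap & frame.blood, mesh, (R, a, d0, alpha, psi_levels)


def _focal_sphere_area_cm2(p) -> float:
    """Analytic outer metal area: contact disc + outer half of each strut."""
    R = p["sphere_diameter_mm"] / 2.0
    a = p["flat_cap_diameter_mm"] / 2.0
    alpha = math.asin(min(a / R, 1.0))
    half_circ = math.pi * p["strut_diameter_mm"] / 2.0  # outer half-cylinder, per mm
    mer_len = p["n_meridians"] * R * (math.pi - alpha)
    psi_levels = np.linspace(alpha, 0.85 * math.pi, p["n_parallels"] + 2)[1:-1]
    par_len = float(sum(2.0 * math.pi * R * math.sin(pl) for pl in psi_levels))
    cap_area = math.pi * a**2
    return (cap_area + (mer_len + par_len) * half_circ) / 100.0  # mm^2 -> cm^2


def _panel_lattice(frame, s_c, t_c, width, height, pitch, w_strut, h):
    """Diamond lattice panel: two +-45-degree strut families plus a frame."""
    ds = frame.ds(s_c)
    dt = frame.T - t_c
    u = (ds + dt) / math.sqrt(2.0)
    v = (ds - dt) / math.sqrt(2.0)
    w = max(w_strut / 2.0, 0.6 * h)
    near_u = np.abs((u + pitch / 2.0) % pitch - pitch / 2.0) <= w
    near_v = np.abs((v + pitch / 2.0) % pitch - pitch / 2.0) <= w
    inside = (np.abs(ds) <= width / 2.0) & (np.abs(dt) <= height / 2.0)
    rim = inside & (
        (np.abs(np.abs(ds) - width / 2.0) <= w) | (np.abs(np.abs(dt) - height / 2.0) <= w)
    )
    member = inside & (near_u | near_v | rim) & _surface_layer(frame, h)
    return _clip(frame, member)


def _panel_area_cm2(p, W: float) -> float:
    """Analytic single-face metal area of one diamond panel (overlaps ignored)."""
    H = p["panel_height_mm"]
    g = p["lattice_pitch_mm"]
    w = p["strut_width_mm"]
    # Total +-45-degree line length clipped to a W x H rectangle, both families.
    lat_len = 0.0
    diag = (W + H) / math.sqrt(2.0)
    for k in np.arange(-diag / g, diag / g + 1):
        c = k * g  # line u = c (and by symmetry v = c)
        # Intersection length of the line s + t = c*sqrt(2) with the rectangle.
        lo = max(-W / 2.0, c * math.sqrt(2.0) - H / 2.0)
        hi = min(W / 2.0, c * math.sqrt(2.0) + H / 2.0)
        if hi > lo:
            lat_len += 2.0 * (hi - lo) * math.sqrt(2.0)  # both families
    rim_len = 2.0 * (W + H)
    return ((lat_len + rim_len) * w) / 100.0


def oneshot_panel_probe_points(params: dict | None = None) -> dict[str, tuple[float, float]]:
    """Chart (s, t) of a strut crossing and the adjacent diamond-opening center.

    Used by field-structure tests: the opening center sits mid-diamond, the
    crossing at a lattice node of the centered panel.
    """
    p = {**default_design_params("oneshot_sphere"), **(params or {})}
    g = p["lattice_pitch_mm"]
    crossing = (0.0, 0.0)
    center = (g / math.sqrt(2.0), 0.0)  # u = v = g/2
    return {"strut_crossing": crossing, "opening_center": center}


# ---------------------------------------------------------------------------
# Catheter builders
# ---------------------------------------------------------------------------

def _return_patch(grid: AnatomyGrid, size_mm: float) -> Electrode:
    """Grounded skin patch on the boundary face farthest from the target."""
    mask = np.zeros(grid.shape, dtype=bool)
    x, y, z = grid.voxel_centers()
    half = size_mm / 2.0
    if grid.kind == "antrum":
        # target faces +x; patch on the -x boundary face
        Y = np.broadcast_to(y, grid.shape)[0]
        Z = np.broadcast_to(z, grid.shape)[0]
        mask[0] = (np.abs(Y) <= half) & (np.abs(Z) <= half)
    else:
        ext = grid.extent_mm
        X = np.broadcast_to(x, grid.shape)[:, :, 0]
        Y = np.broadcast_to(y, grid.shape)[:, :, 0]
        mask[:, :, 0] = (np.abs(X - ext[0] / 2.0) <= half) & (np.abs(Y - ext[1] / 2.0) <= half)
    area = (size_mm / 10.0) ** 2
    return Electrode(name="return_patch", mask=mask, metal_area_cm2=area)


def _check_separation(electrodes: list[Electrode], placement: int) -> None:
    """Co-deployed electrodes must not touch (>= 1 blood voxel between)."""
    group = [el for el in electrodes if el.placement == placement]
    for i, a in enumerate(group):
        grown = ndimage.binary_dilation(a.mask)
        for b in group[i + 1 :]:
            if (grown & b.mask).any():
                raise ValueError(
                    f"electrodes {a.name!r} and {b.name!r} are not separated "
                    "by at least one blood voxel at this grid spacing"
                )


def build_catheter(
    design: str,
    grid: AnatomyGrid,
    target: TargetRegion,
    params: dict | None = None,
) -> ElectrodeSet:
    """Rasterize a catheter design in ideal tangential contact over the target.

    ``target`` fixes the band the layout is centered on; the published
    dimensions are the parameter defaults.  Raises if the footprint does not
    fit the phantom or the spacing cannot separate adjacent electrodes.
    """
    p = {**default_design_params(design), **(params or {})}
    band_w, band_len, _ = target.nominal_dims_mm
    frame = BandFrame(grid)
    h = grid.spacing_mm
    els: list[Electrode] = []
    insulators: list[np.ndarray] = []

    if design == "circular":
        dia = p["electrode_diameter_mm"]
        length = p["electrode_length_mm"]
        n = p["n_electrodes"]
        area = math.pi * (dia / 10.0) * (length / 10.0)
        for k in range(n):
            if frame.wrap_length is not None:
                # closed loop around the lumen: pitch compressed from the
                # nominal 3.7 mm edge-to-edge gap to fit the circumference
                ang = (k * 360.0 / n + 180.0) % 360.0 - 180.0
                s_c = frame.arc(ang)
            else:
                s_c = (k - (n - 1) / 2.0) * (length + p["gap_mm"])
            mask = _ring_along_s(frame, s_c, 0.0, length, dia, h)
            els.append(Electrode(f"ring{k}", mask, area, center_s_mm=s_c))

    elif design == "penta_spline":
        dia = p["ring_diameter_mm"]
        length = p["ring_length_mm"]
        gaps = p["ring_gaps_mm"]
        ring_area = math.pi * (dia / 10.0) * (length / 10.0)
        # axial ring centers from the stated lengths/gaps, centered on the band
        edges = [0.0]
        for g in gaps:
            edges.append(edges[-1] + length + g)
        span = edges[-1] + length
        t_centers = [e + length / 2.0 - span / 2.0 for e in edges]
        n_spl = p["n_splines"]
        for app, off in enumerate(p["app_offsets_deg"]):
            for j in range(n_spl):
                ang = off + j * 360.0 / n_spl
                s_c = frame.arc((ang + 180.0) % 360.0 - 180.0)
                mask = np.zeros(grid.shape, dtype=bool)
                for t_c in t_centers:
                    mask |= _ring_along_t(frame, s_c, t_c, length, dia, h)
                els.append(
                    Electrode(
                        f"app{app}_spline{j}", mask, len(t_centers) * ring_area,
                        center_s_mm=s_c, placement=app,
                    )
                )

    elif design in ("flex_splines", "balloon"):
        e = p["electrode_mm"]
        pitch = p["electrode_pitch_mm"]
        n_per = p["electrodes_per_spline"]
        area = (e / 10.0) ** 2
        for app in range(2):
            rot = 0.0 if app == 0 else p["app_rotation_deg"]
            for j, ang in enumerate(p["spline_angles_deg"]):
                s_c = frame.arc(ang + rot)
                for m in range(n_per):
                    t_c = (m - (n_per - 1) / 2.0) * pitch
                    mask = _plate(frame, s_c, t_c, e, e, h)
                    els.append(
                        Electrode(
                            f"app{app}_spline{j}_e{m}", mask, area,
                            center_s_mm=s_c, center_t_mm=t_c, placement=app,
                        )
                    )
        if design == "balloon":
            half_len = p["balloon_half_length_mm"]
            body = frame.blood & (np.abs(frame.T) <= half_len) & (frame.D >= -0.75 * h)
            if frame.wrap_length is None:
                body &= np.abs(frame.S) <= band_len / 2.0 + 5.0
            for el in els:
                body &= ~el.mask
            insulators.append(body)

    elif design == "focal_sphere_9mm":
        step = p["placement_step_mm"]
        n_pl = p["n_placements"]
        area = _focal_sphere_area_cm2(p)
        for k in range(n_pl):
            s_c = (k - (n_pl - 1) / 2.0) * step
            cap, mesh, _ = _focal_sphere_masks(frame, s_c, 0.0, p, h)
            mask = cap | mesh
            els.append(Electrode(f"sphere{k}", mask, area, center_s_mm=s_c, placement=k))

    elif design == "oneshot_sphere":
        n_pan = p["n_panels"]
        gore_step = 360.0 / n_pan
        # panel width from its gore arc at the contact surface, minus the
        # insulating joint between adjacent panels
        W = frame.arc(gore_step) - p.get("panel_gap_mm", 2.0)
        area = _panel_area_cm2(p, W)
        for k in range(n_pan):
            if grid.kind == "slab" and k > 0:
                continue  # a single centered panel on the validation slab
            ang = (k * gore_step + 180.0) % 360.0 - 180.0
            s_c = frame.arc(ang)
            mask = _panel_lattice(
                frame, s_c, 0.0, W, p["panel_height_mm"], p["lattice_pitch_mm"],
                p["strut_width_mm"], h,
            )
            els.append(Electrode(f"panel{k}", mask, area, center_s_mm=s_c))

    else:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")

    myo = grid.mask("myocardium")
    for el in els:
        if not el.mask.any():
            raise ValueError(
                f"electrode {el.name!r} rasterized to an empty mask: the design "
                "footprint does not fit this phantom at this spacing"
            )
        if (el.mask & myo).any():  # pragma: no cover - guarded by blood clipping
            raise AssertionError("electrode mask overlaps myocardium")

    patch = _return_patch(grid, p["patch_size_mm"]) if design in MONOPOLAR_DESIGNS else None
    eset = ElectrodeSet(
        design=design, electrodes=els, return_patch=patch,
        insulator_masks=insulators, params=p, frame=frame,
    )
    for pl in eset.placements():
        _check_separation(els, pl)
    return eset


# ---------------------------------------------------------------------------
# Vectoring
# ---------------------------------------------------------------------------

#: A positive electrode is "on target" when its center lies inside the band
#: footprint by at least this inset (mm of arc / axial slack).
_BAND_INSET_MM = 0.2
_T_MARGIN_MM = 0.5


def _on_band(el: Electrode, frame: BandFrame, band_len: float, band_w: float) -> bool:
    if frame.r_surface is not None:
        r_mid = frame.r_surface + 1.25  # mid-wall radius for a 2.5 mm wall
        s_half = (band_len / 2.0) * frame.r_surface / r_mid
    else:
        s_half = band_len / 2.0
    return (
        abs(el.center_s_mm) <= s_half - _BAND_INSET_MM
        and abs(el.center_t_mm) <= band_w / 2.0 + _T_MARGIN_MM
    )


def make_vector_scheme(
    electrodes: ElectrodeSet,
    band_length_mm: float = 47.0,
    band_width_mm: float = 6.0,
) -> VectorScheme:
    """Delivery sequence with polarity assignments for a built catheter.

    Target accounting follows the ideal-deployment convention: only energy
    delivered by near-target electrodes is counted, so a delivery is flagged
    ``counted_on_target`` when at least one of its positive electrodes sits
    on the band, and its vector count is the number of such electrodes.
    """
    design = electrodes.design
    frame = electrodes.frame
    deliveries: list[Delivery] = []

    def on_band(el):
        return _on_band(el, frame, band_length_mm, band_width_mm)

    if design == "circular":
        pol = {}
        n_pos = 0
        n_on = 0
        for k, el in enumerate(electrodes.electrodes):
            pol[el.name] = 1 if k % 2 == 0 else -1
            if k % 2 == 0:
                n_pos += 1
                n_on += on_band(el)
        deliveries.append(Delivery(pol, n_on > 0, n_on, n_pos, label="interlaced"))

    elif design == "penta_spline":
        n_spl = electrodes.params["n_splines"]
        for app in electrodes.placements():
            spl = [electrodes.get(f"app{app}_spline{j}") for j in range(n_spl)]
            for j in range(n_spl):
                pos, neg = spl[j], spl[(j + 1) % n_spl]
                pol = {pos.name: 1, neg.name: -1}
                counted = on_band(pos)
                deliveries.append(
                    Delivery(pol, counted, int(counted), 1, placement=app,
                             label=f"app{app}_bipole{j}")
                )

    elif design in ("flex_splines", "balloon"):
        n_per = electrodes.params["electrodes_per_spline"]
        angles = electrodes.params["spline_angles_deg"]
        mid = (n_per - 1) // 2
        for app in electrodes.placements():
            # wide-interlaced: even axial positions active alternately +/-,
            # odd positions inactive; second delivery uses the odd positions
            for phase, lbl in ((0, "even"), (1, "odd")):
                pol = {}
                n_pos = n_on = 0
                for j in range(len(angles)):
                    for m in range(n_per):
                        el = electrodes.get(f"app{app}_spline{j}_e{m}")
                        if (m - phase) % 2 != 0:
                            continue
                        # band-center electrode positive, alternating axially
                        sign = 1 if ((m - phase) // 2 + mid) % 2 == 1 else -1
                        pol[el.name] = sign
                        if sign > 0:
                            n_pos += 1
                            n_on += on_band(el)
                deliveries.append(
                    Delivery(pol, n_on > 0, n_on, n_pos, placement=app,
                             label=f"app{app}_{lbl}")
                )

    elif design in MONOPOLAR_DESIGNS:
        patch = electrodes.return_patch
        for el in electrodes.electrodes:
            counted = on_band(el)
            deliveries.append(
                Delivery({el.name: 1, patch.name: -1}, counted, int(counted), 1,
                         placement=el.placement, label=el.name)
            )

    else:
        raise ValueError(f"unknown design {design!r}")

    return VectorScheme(design=design, deliveries=deliveries)


def electrode_metal_area(design: str, electrodes: ElectrodeSet) -> float:
    """ECD-denominator metal area (cm^2) per the per-design convention.

    Monopolar spheres use the whole cage (focal, outer surfaces only) or a
    single diamond panel (oneshot); the penta-spline uses the total electrode
    area of one spline; all other designs use a single electrode.
    """
    if design != electrodes.design:
        raise ValueError("design does not match the built electrode set")
    return electrodes.electrodes[0].metal_area_cm2
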