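"""Static volume-conductor solver on the voxel grid.

Solves the electro-quasistatic problem div(sigma(|grad phi|) grad phi) = 0
for one energy delivery: Dirichlet potentials on the active electrode
voxels, insulating (zero normal current) outer boundaries, and a
finite-volume 7-point discretization with harmonic face-conductivity
averaging.  Field-dependent conductivity is handled by under-relaxed Picard
iteration; the prescribed per-delivery current is met exactly by scaling in
the linear case and by secant iteration on the applied voltage otherwise.

Internally SI units (V, m, S/m, A, W); electric-field magnitudes are
reported in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .anatomy import (
    INSULATOR_SIGMA,
    AnatomyGrid,
    ConductivityField,
    NonlinearConductivityModel,
)

__all__ = [
    "SolverOptions",
    "FieldSolution",
    "sigma_of_E",
    "conductivity_at_field",
    "solve_delivery",
    "compute_current",
    "SolverConvergenceError",
]

#: Unknown-count threshold below which a sparse direct factorization is used
#: instead of preconditioned conjugate gradients.
_DIRECT_SOLVE_MAX_UNKNOWNS = 40_000


class SolverConvergenceError(RuntimeError):
    """Raised when the Picard or current iteration fails to converge."""

    def __init__(self, message: str, history: list | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class SolverOptions:
    linear_tolerance: float = 1e-8     # relative residual of each linear solve
    picard_tolerance: float = 5e-3     # max relative sigma change at convergence
    max_picard_iters: int = 50
    current_tolerance: float = 1e-3    # relative error on the prescribed current
    max_current_iters: int = 30
    relaxation: float = 0.7            # Picard under-relaxation factor

    def __post_init__(self) -> None:
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation must lie in (0, 1]")
        for name in ("linear_tolerance", "picard_tolerance", "current_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FieldSolution:
    """Converged potential and derived field maps for one delivery."""

    potential: np.ndarray          # V, Dirichlet values filled in
    e_mag: np.ndarray              # V/cm, cell-centered
    power_density: np.ndarray      # W per voxel, face-flux attributed
    sigma: np.ndarray              # S/m, effective conductivity at convergence
    applied_voltage: float         # total inter-electrode voltage
    achieved_current: float        # A through the positive electrode group
    iterations: int                # total linear solves performed
    residual: float                # relative linear residual of the last solve
    dirichlet_mask: np.ndarray = field(repr=False, default=None)
    #: max relative sigma change per Picard step, one sequence per voltage probe
    picard_sigma_changes: list = field(default_factory=list)

    @property
    def total_power(self) -> float:
        """Delivered Joule power I*V (W)."""
        return float(self.applied_voltage * self.achieved_current)

    def current_density(self) -> np.ndarray:
        """Cell-centered |J| in A/cm^2."""
        return self.sigma * self.e_mag * 100.0 / 1e4  # sigma*E[V/m] / (1e4 cm^2/m^2)


def sigma_of_E(model: NonlinearConductivityModel, e_v_per_cm) -> np.ndarray:
    """Sigmoid field-dependent conductivity sigma(|E|), S/m.

    Monotone between sigma0 (low field) and sigma0*(1+A) (high field), with
    midpoint E_mid and logistic width k, all in V/cm.
    """
    E = np.asarray(e_v_per_cm, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    arg = np.clip((E - model.e_mid_v_per_cm) / model.width_v_per_cm, -60.0, 60.0)
    out = model.sigma0 * (1.0 + model.fold_change / (1.0 + np.exp(-arg)))
    return out if out.shape else float(out)


def conductivity_at_field(cond: ConductivityField, e_mag_v_per_cm: np.ndarray) -> np.ndarray:
    """Per-voxel sigma(|E|) from the field's sigmoid parameter maps."""
    arg = np.clip(
        (e_mag_v_per_cm - cond.e_mid_v_per_cm) / cond.width_v_per_cm, -60.0, 60.0
    )
    return cond.sigma0 * (1.0 + cond.fold_change / (1.0 + np.exp(-arg)))


# ---------------------------------------------------------------------------
# Discrete operator
# ---------------------------------------------------------------------------

def _face_conductance(sigma: np.ndarray, axis: int, h_m: float) -> np.ndarray:
    """Harmonic-mean face conductance (S) between neighbors along one axis."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    sa = sigma[tuple(sl_a)]
    sb = sigma[tuple(sl_b)]
    return (2.0 * sa * sb / (sa + sb)) * h_m


def _assemble(sigma, dirichlet_mask, dirichlet_vals, h_m):
    """Build the SPD finite-volume system over non-Dirichlet voxels."""
    shape = sigma.shape
    idx = -np.ones(shape, dtype=np.int64)
    free = ~dirichlet_mask
    n = int(free.sum())
    idx[free] = np.arange(n)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows, cols, vals = [], [], []
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ia = idx[tuple(sl_a)].ravel()
        ib = idx[tuple(sl_b)].ravel()
        gf = g.ravel()
        va = dirichlet_vals[tuple(sl_a)].ravel()
        vb = dirichlet_vals[tuple(sl_b)].ravel()
        both = (ia >= 0) & (ib >= 0)
        rows.append(ia[both]); cols.append(ib[both]); vals.append(-gf[both])
        rows.append(ib[both]); cols.append(ia[both]); vals.append(-gf[both])
        np.add.at(diag, ia[both], gf[both])
        np.add.at(diag, ib[both], gf[both])
        a_free = (ia >= 0) & (ib < 0)
        np.add.at(diag, ia[a_free], gf[a_free])
        np.add.at(rhs, ia[a_free], gf[a_free] * vb[a_free])
        b_free = (ib >= 0) & (ia < 0)
        np.add.at(diag, ib[b_free], gf[b_free])
        np.add.at(rhs, ib[b_free], gf[b_free] * va[b_free])
    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return A, rhs, idx


def _solve_linear_system(A, b, tol, x0=None):
    """Solve the SPD system; sparse Cholesky-like direct factorization for
    moderate sizes, Jacobi-preconditioned conjugate gradients beyond."""
    n = A.shape[0]
    if n <= _DIRECT_SOLVE_MAX_UNKNOWNS:
        x = spla.splu(A.tocsc()).solve(b)
    else:
        d_inv = 1.0 / A.diagonal()
        M = spla.LinearOperator(A.shape, lambda v: d_inv * v)
        x, info = spla.cg(A, b, x0=x0, rtol=tol, maxiter=50_000, M=M)
        if info != 0:
            raise SolverConvergenceError(f"CG failed to converge (info={info})")
    bn = np.linalg.norm(b)
    res = float(np.linalg.norm(A @ x - b) / bn) if bn > 0 else 0.0
    return x, res


def _fill_potential(idx, x, dirichlet_vals):
    phi = dirichlet_vals.copy()
    phi[idx >= 0] = x[idx[idx >= 0]]
    return phi


def _e_mag_v_per_cm(phi: np.ndarray, h_m: float) -> np.ndarray:
    gx, gy, gz = np.gradient(phi, h_m)
    return np.sqrt(gx**2 + gy**2 + gz**2) / 100.0


def _face_power_and_currents(phi, sigma, dirichlet_mask, electrode_ids, h_m):
    """Face-flux power attribution and net current per Dirichlet electrode id.

    Returns (power_per_voxel W, currents dict id -> A).  Faces joining two
    Dirichlet voxels are skipped: within one electrode the potential jump is
    zero, and distinct electrodes are kept separated by construction.
    """
    power = np.zeros_like(phi)
    currents: dict[int, float] = {int(i): 0.0 for i in np.unique(electrode_ids) if i >= 0}
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pa = phi[tuple(sl_a)]
        pb = phi[tuple(sl_b)]
        da = dirichlet_mask[tuple(sl_a)]
        db = dirichlet_mask[tuple(sl_b)]
        active = ~(da & db)
        dphi = np.where(active, pa - pb, 0.0)
        p_face = g * dphi**2
        power[tuple(sl_a)] += 0.5 * p_face
        power[tuple(sl_b)] += 0.5 * p_face
        ea = electrode_ids[tuple(sl_a)]
        eb = electrode_ids[tuple(sl_b)]
        flux = g * dphi
        sel = da & ~db
        for i in currents:
            currents[i] += float(flux[sel & (ea == i)].sum())
        sel = db & ~da
        for i in currents:
            currents[i] -= float(flux[sel & (eb == i)].sum())
    return power, currents


# ---------------------------------------------------------------------------
# Delivery solve
# ---------------------------------------------------------------------------

def _dirichlet_setup(grid, electrodes, delivery):
    """Dirichlet mask, unit-voltage value map, and electrode id map."""
    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    vals = np.zeros(shape, dtype=np.float64)
    ids = -np.ones(shape, dtype=np.int32)
    pos_names, neg_names = [], []
    for i, el in enumerate(electrodes.all_electrodes()):
        pol = delivery.polarity.get(el.name, 0)
        if pol == 0:
            continue
        if mask[el.mask].any():
            raise ValueError(f"electrode {el.name!r} overlaps another active electrode")
        mask |= el.mask
        vals[el.mask] = 0.5 * pol
        ids[el.mask] = i
        (pos_names if pol > 0 else neg_names).append(el.name)
    if not pos_names or not neg_names:
        raise ValueError("delivery must have at least one positive and one negative electrode")
    return mask, vals, ids, pos_names, neg_names


def _effective_sigma0(grid, cond, electrodes) -> np.ndarray:
    """Baseline sigma map with insulator bodies (balloon) overridden."""
    sigma = cond.sigma0.copy()
    for ins in electrodes.insulator_masks:
        sigma[ins] = INSULATOR_SIGMA
    return sigma


def solve_delivery(
    grid: AnatomyGrid,
    cond: ConductivityField,
    electrodes,
    delivery,
    target_current: float,
    opts: SolverOptions = SolverOptions(),
) -> FieldSolution:
    """Solve one energy delivery driven to a prescribed total current.

    ``target_current`` is the net current through the positive electrode
    group (A).  With purely linear conductivity a single unit-voltage solve
    is scaled exactly; otherwise a secant iteration on the applied voltage
    wraps the Picard loop for sigma(|E|).
    """
    if target_current <= 0:
        raise ValueError("target_current must be positive")
    h_m = grid.spacing_mm * 1e-3
    dir_mask, unit_vals, ids, pos_names, _ = _dirichlet_setup(grid, electrodes, delivery)
    nonlinear_sel = cond.fold_change != 0.0
    linear = not bool(nonlinear_sel.any())

    def run_linear(sigma, voltage, x0=None):
        vals = unit_vals * voltage
        A, b, idx = _assemble(sigma, dir_mask, vals, h_m)
        x, res = _solve_linear_system(A, b, opts.linear_tolerance, x0=x0)
        phi = _fill_potential(idx, x, vals)
        return phi, res

    def positive_current(phi, sigma):
        _, cur = _face_power_and_currents(phi, sigma, dir_mask, ids, h_m)
        total = 0.0
        for i, el in enumerate(electrodes.all_electrodes()):
            if el.name in pos_names and i in cur:
                total += cur[i]
        return total

    n_solves = 0
    picard_changes: list[float] = []
    if linear:
        sigma = _effective_sigma0(grid, cond, electrodes)
        phi1, res = run_linear(sigma, 1.0)
        n_solves += 1
        i1 = positive_current(phi1, sigma)
        scale = target_current / i1
        phi = phi1 * scale
        voltage = scale
        current = target_current
    else:
        sigma = _effective_sigma0(grid, cond, electrodes)
        # start from the linear scaling estimate
        phi0, res = run_linear(sigma, 1.0)
        n_solves += 1
        i0 = positive_current(phi0, sigma)
        voltage = target_current / i0
        v_prev, i_prev = None, None
        phi = phi0 * voltage
        for k_outer in range(opts.max_current_iters):
            # Picard loop at fixed applied voltage
            seq: list[float] = []
            picard_changes.append(seq)
            for k_pic in range(opts.max_picard_iters):
                e_mag = _e_mag_v_per_cm(phi, h_m)
                sigma_new = conductivity_at_field(cond, e_mag)
                sigma_new[~nonlinear_sel] = sigma[~nonlinear_sel]
                sigma_upd = sigma + opts.relaxation * (sigma_new - sigma)
                for ins in electrodes.insulator_masks:
                    sigma_upd[ins] = INSULATOR_SIGMA
                change = float(np.max(np.abs(sigma_upd - sigma) / sigma))
                seq.append(change)
                sigma = sigma_upd
                if change < opts.picard_tolerance and k_pic > 0:
                    break
                phi, res = run_linear(sigma, voltage)
                n_solves += 1
            else:
                raise SolverConvergenceError(
                    f"Picard iteration did not converge within {opts.max_picard_iters} steps"
                )
            current = positive_current(phi, sigma)
            err = (current - target_current) / target_current
            if abs(err) < opts.current_tolerance:
                break
            if v_prev is None or current == i_prev:
                v_next = voltage * target_current / current
            else:
                v_next = voltage - (current - target_current) * (voltage - v_prev) / (
                    current - i_prev
                )
            v_prev, i_prev = voltage, current
            voltage = v_next
            phi, res = run_linear(sigma, voltage)
            n_solves += 1
        else:
            raise SolverConvergenceError(
                f"current iteration did not reach {target_current} A within "
                f"{opts.max_current_iters} secant steps"
            )

    e_mag = _e_mag_v_per_cm(phi, h_m)
    power, currents = _face_power_and_currents(phi, sigma, dir_mask, ids, h_m)
    achieved = positive_current(phi, sigma)
    return FieldSolution(
        potential=phi,
        e_mag=e_mag,
        power_density=power,
        sigma=sigma,
        applied_voltage=float(voltage),
        achieved_current=float(achieved),
        iterations=n_solves,
        residual=res,
        dirichlet_mask=dir_mask,
        picard_sigma_changes=picard_changes,
    )


def compute_current(sol: FieldSolution, electrodes, name: str, grid: AnatomyGrid) -> float:
    """Net outward current (A) through the faces surrounding one electrode.

    For an electrode that was not driven (no Dirichlet values) the discrete
    divergence-free interior makes the net flux vanish, which is the
    floating-conductor-as-no-op approximation this solver adopts.
    """
    el = electrodes.get(name)
    h_m = grid.spacing_mm * 1e-3
    phi, sigma = sol.potential, sol.sigma
    total = 0.0
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ma = el.mask[tuple(sl_a)]
        mb = el.mask[tuple(sl_b)]
        dphi = phi[tuple(sl_a)] - phi[tuple(sl_b)]
        sel = ma & ~mb
        total += float((g * dphi)[sel].sum())
        sel = mb & ~ma
        total -= float((g * dphi)[sel].sum())
    return total
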