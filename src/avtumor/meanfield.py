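"""Mean-field PDE tumor model on the shared lattice.

Deterministic counterpart of the stochastic lattice model: a cell density
ρ ∈ [0, 1] is advected by the Darcy velocity −∇p and grows/dies at the
oxygen-thresholded regional rates

    Γ = μ_prol ρ  (c >= κ_prol),   0  (quiescent),   −μ_death ρ  (c < κ_death).

The tumor domain is the sharp interface ρ >= 0.5, which keeps the pressure
problem and the boundary condition p = p_ext − σC identical in form to the
stochastic model's (grid-identical comparisons).  Time stepping is explicit
Euler with first-order conservative upwind advection under a CFL safety
factor of 0.5; optional zero-mean Gaussian noise of amplitude
``noise_amp·sqrt(dt)`` is injected on interface nodes to emulate the
process noise of the stochastic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ModelParams, ScalarField, solve_oxygen, solve_pressure
from .grid import LatticeGrid, extract_boundary

__all__ = ["DensityState", "growth_source", "step_density", "run_pde"]


@dataclass
class DensityState:
    """Cell density field at time t."""

    rho: np.ndarray  # (n, n) float in [0, 1]
    grid: LatticeGrid
    t: float = 0.0

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if (self.rho < -1e-12).any() or (self.rho > 1 + 1e-12).any():
            raise ValueError("density must lie in [0, 1]")
        self.rho = np.clip(self.rho, 0.0, 1.0)
        self.rho[~self.grid.mask] = 0.0

    @property
    def tumor_mask(self) -> np.ndarray:
        """Region enclosed by the ρ = 0.5 interface.

        Interior holes (necrotic regions whose density has been consumed)
        remain part of the tumor domain: they are enclosed by the rim and
        are not ambient medium.
        """
        from scipy.ndimage import binary_fill_holes

        return binary_fill_holes(self.rho >= 0.5) & self.grid.mask

    def copy(self) -> "DensityState":
        return DensityState(self.rho.copy(), self.grid, self.t)


def interface_contour(rho: np.ndarray, grid: LatticeGrid, blur: float = 1.0):
    """Tumor interface from a lightly smoothed density field."""
    return extract_boundary(rho, grid, blur=blur)


def growth_source(state: DensityState, c: ScalarField,
                  params: ModelParams) -> np.ndarray:
    """Regional growth/death source Γ (units: density per cell cycle)."""
    cv = c.values
    gamma = np.zeros_like(state.rho)
    clamped = (c.clamped if c.clamped is not None
               else np.zeros(cv.shape, dtype=bool))
    nec = (cv < params.kappa_death) | clamped
    prol = (cv >= params.kappa_prol) & ~nec
    gamma[prol] = params.mu_prol * state.rho[prol]
    gamma[nec] = -params.mu_death * state.rho[nec]
    gamma[~state.grid.mask] = 0.0
    return gamma


def _face_velocities(p: ScalarField, tumor: np.ndarray, h: float):
    """Darcy velocities on x- and y-faces, nonzero only on faces touching
    the tumor where both pressure values are available."""
    pv = p.values
    with np.errstate(invalid="ignore"):
        vx = -(pv[1:, :] - pv[:-1, :]) / h  # velocity at face between (i,i+1)
        vy = -(pv[:, 1:] - pv[:, :-1]) / h
    vx = np.where(np.isfinite(vx), vx, 0.0)
    vy = np.where(np.isfinite(vy), vy, 0.0)
    return vx, vy


def step_density(
    state: DensityState,
    p: ScalarField,
    gamma: np.ndarray,
    dt: float,
    noise_amp: float = 0.0,
    rng: np.random.Generator | None = None,
    cfl: float = 0.5,
) -> DensityState:
    """One conservative upwind advection + growth step.

    Raises if dt violates the advective CFL bound (the error message
    carries the largest admissible step).
    """
    h = state.grid.h
    vx, vy = _face_velocities(p, state.tumor_mask, h)
    vmax = max(np.abs(vx).max(), np.abs(vy).max(), 1e-300)
    dt_max = cfl * h / vmax
    if dt > dt_max * (1 + 1e-9):
        raise ValueError(f"CFL violation: dt={dt:.3e} exceeds {dt_max:.3e}")

    rho = state.rho
    # upwind face fluxes F = v * rho_upwind
    fx = np.where(vx > 0, vx * rho[:-1, :], vx * rho[1:, :])
    fy = np.where(vy > 0, vy * rho[:, :-1], vy * rho[:, 1:])
    div = np.zeros_like(rho)
    div[:-1, :] += fx / h   # flux leaving cell i through +x face
    div[1:, :] -= fx / h    # flux entering cell i+1
    div[:, :-1] += fy / h
    div[:, 1:] -= fy / h

    new = rho - dt * div + dt * gamma
    if noise_amp > 0.0:
        if rng is None:
            raise ValueError("noise injection requires an rng")
        interface = (rho > 0.05) & (rho < 0.95) & state.grid.mask
        noise = np.zeros_like(rho)
        noise[interface] = rng.normal(0.0, noise_amp * np.sqrt(dt),
                                      int(interface.sum()))
        new = new + noise
    new = np.clip(new, 0.0, 1.0)
    new[~state.grid.mask] = 0.0
    return DensityState(new, state.grid, state.t + dt)


def _summarize(state: DensityState, c: ScalarField, params: ModelParams,
               k_max: int = 0) -> dict:
    from . import morphology

    rec = {"t": state.t, "mass": float(state.rho.sum() * state.grid.h**2)}
    vp, vq, vn = morphology.region_volumes(state.rho, c, params, state.grid,
                                           density=True)
    rec.update(V_p=vp, V_q=vq, V_n=vn)
    try:
        contour = interface_contour(state.rho, state.grid)
        rec["roundness"] = morphology.roundness_of(contour)
        rec["split_flag"] = contour.flagged
    except ValueError:
        rec["roundness"] = np.nan
        rec["split_flag"] = False
        contour = None
    X, Y = state.grid.coords()
    tot = state.rho.sum()
    rec["com_x"] = float((X * state.rho).sum() / tot) if tot else np.nan
    rec["com_y"] = float((Y * state.rho).sum() / tot) if tot else np.nan
    if k_max and contour is not None and not contour.flagged:
        try:
            alphas, _ = morphology.boundary_modes(contour, k_max)
            for k in range(1, k_max + 1):
                rec[f"alpha_{k}"] = alphas[k - 1]
        except ValueError:
            pass
    return rec


def run_pde(
    initial: DensityState,
    params: ModelParams,
    t_end: float,
    seed: int | None = None,
    noise_amp: float = 1e-3,
    record_times: np.ndarray | None = None,
    record_modes: int = 0,
    snapshot_times: np.ndarray | None = None,
    dt_max: float = 0.05,
    freeze_growth: bool = False,
) -> dict:
    """Advance the mean-field model to t_end.

    Per step: mean-field oxygen fixed point -> regional source Γ -> pressure
    solve with the Young-Laplace rim condition -> CFL-limited upwind density
    step (plus interface noise when ``noise_amp > 0``; ``seed`` is then
    required).  ``freeze_growth=True`` forces Γ = 0 (mass-conservation
    checks).  Terminates early, flagged, if the tumor domain vanishes.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    if noise_amp > 0.0 and rng is None:
        raise ValueError("noise_amp > 0 requires a seed")
    state = initial.copy()
    grid = state.grid
    if record_times is None:
        record_times = np.linspace(state.t, t_end, 21)
    record_times = np.asarray(record_times, dtype=float)
    snapshot_times = (np.asarray(snapshot_times, dtype=float)
                      if snapshot_times is not None else np.empty(0))

    records: list[dict] = []
    snapshots: list[tuple[float, np.ndarray]] = []
    i_rec = i_snap = 0
    vanished = False
    prev_clamped = None

    def emit(c):
        nonlocal i_rec, i_snap
        while i_rec < len(record_times) and record_times[i_rec] <= state.t + 1e-9:
            saved = state.t
            state.t = record_times[i_rec]
            records.append(_summarize(state, c, params, record_modes))
            state.t = saved
            i_rec += 1
        while i_snap < len(snapshot_times) and snapshot_times[i_snap] <= state.t + 1e-9:
            snapshots.append((float(snapshot_times[i_snap]), state.rho.copy()))
            i_snap += 1

    n_steps = 0
    breakdown = False
    while state.t < t_end - 1e-12:
        tumor = state.tumor_mask
        if not tumor.any():
            vanished = True
            break
        if (tumor & grid.boundary_mask()).any():
            breakdown = True  # tumor reached the oxygen source: avascularity lost
            break
        c = solve_oxygen(state.rho, grid, params, mean_field=True,
                         clamped_init=prev_clamped)
        prev_clamped = c.clamped
        emit(c)
        # growth acts on the tumor domain only; stray sub-threshold density
        # outside the rim is inert debris of the sharp-interface picture
        gamma = np.where(tumor, growth_source(state, c, params), 0.0)
        if freeze_growth:
            gamma = np.zeros_like(gamma)
        # pressure source Γ/ρ is regionally constant (1, 0, or -mu_death)
        # and is applied on the whole labeled region: with the matching
        # velocity divergence, density is transported unchanged along
        # streamlines and stays near 1 inside the tumor
        src = np.zeros_like(gamma)
        if not freeze_growth:
            cv = c.values
            clamped = (c.clamped if c.clamped is not None
                       else np.zeros(cv.shape, dtype=bool))
            nec = tumor & ((cv < params.kappa_death) | clamped)
            src[tumor & (cv >= params.kappa_prol) & ~nec] = params.mu_prol
            src[nec] = -params.mu_death
        # curvature consumers need an aggressively smoothed interface
        contour = (interface_contour(state.rho, grid, blur=2.0)
                   if params.sigma > 0 else None)
        p = solve_pressure(src, tumor, grid, params, contour=contour)

        vx, vy = _face_velocities(p, tumor, grid.h)
        vmax = max(np.abs(vx).max(), np.abs(vy).max(), 1e-300)
        dt = min(0.5 * grid.h / vmax, dt_max, t_end - state.t)
        # align with the next record time to land exactly on outputs
        if i_rec < len(record_times):
            dt = min(dt, max(record_times[i_rec] - state.t, 1e-9))
        state = step_density(state, p, gamma, dt, noise_amp, rng)
        if not freeze_growth:
            # the incompressible bulk has rho = 1 exactly (density is
            # invariant along streamlines entering from the full interior);
            # drifts there are discretization error of the upwind transport
            # and would bias the oxygen field, so the interior of the
            # domain (interface band excluded) is pinned back to 1
            from scipy.ndimage import binary_erosion

            bulk = binary_erosion(state.tumor_mask, iterations=2)
            state.rho[bulk] = 1.0
        n_steps += 1

    if not vanished and state.tumor_mask.any():
        c = solve_oxygen(state.rho, grid, params, mean_field=True,
                         clamped_init=prev_clamped)
        prev_clamped = c.clamped
        emit(c)
    return {"records": records, "snapshots": snapshots, "final": state,
            "n_steps": n_steps, "vanished": vanished, "breakdown": breakdown}
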