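"""Quasi-stationary pressure and oxygen solvers.

Both the stochastic lattice model and the mean-field PDE assume that
mechanics (pressure) and nutrient transport (oxygen) relax much faster than
cell migration, division and death, so each is solved as a stationary
Poisson problem on the current state:

* pressure: ``-Δp = s`` on the tumor domain with the Young-Laplace Dirichlet
  condition ``p = p_ext + σ C`` on the rim, where C is the geometric
  (convex-positive) boundary curvature: surface tension raises the rim
  pressure on bulges, which is the stabilizing sign of the dispersion
  relation's surface-tension term.  The external medium is taken infinitely
  permeable (``D_ext = ∞``), so the ambient pressure is spatially constant.
* oxygen: ``-Δc = -λ a`` on the whole computational disc with ``c = 1`` on
  the radius-1 circle; the mean-field variant is an obstacle problem (the
  sink shuts down where c would fall below κ_death, pinning the core at
  exactly the survival threshold), solved by a primal-dual active set
  iteration.

The oxygen operator lives on the fixed disc, so its sparse factorization is
cached on the grid and every solve is a pair of triangular substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .grid import (
    BoundaryContour,
    LatticeGrid,
    assemble_laplacian,
    estimate_curvature,
    extract_boundary,
)

__all__ = ["ModelParams", "ScalarField", "solve_pressure", "solve_oxygen",
           "edge_flux", "export_field", "spectral_rim_curvature"]


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional model parameters.

    Units follow the scaling R = μ_prol = c_out = D = 1: lengths are
    fractions of the oxygen-source radius, times are cell cycles.

    mu_prol     division rate of well-oxygenated cells (1 by the
                nondimensional time scaling; a knob for test systems)
    mu_death    death rate of oxygen-starved cells (per cell cycle)
    mu_deg      degradation rate of necrotic material (lattice model only)
    kappa_prol  oxygen threshold for proliferation (fraction of c_out)
    kappa_death oxygen threshold for survival
    lam         oxygen consumption / diffusion ratio λ
    sigma       surface-tension coefficient σ
    p_ext       ambient pressure far from the tumor
    D_ext       Darcy coefficient of the external medium relative to the
                tumor tissue (np.inf = freely flowing medium)
    D1, D2      pressure-gradient-to-rate conversion factors of the lattice
                model (moves into empty / singly occupied voxels)
    """

    mu_prol: float = 1.0
    mu_death: float = 0.5
    mu_deg: float = 0.05
    kappa_prol: float = 0.94
    kappa_death: float = 0.93
    lam: float = 1.0
    sigma: float = 0.0
    p_ext: float = 0.0
    D_ext: float = np.inf
    D1: float = 1.0
    D2: float = 25.0

    def __post_init__(self):
        for name in ("mu_prol", "mu_death", "mu_deg", "kappa_prol",
                     "kappa_death", "lam", "sigma", "D1", "D2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.kappa_death <= self.kappa_prol <= 1.0:
            raise ValueError("need kappa_death <= kappa_prol <= 1")
        if self.D_ext <= 0:
            raise ValueError("D_ext must be positive (np.inf allowed)")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class ScalarField:
    """Solution of one stationary field solve on the lattice.

    ``values`` is a full (n, n) array, NaN outside the solved region unless
    a fill value was requested; ``residual`` is the max-norm residual of the
    linear system.
    """

    values: np.ndarray
    grid: LatticeGrid
    dirichlet: np.ndarray | None = None
    residual: float = 0.0
    #: nodes where the oxygen obstacle is active (c pinned at kappa_death
    #: with a partial sink) — the necrotic core of the mean-field model
    clamped: np.ndarray | None = None

    def __getitem__(self, key):
        return self.values[key]


def spectral_rim_curvature(
    contour: BoundaryContour,
    points: np.ndarray,
    k_max: int = 16,
    n_theta: int = 512,
) -> np.ndarray:
    """Curvature at arbitrary rim points from a truncated Fourier fit.

    The boundary radius function r(θ) about the contour centroid is
    resampled uniformly, truncated at wavenumber ``k_max`` (modes beyond
    the truncation receive no surface-tension feedback, so the band must
    cover every mode the lattice can meaningfully express), and the
    curvature of the smooth truncated curve

        C(θ) = (r² + 2r'² − r r'') / (r² + r'²)^(3/2)

    is evaluated at the polar angles of ``points``.  Truncation discards
    lattice-scale boundary noise (whose true curvature is O(1/h)) while
    leaving the low shape modes — the ones the linear-stability analysis
    describes — untouched.  Requires a star-shaped contour; raises
    ValueError otherwise.
    """
    center = contour.centroid()
    v = contour.vertices
    theta = np.unwrap(np.arctan2(v[:, 1] - center[1], v[:, 0] - center[0]))
    r = np.hypot(v[:, 0] - center[0], v[:, 1] - center[1])
    dtheta = np.diff(theta)
    if (dtheta < -1e-9).any() or not 1.8 * np.pi < theta[-1] - theta[0] < 2.0 * np.pi + 1e-6:
        raise ValueError("contour is not star-shaped about its centroid")
    theta = np.maximum.accumulate(theta)
    tgrid = np.linspace(theta[0], theta[0] + 2 * np.pi, n_theta, endpoint=False)
    rg = np.interp(tgrid, np.concatenate([theta, theta[:1] + 2 * np.pi]),
                   np.concatenate([r, r[:1]]))
    coef = np.fft.rfft(rg) / n_theta
    # never fit more modes than the vertex sampling can support
    k_max = min(k_max, max(4, len(v) // 4), len(coef) - 1)
    ks = np.arange(1, k_max + 1)
    # absolute angles: the FFT phase is relative to tgrid[0]
    phi = np.arctan2(points[:, 1] - center[1], points[:, 0] - center[0])
    e = np.exp(1j * np.outer(phi - tgrid[0], ks))
    ck = coef[1 : k_max + 1]
    r0 = coef[0].real
    rr = r0 + 2.0 * (e * ck).real.sum(axis=1)
    rp = 2.0 * (1j * ks * e * ck).real.sum(axis=1)
    rpp = 2.0 * (-(ks**2) * e * ck).real.sum(axis=1)
    return (rr**2 + 2 * rp**2 - rr * rpp) / (rr**2 + rp**2) ** 1.5


def _solve(A, rhs):
    x = spla.spsolve(A.tocsc(), rhs)
    res = float(np.abs(A @ x - rhs).max()) if rhs.size else 0.0
    return x, res


def solve_pressure(
    source: np.ndarray,
    tumor_mask: np.ndarray,
    grid: LatticeGrid,
    params: ModelParams,
    contour: BoundaryContour | None = None,
    curvature_window: int | None = None,
) -> ScalarField:
    """Stationary pressure on the tumor domain.

    Parameters
    ----------
    source : (n, n) float
        Right-hand side s of ``-Δp = s`` (1 on voxels above carrying
        capacity for the lattice model; the regional growth rate for the
        mean-field model).
    tumor_mask : (n, n) bool
        The tumor domain Ω.  Empty in-domain neighbors of Ω become
        Dirichlet nodes at ``p_ext + σ C`` (C convex-positive, evaluated
        on the supplied or extracted rim contour).

    The field is returned with the Dirichlet values filled in on the rim
    nodes (so edge fluxes across the rim are directly available) and NaN
    elsewhere outside Ω.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("empty tumor domain")

    # Dirichlet set: in-grid empty neighbors of the tumor
    rim_out = np.zeros(grid.shape, dtype=bool)
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        shifted = np.zeros_like(tumor_mask)
        src = tumor_mask
        if di == -1:
            shifted[:-1] |= src[1:]
        elif di == 1:
            shifted[1:] |= src[:-1]
        elif dj == -1:
            shifted[:, :-1] |= src[:, 1:]
        else:
            shifted[:, 1:] |= src[:, :-1]
        rim_out |= shifted
    rim_out &= ~tumor_mask & grid.mask

    dval = np.full(grid.shape, np.nan)
    if params.sigma > 0.0:
        if contour is None:
            contour = extract_boundary(tumor_mask.astype(float), grid)
        pts_i, pts_j = np.nonzero(rim_out)
        X, Y = grid.coords()
        pts = np.column_stack([X[pts_i, pts_j], Y[pts_i, pts_j]])
        try:
            curv_at_pts = spectral_rim_curvature(contour, pts)
        except ValueError:
            # post-splitting / non-star-shaped rim: fall back to local
            # circumcircle curvature at the nearest smoothed vertex
            if curvature_window is None:
                w = max(5, int(round(0.6 * np.sqrt(len(contour)))))
                curvature_window = w + 1 if w % 2 == 0 else w
            sm = contour.smoothed(curvature_window)
            curv = estimate_curvature(sm, window=curvature_window)
            _, nearest = cKDTree(sm.vertices).query(pts)
            curv_at_pts = curv[nearest]
        # Young-Laplace with geometric (convex-positive) curvature: the
        # interior pressure at the rim EXCEEDS the ambient by sigma*C, so a
        # bulge (larger C) pushes back harder — the stabilizing sign of the
        # surface-tension term in the dispersion relation
        dval[pts_i, pts_j] = params.p_ext + params.sigma * curv_at_pts
    else:
        dval[rim_out] = params.p_ext

    A, b, idx = assemble_laplacian(grid, tumor_mask, dval)
    rhs = np.asarray(source, dtype=float).ravel()[idx] + b
    x, res = _solve(A, rhs)
    values = np.full(grid.shape, np.nan)
    values.ravel()[idx] = x
    values[rim_out] = dval[rim_out]
    return ScalarField(values=values, grid=grid, dirichlet=dval, residual=res)


def _oxygen_operator(grid: LatticeGrid):
    """Cached factorization of -Δ on the disc with the Dirichlet condition
    imposed on the true circle via Shortley-Weller cut cells.

    Lattice arms that cross the circle of radius ``grid.radius`` are
    shortened to the intersection point, where c = c_out = 1 is applied.
    This keeps the solution O(h²) accurate: the oxygen minimum is flat near
    the necrotic interface, so a staircase-boundary O(h) error would
    translate into an O(sqrt(h)) error in the labeled region radii.
    """
    if grid._oxygen_factor is None:
        import scipy.sparse as sp

        mask = grid.mask
        ni, nj = grid.shape
        h = grid.h
        idx = np.flatnonzero(mask.ravel())
        pos = -np.ones(ni * nj, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        X, Y = grid.coords()
        xs = X.ravel()[idx]
        ys = Y.ravel()[idx]
        R2 = grid.radius**2

        rows, cols, data = [], [], []
        diag = np.zeros(idx.size)
        b = np.zeros(idx.size)
        ii, jj = np.unravel_index(idx, (ni, nj))
        theta_min = 0.05
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni2, nj2 = ii + di, jj + dj
            inside = (ni2 >= 0) & (ni2 < ni) & (nj2 >= 0) & (nj2 < nj)
            nbr_flat = np.where(inside,
                                np.clip(ni2, 0, ni - 1) * nj + np.clip(nj2, 0, nj - 1), 0)
            nbr_in = inside & (pos[nbr_flat] >= 0)
            # neighbor coordinates (also valid off-grid, extrapolated)
            xn = xs + di * h
            yn = ys + dj * h
            # cut arm: neighbor missing AND beyond the circle; a missing
            # neighbor still inside the circle (irregular test masks) is a
            # zero-flux arm and simply drops out of the stencil
            cut = ~nbr_in & (xn**2 + yn**2 > R2)
            bq = h * (xs * di + ys * dj)
            c0 = xs**2 + ys**2 - R2
            disc = np.maximum(bq**2 - h**2 * c0, 0.0)
            theta = np.clip((-bq + np.sqrt(disc)) / h**2, theta_min, 1.0)
            theta = np.where(cut, theta, 1.0)
            # Shortley-Weller: arm of length theta*h toward a value v
            # contributes -2/(theta(theta+theta_opp)h^2) * v; the opposite
            # arm is regular (theta_opp = 1) except in degenerate corners,
            # where the clamp on theta keeps the row bounded
            w = 2.0 / (theta * (theta + 1.0) * h**2)
            keep = nbr_in | cut
            rows.append(np.flatnonzero(nbr_in))
            cols.append(pos[nbr_flat[nbr_in]])
            data.append(-w[nbr_in])
            diag[keep] += w[keep]
            b[cut] += w[cut] * 1.0  # c_out = 1 on the circle

        A = sp.coo_matrix(
            (np.concatenate(data + [diag]),
             (np.concatenate(rows + [np.arange(idx.size)]),
              np.concatenate(cols + [np.arange(idx.size)]))),
            shape=(idx.size, idx.size)).tocsc()
        lu = spla.splu(A)
        grid._oxygen_factor = (lu, b, idx, mask, A)
    return grid._oxygen_factor


def solve_oxygen(
    sink_density: np.ndarray,
    grid: LatticeGrid,
    params: ModelParams,
    mean_field: bool = False,
    max_iter: int = 50,
    clamped_init: np.ndarray | None = None,
) -> ScalarField:
    """Stationary oxygen field with c = 1 on the outer circle.

    ``sink_density`` is the local living-cell density a(u) (0, 1 or 2 per
    voxel for the lattice model; ρ for the mean-field model).  With
    ``mean_field=True`` the sink is active only where the resulting
    concentration stays at or above ``kappa_death``; the self-consistent
    support is found by active-set iteration.
    """
    a_full = np.asarray(sink_density, dtype=float)
    if params.lam == 0 or not (a_full > 0).any():
        # no sink anywhere: c == c_out without touching the operator (also
        # covers irregular test masks with no path to the outer circle)
        values = np.where(grid.mask, 1.0, np.nan)
        return ScalarField(values=values, grid=grid, residual=0.0)

    lu, b, idx, _, A = _oxygen_operator(grid)
    a = a_full.ravel()[idx]

    def solve_with(support):
        rhs = -params.lam * a * support + b
        x = lu.solve(rhs)
        return x, rhs

    if not mean_field:
        x, rhs = solve_with(np.ones_like(a))
    else:
        # The conditional sink makes this a linear complementarity problem:
        # where c > kappa_death the full sink acts (-Δc = -λρ); in the core
        # c is pinned at exactly kappa_death with a PARTIAL residual sink
        # (0 <= s <= λρ).  A binary on/off sink iteration cannot represent
        # the degenerate core and systematically over- or under-consumes, so
        # the obstacle problem is solved by a primal-dual active set method:
        # clamped nodes become Dirichlet rows at kappa_death, and the set is
        # updated from the primal violation (c < kappa_death) and the dual
        # multiplier (residual sink must stay nonnegative).
        import scipy.sparse as sp

        psi = params.kappa_death
        f = -params.lam * a + b
        n = idx.size
        candidates = a > 0
        if clamped_init is not None:
            # warm start from the previous time step's active set: the
            # obstacle region moves slowly, so one factorization usually
            # confirms the set
            clamped = np.asarray(clamped_init).ravel()[idx] & candidates
            if clamped.any():
                sel = sp.diags((~clamped).astype(float))
                A_mod = (sel @ A + sp.diags(clamped.astype(float))).tocsc()
                x = spla.splu(A_mod).solve(np.where(clamped, psi, f))
            else:
                x = lu.solve(f)
        else:
            clamped = np.zeros(n, dtype=bool)
            x = lu.solve(f)
        for _ in range(max_iter):
            # clamped nodes stay while the residual sink (multiplier
            # m = (Ac - f) = λρ(1-s)) is positive; free nodes join when the
            # obstacle is violated
            new_clamped = candidates & (
                np.where(clamped, A @ x - f, psi - x) > 1e-13)
            if np.array_equal(new_clamped, clamped):
                break
            clamped = new_clamped
            if not clamped.any():
                x = lu.solve(f)
            else:
                sel = sp.diags((~clamped).astype(float))
                A_mod = (sel @ A + sp.diags(clamped.astype(float))).tocsc()
                f_mod = np.where(clamped, psi, f)
                x = spla.splu(A_mod).solve(f_mod)
        else:
            raise RuntimeError("oxygen obstacle problem did not converge")
        values = np.ones(grid.shape)
        values[~grid.mask] = np.nan
        values.ravel()[idx] = x
        clamp_full = np.zeros(grid.shape, dtype=bool)
        clamp_full.ravel()[idx] = clamped
        return ScalarField(values=values, grid=grid, residual=0.0,
                           clamped=clamp_full)

    res = float(np.abs(A @ x - rhs).max())
    values = np.ones(grid.shape)  # Dirichlet ring and exterior padding at c_out
    values[~grid.mask] = np.nan
    values.ravel()[idx] = x
    return ScalarField(values=values, grid=grid, residual=res)


def export_field(field: ScalarField, path, fmt: str = "tsv") -> None:
    """Write a field snapshot as delimited text or a raster image.

    Text format: one row per in-domain node with columns
    ``index  x  y  value``.  PNG renders the array with NaNs transparent.
    """
    from pathlib import Path

    path = Path(path)
    if fmt == "tsv":
        X, Y = field.grid.coords()
        sel = np.isfinite(field.values)
        idx = np.flatnonzero(sel.ravel())
        data = np.column_stack([idx, X[sel], Y[sel], field.values[sel]])
        header = "index\tx\ty\tvalue"
        np.savetxt(path, data, delimiter="\t", header=header, comments="",
                   fmt=("%d", "%.10g", "%.10g", "%.10g"))
    elif fmt == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        extent = (field.grid.y[0], field.grid.y[-1],
                  field.grid.x[0], field.grid.x[-1])
        im = ax.imshow(field.values, origin="lower", extent=extent)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_xlabel("y")
        ax.set_ylabel("x")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def edge_flux(p: ScalarField, i: tuple[int, int], j: tuple[int, int]) -> float:
    """Pressure gradient integrated over the shared voxel edge.

    On the square lattice the shared edge length h cancels one h of the
    finite-difference gradient, leaving simply ``p_i - p_j``.
    """
    if abs(i[0] - j[0]) + abs(i[1] - j[1]) != 1:
        raise ValueError(f"voxels {i} and {j} are not 4-adjacent")
    return float(p.values[i] - p.values[j])
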