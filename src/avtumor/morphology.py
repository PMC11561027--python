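"""Quantitative tumor morphology.

Roundness (the isoperimetric ratio 4π·Area/Perimeter²), regional volumes
by oxygen class, boundary Fourier mode amplitudes, exponential mode-growth
fitting, and center-of-mass drift.  Perimeters of lattice-extracted
contours are measured after a 3-point vertex smoothing: raw
marching-squares polygons bias the perimeter high and hence roundness low.
"""

from __future__ import annotations

import numpy as np

from .fields import ModelParams, ScalarField
from .grid import BoundaryContour, LatticeGrid

__all__ = [
    "roundness",
    "roundness_of",
    "region_volumes",
    "boundary_modes",
    "fit_mode_growth",
    "moving_window_std",
]


def roundness(area: float, perimeter: float) -> float:
    """4π·Area / Perimeter²; equals 1 exactly for a circle and is < 1 for
    every other shape (isoperimetric inequality)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def roundness_of(contour: BoundaryContour, smooth_window: int = 3) -> float:
    """Roundness of an extracted contour (smoothed perimeter estimator).

    Flagged multi-component contours are evaluated on the retained largest
    component; the caller should treat the value as unreliable once the
    tumor splits.
    """
    sm = contour.smoothed(smooth_window)
    return roundness(abs(sm.area), sm.perimeter)


def region_volumes(
    state: np.ndarray,
    c: ScalarField,
    params: ModelParams,
    grid: LatticeGrid,
    density: bool = False,
) -> tuple[float, float, float]:
    """Areas (V_p, V_q, V_n) of the oxygen-defined regions.

    For the lattice model (``density=False``) the areas are h² times voxel
    counts: living voxels split by oxygen class, all necrotic voxels (and
    living voxels already below the survival threshold) counted in V_n.
    For the mean-field model the areas are density-weighted integrals over
    the same oxygen classes.
    """
    h2 = grid.h**2
    cv = c.values
    if density:
        from scipy.ndimage import binary_fill_holes

        rho = np.asarray(state, dtype=float)
        occ = rho
        # restrict to the tumor domain: the smeared interface foot outside
        # the 0.5 level would otherwise inflate the outermost region
        inside = binary_fill_holes(rho >= 0.5) & grid.mask
        # clamped nodes sit at c = kappa_death exactly (partial sink): they
        # are the necrotic core, not quiescent tissue
        clamped = c.clamped if c.clamped is not None else np.zeros_like(inside)
        nec = inside & ((cv < params.kappa_death) | clamped)
        prol = inside & (cv >= params.kappa_prol) & ~nec
        qui = inside & ~nec & ~prol
        return (float(occ[prol].sum() * h2), float(occ[qui].sum() * h2),
                float(occ[nec].sum() * h2))
    u = np.asarray(state)
    living = u >= 1
    prol = living & (cv >= params.kappa_prol)
    qui = living & (cv < params.kappa_prol) & (cv >= params.kappa_death)
    nec = (u == -1) | (living & (cv < params.kappa_death))
    return (float(prol.sum() * h2), float(qui.sum() * h2), float(nec.sum() * h2))


def boundary_modes(
    contour: BoundaryContour,
    k_max: int,
    center: np.ndarray | None = None,
    n_theta: int = 512,
) -> tuple[np.ndarray, float]:
    """Fourier amplitudes of the boundary radius function.

    The contour must be star-shaped about ``center`` (default: its
    centroid) so r(θ) is single-valued; it is resampled uniformly in θ and
    α_k = 2|FFT_k|/N combines the cosine and sine channels (the
    perturbation phase is arbitrary in measurements).  Returns
    (α_1..α_k_max, mean radius).
    """
    v = contour.vertices
    if center is None:
        center = contour.centroid()
    dx = v[:, 0] - center[0]
    dy = v[:, 1] - center[1]
    theta = np.unwrap(np.arctan2(dy, dx))
    r = np.hypot(dx, dy)
    # star-shapedness: the polar angle must wind monotonically (once) around
    # the center, otherwise some ray cuts the contour more than once
    dtheta = np.diff(theta)
    winding = theta[-1] - theta[0]
    if (dtheta < -1e-9).any() or len(theta) < max(8, 2 * k_max + 1) \
            or not 1.8 * np.pi < winding < 2.0 * np.pi + 1e-6:
        raise ValueError("contour is not star-shaped about the center; "
                         "mode analysis unreliable (post-splitting?)")
    theta = np.maximum.accumulate(theta - theta[0])
    theta_ext = np.concatenate([theta, theta[:1] + 2 * np.pi])
    r_ext = np.concatenate([r, r[:1]])
    tgrid = np.linspace(theta[0], theta[0] + 2 * np.pi, n_theta, endpoint=False)
    rg = np.interp(tgrid, theta_ext, r_ext)
    coef = np.fft.rfft(rg) / n_theta
    if k_max >= len(coef):
        raise ValueError("k_max too large for the angular resolution")
    alphas = 2.0 * np.abs(coef[1 : k_max + 1])
    return alphas, float(coef[0].real)


def fit_mode_growth(t: np.ndarray, alpha: np.ndarray,
                    window: tuple[float, float] | None = None
                    ) -> tuple[float, float]:
    """Least-squares exponential growth rate of a mode amplitude.

    Fits ln α against t over the requested time window (whole series by
    default); non-positive amplitudes are dropped.  Returns (rate,
    standard error) with the standard error from the fit residuals.
    """
    t = np.asarray(t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    sel = np.isfinite(alpha) & (alpha > 0)
    if window is not None:
        sel &= (t >= window[0]) & (t <= window[1])
    t, alpha = t[sel], alpha[sel]
    if len(t) < 5:
        raise ValueError("need at least 5 positive samples in the window")
    y = np.log(alpha)
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    resid = y - A @ coef
    dof = len(t) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    tc = t - t.mean()
    denom = float(tc @ tc)
    se = np.sqrt(s2 / denom) if denom > 0 else np.inf
    return float(slope), float(se)


def moving_window_std(t: np.ndarray, x: np.ndarray, window: float = 1.0) -> np.ndarray:
    """Standard deviation of x in a centered moving time window."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    for i, ti in enumerate(t):
        sel = np.abs(t - ti) <= window / 2
        if sel.sum() >= 2:
            out[i] = np.std(x[sel], ddof=1)
    return out
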