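"""Cartesian lattice, masked discrete Laplacian, and boundary geometry.

The computational domain is the unit disc (the oxygen source sits on the
radius-1 circle), discretized on a square lattice of spacing ``h`` with
4-connectivity and the standard 5-point Laplacian.  Tumor boundaries are
extracted as marching-squares contours of an occupancy indicator and carry
per-vertex curvature estimates used by the Young-Laplace pressure condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from skimage import measure

__all__ = [
    "LatticeGrid",
    "BoundaryContour",
    "build_lattice",
    "grid_from_mask",
    "assemble_laplacian",
    "extract_boundary",
    "estimate_curvature",
]

#: index offsets of the 4-neighborhood, row-major (di, dj)
NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class LatticeGrid:
    """Square lattice covering the computational disc.

    Nodes live at ``(i*h, j*h)`` relative to the disc center; ``mask`` marks
    nodes inside the computational domain (the unit disc for production runs,
    arbitrary shapes for small test systems).
    """

    h: float
    radius: float
    x: np.ndarray  # (n,) physical coordinates along one axis
    y: np.ndarray
    mask: np.ndarray  # (n, n) bool, True inside the domain
    _oxygen_factor: object = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_nodes(self) -> int:
        return int(self.mask.sum())

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of physical node coordinates (indexing='ij')."""
        return np.meshgrid(self.x, self.y, indexing="ij")

    def radii(self) -> np.ndarray:
        X, Y = self.coords()
        return np.hypot(X, Y)

    def interior_mask(self) -> np.ndarray:
        """Nodes of the domain whose 4 neighbors are all inside the domain."""
        m = self.mask
        inner = m.copy()
        inner[0, :] = inner[-1, :] = inner[:, 0] = inner[:, -1] = False
        for di, dj in NEIGHBOR_OFFSETS:
            inner &= np.roll(np.roll(m, -di, axis=0), -dj, axis=1)
        return inner

    def boundary_mask(self) -> np.ndarray:
        """Domain nodes with at least one neighbor outside the domain."""
        return self.mask & ~self.interior_mask()


@dataclass
class BoundaryContour:
    """Closed simple polygon of a region boundary in physical coordinates.

    Vertices are ordered counterclockwise so the shoelace area is positive
    for any valid contour.  ``n_components`` counts the disjoint boundary
    loops found in the source indicator; only the largest is retained and
    ``flagged`` is set when more than one was present (detachment events).
    """

    vertices: np.ndarray  # (N, 2), closed implicitly (last != first)
    n_components: int = 1
    flagged: bool = False

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starting at 0)."""
        d = self.vertices - np.roll(self.vertices, 1, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
        seg[0] = 0.0
        return np.cumsum(seg)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def smoothed(self, window: int = 3) -> "BoundaryContour":
        """Circular moving-average smoothing of the vertex chain."""
        if window <= 1 or len(self.vertices) < window:
            return self
        kernel = np.ones(window) / window
        pad = window // 2
        v = np.concatenate([self.vertices[-pad:], self.vertices, self.vertices[:pad]])
        sm = np.column_stack(
            [np.convolve(v[:, 0], kernel, "valid"), np.convolve(v[:, 1], kernel, "valid")]
        )
        return BoundaryContour(sm, self.n_components, self.flagged)


def build_lattice(h: float, radius: float = 1.0) -> LatticeGrid:
    """Build a square lattice whose mask is the disc of the given radius.

    The bounding square spans ``[-radius, radius]`` in each axis with
    ``2*round(radius/h) + 1`` nodes per axis.
    """
    if h <= 0 or radius <= 0:
        raise ValueError(f"h and radius must be positive, got h={h}, radius={radius}")
    if h >= radius:
        raise ValueError(f"lattice spacing h={h} must be smaller than radius={radius}")
    m = int(round(radius / h))
    ax = np.arange(-m, m + 1) * h
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    mask = X**2 + Y**2 <= radius**2 + 1e-12
    return LatticeGrid(h=h, radius=radius, x=ax, y=ax, mask=mask)


def grid_from_mask(h: float, mask: np.ndarray, radius: float | None = None) -> LatticeGrid:
    """Lattice over an explicit boolean mask (small test systems).

    The mask is centered so that node ``(i, j)`` sits at
    ``((i - (ni-1)/2) h, (j - (nj-1)/2) h)``.
    """
    mask = np.asarray(mask, dtype=bool)
    ni, nj = mask.shape
    x = (np.arange(ni) - (ni - 1) / 2) * h
    y = (np.arange(nj) - (nj - 1) / 2) * h
    if radius is None:
        radius = max(x.max(), y.max()) + h
    return LatticeGrid(h=h, radius=radius, x=x, y=y, mask=mask)


def assemble_laplacian(
    grid: LatticeGrid,
    active: np.ndarray,
    dirichlet_values: np.ndarray | None = None,
    check_connectivity: bool = True,
):
    """5-point negative Laplacian (-Δ) over the active node set.

    Parameters
    ----------
    active : (n, n) bool
        Unknown nodes.  Must be a subset of ``grid.mask``.
    dirichlet_values : (n, n) float or None
        Known boundary values; a node ``j`` adjacent to an active node is a
        Dirichlet node iff ``dirichlet_values[j]`` is finite.  Its value is
        eliminated into the returned right-hand-side contribution.  Neighbors
        that are neither active nor Dirichlet (e.g. outside ``grid.mask``)
        are treated as zero-flux and dropped from the stencil.

    Returns
    -------
    A : csr_matrix, shape (m, m)
        Symmetric positive definite operator (units 1/length^2).
    b : (m,) ndarray
        Right-hand-side contribution of the eliminated Dirichlet values.
    idx : (m,) ndarray
        Flat indices of the active nodes in row-major grid order.
    """
    active = np.asarray(active, dtype=bool)
    if not active.any():
        raise ValueError("active node set is empty")
    if (active & ~grid.mask).any():
        raise ValueError("active nodes must lie inside the grid mask")

    h2 = grid.h**2
    ni, nj = grid.shape
    flat_active = active.ravel()
    idx = np.flatnonzero(flat_active)
    pos = -np.ones(ni * nj, dtype=np.int64)
    pos[idx] = np.arange(idx.size)

    if dirichlet_values is None:
        dval = np.full(grid.shape, np.nan)
    else:
        dval = np.asarray(dirichlet_values, dtype=float)
    is_dir = np.isfinite(dval).ravel()

    ii, jj = np.unravel_index(idx, (ni, nj))
    rows_list, cols_list = [], []
    diag = np.zeros(idx.size)
    b = np.zeros(idx.size)
    for di, dj in NEIGHBOR_OFFSETS:
        ni2, nj2 = ii + di, jj + dj
        inside = (ni2 >= 0) & (ni2 < ni) & (nj2 >= 0) & (nj2 < nj)
        nbr_flat = np.where(inside, np.clip(ni2, 0, ni - 1) * nj + np.clip(nj2, 0, nj - 1), 0)
        nbr_active = inside & flat_active[nbr_flat]
        nbr_dir = inside & ~flat_active[nbr_flat] & is_dir[nbr_flat]
        # links to unknown neighbors
        rows_list.append(np.flatnonzero(nbr_active))
        cols_list.append(pos[nbr_flat[nbr_active]])
        diag[nbr_active] += 1.0
        diag[nbr_dir] += 1.0
        b[nbr_dir] += dval.ravel()[nbr_flat[nbr_dir]] / h2

    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    data = np.full(rows.size, -1.0 / h2)
    A = sp.coo_matrix(
        (np.concatenate([data, diag / h2]), (np.concatenate([rows, np.arange(idx.size)]),
                                             np.concatenate([cols, np.arange(idx.size)]))),
        shape=(idx.size, idx.size),
    ).tocsr()

    if check_connectivity:
        # a node is anchored iff its diagonal exceeds its number of active
        # links, i.e. it has at least one eliminated Dirichlet neighbor
        n_links = np.zeros(idx.size)
        np.add.at(n_links, rows, 1.0)
        anchored = diag > n_links + 1e-12
        ncomp, labels = connected_components(A, directed=False)
        ok = np.zeros(ncomp, dtype=bool)
        ok[labels[anchored]] = True
        if not ok.all():
            raise np.linalg.LinAlgError(
                "singular system: active component with no path to a Dirichlet node"
            )
    return A, b, idx


def extract_boundary(indicator: np.ndarray, grid: LatticeGrid,
                     blur: float = 0.0) -> BoundaryContour:
    """Marching-squares 0.5-level contour of a node-centered indicator.

    Returns the largest closed loop, counterclockwise, in physical
    coordinates; additional disjoint loops only set ``n_components`` and
    ``flagged`` (cluster detachment).  ``blur`` (in cells) optionally
    Gaussian-smooths the indicator first: lattice-scale staircase wiggles
    of the raw level set carry O(1/h) curvature noise, so smoothed contours
    are the right input for curvature-sensitive consumers.
    """
    arr = np.asarray(indicator, dtype=float)
    if not (arr > 0.5).any():
        raise ValueError("empty domain: indicator has no interior node")
    if blur > 0.0:
        from scipy.ndimage import gaussian_filter

        arr = gaussian_filter(arr, blur)
        if not (arr > 0.5).any():
            raise ValueError("empty domain after smoothing")
    contours = measure.find_contours(arr, 0.5)
    closed = [c for c in contours if len(c) >= 3]
    if not closed:
        raise ValueError("no closed contour found at the 0.5 level")

    def shoelace(c):
        x, y = c[:, 0], c[:, 1]
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    areas = np.array([abs(shoelace(c)) for c in closed])
    best = closed[int(np.argmax(areas))]
    # index space -> physical coordinates (row index ~ x, col index ~ y)
    verts = np.column_stack(
        [np.interp(best[:, 0], np.arange(len(grid.x)), grid.x),
         np.interp(best[:, 1], np.arange(len(grid.y)), grid.y)]
    )
    # drop duplicated closing vertex if present
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if shoelace(verts) < 0:
        verts = verts[::-1]
    return BoundaryContour(
        vertices=verts,
        n_components=len(closed),
        flagged=len(closed) > 1,
    )


def estimate_curvature(contour: BoundaryContour, window: int = 5) -> np.ndarray:
    """Signed curvature per vertex from circumscribed circles.

    For each vertex i the circle through vertices (i-w, i, i+w), w =
    window // 2, gives |curvature| = 1/circumradius; the sign follows the
    cross product so convex (counterclockwise-turning) arcs are positive.
    A final moving average of length ``window`` suppresses staircase noise.
    Collinear triples give exactly zero.
    """
    v = contour.vertices
    if len(v) < 3:
        raise ValueError("contour needs at least 3 vertices")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    w = max(1, min(window // 2, (len(v) - 1) // 2))
    a = np.roll(v, w, axis=0)
    b = v
    c = np.roll(v, -w, axis=0)
    ab = b - a
    bc = c - b
    ac = c - a
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    denom = (
        np.hypot(ab[:, 0], ab[:, 1])
        * np.hypot(bc[:, 0], bc[:, 1])
        * np.hypot(ac[:, 0], ac[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(denom > 0, 2.0 * cross / np.where(denom > 0, denom, 1.0), 0.0)
    if len(curv) > window:
        kernel = np.ones(window) / window
        pad = window // 2
        ext = np.concatenate([curv[-pad:], curv, curv[:pad]])
        curv = np.convolve(ext, kernel, "valid")
    return curv
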