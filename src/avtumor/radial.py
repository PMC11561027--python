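"""Radially symmetric reduction of the mean-field tumor model.

Under radial symmetry and unit cell density the model collapses to three
interface radii: the outer rim ``r_p``, the quiescent interface ``r_q``
(oxygen = κ_prol) and the necrotic interface ``r_n`` (oxygen = κ_death).
The oxygen field has a closed form, the interior radii are algebraic
functions of ``r_p`` through the reduced parameters

    K_prol  = 4 (1 - κ_prol) / λ
    K_death = 4 (1 - κ_death) / λ

and the tumor area obeys the scalar mass-balance ODE

    d(r_p²)/dt = -μ_death r_n² - r_q² + r_p²

(proliferation rate normalized to 1).  The stationary state, its single
eigenvalue, and a small-tumor sufficient stability criterion
(``r_p ≤ exp(-1)``) are all available in closed or near-closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .fields import ModelParams

__all__ = [
    "RadialState",
    "ReducedParams",
    "oxygen_profile",
    "region_relations",
    "solve_regions",
    "radial_rhs",
    "integrate_radial",
    "find_stationary",
    "eigenvalue_radial",
    "eigenvalue_radial_eta",
    "prop31_guaranteed_stable",
    "pressure_profile",
    "reduced_params",
    "stationary_from_eta",
]

_TINY = 1e-14


@dataclass(frozen=True)
class RadialState:
    """Ordered zonation radii 0 <= r_n <= r_q <= r_p < 1."""

    r_n: float
    r_q: float
    r_p: float

    def __post_init__(self):
        if not (0.0 <= self.r_n <= self.r_q <= self.r_p):
            raise ValueError(f"radii must satisfy 0 <= r_n <= r_q <= r_p, got {self}")
        if self.r_p >= 1.0:
            raise ValueError("r_p must stay below the oxygen source radius 1")

    def as_tuple(self):
        return (self.r_n, self.r_q, self.r_p)


@dataclass(frozen=True)
class ReducedParams:
    """Reduced parameter set (K_prol, K_death, mu_death) driving the 1D dynamics."""

    K_prol: float
    K_death: float
    mu_death: float

    def __post_init__(self):
        if not 0.0 <= self.K_prol <= self.K_death:
            raise ValueError("need 0 <= K_prol <= K_death (kappa_death <= kappa_prol)")


def reduced_params(params: ModelParams) -> ReducedParams:
    if params.lam <= 0:
        raise ValueError("reduced parameters require lam > 0")
    return ReducedParams(
        K_prol=4.0 * (1.0 - params.kappa_prol) / params.lam,
        K_death=4.0 * (1.0 - params.kappa_death) / params.lam,
        mu_death=params.mu_death,
    )


def oxygen_profile(r, state: RadialState, lam: float, kappa_death: float = 0.93):
    """Closed-form radially symmetric oxygen concentration.

    Piecewise in r: logarithmic decay outside the tumor, a log + quadratic
    profile across the consuming annulus ``r_n <= r <= r_p``, and the
    constant survival threshold inside the necrotic core.  C^1 across r_p.
    """
    r = np.asarray(r, dtype=float)
    if (r > 1.0 + 1e-12).any() or (r < 0).any():
        raise ValueError("r must lie in [0, 1]")
    rn, _, rp = state.as_tuple()
    rn2, rp2 = rn**2, rp**2
    logr = np.log(np.maximum(r, _TINY))
    outer = 1.0 + lam / 2.0 * (rp2 - rn2) * logr
    log_rp = np.log(max(rp, _TINY))
    mid = 1.0 + lam / 2.0 * (rp2 * log_rp - rn2 * logr + (r**2 - rp2) / 2.0)
    c = np.where(r >= rp, outer, mid)
    if rn > 0 and lam > 0:
        c = np.where(r <= rn, kappa_death, c)
    return c if c.ndim else float(c)


def region_relations(state: RadialState, lam: float, kappa_prol: float,
                     kappa_death: float) -> tuple[float, float]:
    """Residuals of the two algebraic zonation relations.

    Both vanish for a consistent zonation; a relation is inactive (residual
    reported as 0) when its interface does not exist — no quiescent
    interface when even the center stays above kappa_prol, no necrotic core
    when the center stays above kappa_death.
    """
    rn2, rq2, rp2 = state.r_n**2, state.r_q**2, state.r_p**2
    K_prol = 4.0 * (1.0 - kappa_prol) / lam
    K_death = 4.0 * (1.0 - kappa_death) / lam
    lp = np.log(max(rp2, _TINY))
    if state.r_q > 0:
        res_prol = (-rp2 * lp + rn2 * np.log(max(rq2, _TINY)) - rq2 + rp2) - K_prol
    else:
        center = oxygen_profile(0.0, state, lam, kappa_death)
        res_prol = 0.0 if center >= kappa_prol else (-rp2 * lp + rp2) - K_prol
    if state.r_n > 0:
        res_death = (-rp2 * lp + rn2 * np.log(rn2) - rn2 + rp2) - K_death
    else:
        center = oxygen_profile(0.0, state, lam, kappa_death)
        res_death = 0.0 if center >= kappa_death else (-rp2 * lp + rp2) - K_death
    return float(res_prol), float(res_death)


def solve_regions(K_prol: float, K_death: float, r_p: float,
                  xtol: float = 1e-14) -> RadialState:
    """Interior radii slaved to the rim radius.

    Solves the zonation relations for (r_n, r_q) at fixed r_p by bracketed
    root finding.  Degenerate regimes are handled explicitly: no necrotic
    core (r_n = 0) when the center stays above the survival threshold, no
    proliferative rim (r_q = r_p) when even the rim oxygen falls below the
    proliferation threshold.
    """
    if not 0.0 < r_p < 1.0:
        raise ValueError("r_p must lie in (0, 1)")
    x = r_p**2
    base = -x * np.log(x) + x  # relation value at z -> 0

    # necrotic interface from the K_death relation; phi is decreasing in z
    def phi(z):
        return base + z * np.log(z) - z - K_death

    if phi(_TINY) <= 0.0:
        z = 0.0
    else:
        z = brentq(phi, _TINY, x, xtol=xtol)

    # quiescent interface from the K_prol relation; psi decreasing in y > z
    def psi(y):
        zy = z * np.log(y) if z > 0 else 0.0
        return base + zy - y - K_prol

    if z == 0.0:
        y = base - K_prol
        y = min(max(y, 0.0), x)
    else:
        if psi(x) >= 0.0:
            y = x  # whole tumor below the proliferation threshold
        else:
            y = brentq(psi, max(z, _TINY), x, xtol=xtol)
    y = max(y, z)
    return RadialState(r_n=np.sqrt(z), r_q=np.sqrt(y), r_p=r_p)


def radial_rhs(state: RadialState, mu_death: float) -> float:
    """Mass-balance rate of change of the tumor area, d(r_p²)/dt."""
    return -mu_death * state.r_n**2 - state.r_q**2 + state.r_p**2


def _rhs_of_x(x: float, rp: ReducedParams) -> float:
    st = solve_regions(rp.K_prol, rp.K_death, np.sqrt(x))
    return radial_rhs(st, rp.mu_death)


def integrate_radial(
    r_p0: float,
    params: ModelParams | ReducedParams,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the 1D dynamics from an initial rim radius.

    The interior radii are algebraically slaved at every step (quasi-static
    zonation).  Integration stops early, flagged, if the rim approaches the
    oxygen source (avascularity breakdown) or the tumor collapses.

    Returns a dict with arrays t, r_n, r_q, r_p and a ``terminated`` flag.
    """
    rp = params if isinstance(params, ReducedParams) else reduced_params(params)
    if not 0.0 < r_p0 < 1.0:
        raise ValueError("r_p0 must lie in (0, 1)")

    def rhs(t, xv):
        x = min(max(xv[0], _TINY), (1.0 - 1e-9) ** 2)
        return [_rhs_of_x(x, rp)]

    def breakdown(t, xv):
        return xv[0] - 0.98**2

    breakdown.terminal = True

    def collapse(t, xv):
        return xv[0] - (1e-4) ** 2

    collapse.terminal = True

    sol = solve_ivp(
        rhs, (0.0, t_end), [r_p0**2], t_eval=t_eval, rtol=rtol, atol=atol,
        events=[breakdown, collapse], dense_output=t_eval is None,
    )
    x = np.maximum(sol.y[0], _TINY)
    states = [solve_regions(rp.K_prol, rp.K_death, np.sqrt(xi)) for xi in x]
    return {
        "t": sol.t,
        "r_n": np.array([s.r_n for s in states]),
        "r_q": np.array([s.r_q for s in states]),
        "r_p": np.array([s.r_p for s in states]),
        "terminated": sol.status == 1,
    }


def find_stationary(params: ModelParams | ReducedParams,
                    x_max: float = 0.96**2) -> RadialState:
    """Nontrivial stationary zonation of the 1D dynamics.

    Scans the area variable for a sign change of the mass-balance rate and
    brackets the root.  Raises if the parameters admit no nontrivial
    equilibrium below the avascularity cutoff.
    """
    rp = params if isinstance(params, ReducedParams) else reduced_params(params)
    xs = np.linspace(1e-6, x_max, 400)
    vals = np.array([_rhs_of_x(x, rp) for x in xs])
    sign_change = np.nonzero((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if sign_change.size == 0:
        if (vals > 0).all():
            raise ValueError("no stationary state: unbounded growth up to the "
                             "avascularity cutoff (r_p -> 1)")
        raise ValueError("no stationary state: tumor collapses (r_p -> 0)")
    i = sign_change[0]
    x_eq = brentq(lambda x: _rhs_of_x(x, rp), xs[i], xs[i + 1], xtol=1e-15)
    return solve_regions(rp.K_prol, rp.K_death, np.sqrt(x_eq))


def eigenvalue_radial(state: RadialState, mu_death: float) -> float:
    """Growth-rate eigenvalue of the linearized 1D dynamics.

    Λ_r = 1 - (log r_p / log r_n) (μ_death + 2 log(r_q/r_n) / (r_q² - r_n²) · r_q²)

    with the degenerate zonations handled by their analytic limits:
    r_n → 0 gives Λ_r = 1 + 2 log r_p, and r_q → r_n replaces the
    difference quotient by 1/r_q².
    """
    rn, rq, rpp = state.as_tuple()
    if rpp <= 0:
        raise ValueError("r_p must be positive")
    if rn == 0.0:
        return 1.0 + 2.0 * np.log(rpp)
    y, z = rq**2, rn**2
    quot = 1.0 / y if np.isclose(y, z, rtol=1e-12, atol=1e-300) \
        else 2.0 * np.log(rq / rn) / (y - z)
    return float(1.0 - np.log(rpp) / np.log(rn) * (mu_death + quot * y))


def stationary_from_eta(eta, mu_death, r_p):
    """Stationary zonation from the ratio parametrization.

    η = r_n²/r_q² in [0, 1]; stationarity fixes r_q² = r_p²/(1 + μ_death η).
    Vectorized over η and mu_death; returns (r_n, r_q) arrays.
    """
    eta = np.asarray(eta, dtype=float)
    mu = np.asarray(mu_death, dtype=float)
    y = r_p**2 / (1.0 + mu * eta)
    z = eta * y
    return np.sqrt(z), np.sqrt(y)


def eigenvalue_radial_eta(eta, mu_death, r_p):
    """Vectorized eigenvalue over the (η, μ_death) stationary family at fixed r_p.

    Uses the same closed form as :func:`eigenvalue_radial`, written in
    (η, μ) to remain finite at the η → 0 and η → 1 limits.
    """
    eta = np.asarray(eta, dtype=float)
    mu = np.asarray(mu_death, dtype=float)
    log_rp = np.log(r_p)
    # -log(eta)/(1-eta), with limit 1 at eta -> 1
    q = np.where(
        np.isclose(eta, 1.0, atol=1e-12),
        1.0,
        -np.log(np.maximum(eta, _TINY)) / (1.0 - eta),
    )
    log_rn = log_rp + 0.5 * np.log(np.maximum(eta, _TINY) / (1.0 + mu * eta))
    lam = 1.0 - log_rp / log_rn * (mu + q)
    # eta -> 0 analytic limit
    lam = np.where(eta <= _TINY, 1.0 + 2.0 * log_rp, lam)
    return lam


def prop31_guaranteed_stable(state: RadialState) -> bool:
    """Sufficient small-tumor stability criterion: r_p <= exp(-1).

    True guarantees a negative radial eigenvalue for any admissible interior
    zonation and death rate; False carries no conclusion.
    """
    return state.r_p <= np.exp(-1.0)


def pressure_profile(r, state: RadialState, mu_death: float,
                     D_ext: float = np.inf, sigma: float = 0.0,
                     p_ext: float = 0.0):
    """Closed-form radially symmetric pressure.

    Four branches (external medium, proliferative annulus, quiescent
    annulus, necrotic core), glued by flux continuity; the rim carries the
    Young-Laplace jump +σ/r_p (interior pressure above ambient for a
    convex tumor).  The negative pressure gradient at the rim
    equals the rim velocity of the mass-balance ODE.

    Note the quiescent-annulus log coefficient is μ_death r_n²/2: the flux
    through any circle inside that annulus encloses only the necrotic sink.
    """
    r = np.asarray(r, dtype=float)
    rn, rq, rpp = state.as_tuple()
    z, y, x = rn**2, rq**2, rpp**2
    net = mu_death * z + y - x  # total signed source strength (negative while growing)

    if np.isinf(D_ext):
        p_at_rp = p_ext
    else:
        p_at_rp = p_ext + net / (2.0 * D_ext) * np.log(max(rpp, _TINY))

    if rpp == 0.0:
        out = np.full_like(r, p_ext - (sigma / rpp if rpp > 0 else 0.0))
        return out if out.ndim else float(out)

    C = 1.0 / rpp
    logr = np.log(np.maximum(r, _TINY))
    if np.isinf(D_ext):
        p_outer = np.full_like(r, p_ext)
    else:
        p_outer = p_ext + net / (2.0 * D_ext) * logr

    p_rp_in = p_at_rp + sigma * C
    p_p = ((mu_death * z + y) / 2.0 * (logr - np.log(rpp))
           - 0.25 * (r**2 - x) + p_rp_in)

    def p_p_at(rv):
        return ((mu_death * z + y) / 2.0 * (np.log(max(rv, _TINY)) - np.log(rpp))
                - 0.25 * (rv**2 - x) + p_rp_in)

    p_q = p_p_at(rq) + mu_death / 2.0 * z * (logr - np.log(max(rq, _TINY)))

    def p_q_at(rv):
        return p_p_at(rq) + mu_death / 2.0 * z * (
            np.log(max(rv, _TINY)) - np.log(max(rq, _TINY)))

    p_n = p_q_at(rn) + mu_death / 4.0 * (r**2 - z)

    p = np.where(r >= rpp, p_outer, p_p)
    if rq > 0:
        p = np.where(r < rq, p_q, p)
    if rn > 0:
        p = np.where(r < rn, p_n, p)
    return p if p.ndim else float(p)
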