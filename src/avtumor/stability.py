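"""Linear stability of the radially symmetric tumor boundary.

A cosine perturbation of the rim, r̃_p(θ) = r_p + ε α_k cos(kθ), grows or
decays exponentially at the rate Λ(k) given by the dispersion relation

    Λ(k) = Δ_θ ( (1 - D_ext)/(1 + D_ext) k - 1 )
         + D_ext/(1 + D_ext) ( 1 - A_k - σ k(k²-1)/r_p³ ),

where Δ_θ = r_p'/r_p is the growth-phase discriminant, A_k ≥ 0 is the
combined inner-region (oxygen-zonation) damping term, and the last term is
the Young-Laplace surface-tension penalty.  The three named pieces are the
Saffman-Taylor contribution of the two-phase Darcy flow, the stabilizing
response of the interior interfaces, and surface tension.

Mode k = 1 is a rigid translation ("creeping" of the tumor toward the
oxygen source): surface tension cannot act on it and its rate is always
nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radial import RadialState, radial_rhs

__all__ = [
    "PerturbationSpec",
    "DispersionResult",
    "inner_term",
    "dispersion",
    "creeping_rate",
    "sigma_stable",
    "sigma_bound",
    "growth_phase_discriminant",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Cosine boundary perturbation: mode k, relative amplitude eps, base radius."""

    k: int
    eps: float
    r_p: float
    phase: float = 0.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("perturbation mode k must be >= 1")
        if abs(self.eps) > 0.2:
            raise ValueError("|eps| must stay <= 0.2 for the linear analysis to apply")
        if abs(self.eps) > 0.1:
            import warnings

            warnings.warn("|eps| > 0.1: linearization accuracy degrades", stacklevel=2)


@dataclass(frozen=True)
class DispersionResult:
    """Λ(k) and its decomposition.

    saffman_taylor + weight * (1 - inner - surface) == rate, where
    weight = D_ext / (1 + D_ext).
    """

    k: int
    rate: float
    saffman_taylor: float
    inner: float
    surface: float
    weight: float


def _dext_factors(D_ext: float) -> tuple[float, float]:
    """((1 - D)/(1 + D), D/(1 + D)) with the D -> inf limits (-1, 1)."""
    if np.isinf(D_ext):
        return -1.0, 1.0
    return (1.0 - D_ext) / (1.0 + D_ext), D_ext / (1.0 + D_ext)


def inner_term(k: int, theta_n: float, theta_q: float, r_p: float,
               mu_death: float) -> float:
    """Combined inner-region perturbation term A_k (dimensionless, >= 0).

    θ_n = r_n²/r_p² and θ_q = r_q²/r_p² are the interior area fractions.
    The coincident-interface case θ_q = θ_n uses the analytic limit of the
    difference quotient, k θ^(k-1).  A_k → 0 as k → ∞ whenever r_p < 1.
    """
    if k < 1:
        raise ValueError("mode k must be >= 1")
    if not (0.0 <= theta_n <= theta_q <= 1.0) or not (0.0 < r_p < 1.0):
        raise ValueError("need 0 <= theta_n <= theta_q <= 1 and 0 < r_p < 1")
    tn_k = theta_n**k
    tq_k = theta_q**k
    if np.isclose(theta_q, theta_n, rtol=1e-12, atol=1e-300):
        quot = k * theta_n ** (k - 1)
    else:
        quot = (tq_k - tn_k) / (theta_q - theta_n)
    rp2k = r_p ** (2 * k)
    return float((1.0 - rp2k) / (1.0 - tn_k * rp2k)
                 * (mu_death * tn_k + quot * theta_q / k))


def growth_phase_discriminant(state: RadialState, mu_death: float) -> float:
    """Relative rim velocity Δ_θ = r_p'/r_p.

    Exactly 1/2 for a fully proliferative tumor (r_n = r_q = 0), 0 at a
    stationary state, negative while shrinking.
    """
    return radial_rhs(state, mu_death) / (2.0 * state.r_p**2)


def dispersion(k: int, state: RadialState, mu_death: float,
               D_ext: float = np.inf, sigma: float = 0.0) -> DispersionResult:
    """Perturbation growth rate Λ(k) with its term decomposition."""
    if k < 1:
        raise ValueError("k = 0 is not a shape mode; k must be >= 1")
    rn, rq, rp = state.as_tuple()
    if rp <= 0:
        raise ValueError("r_p must be positive")
    st_factor, weight = _dext_factors(D_ext)
    delta = growth_phase_discriminant(state, mu_death)
    st = delta * (st_factor * k - 1.0)
    A_k = inner_term(k, rn**2 / rp**2, rq**2 / rp**2, rp, mu_death)
    surf = sigma * k * (k**2 - 1) / rp**3
    rate = st + weight * (1.0 - A_k - surf)
    return DispersionResult(k=k, rate=float(rate), saffman_taylor=float(st),
                            inner=float(A_k), surface=float(surf), weight=weight)


def creeping_rate(state: RadialState, mu_death: float,
                  D_ext: float = np.inf) -> float:
    """Closed-form k = 1 (center-of-mass translation) growth rate.

    Λ(1) = D_ext/(1+D_ext) · (μ_death r_n² + r_q²)/r_p² · (r_p² - r_n²)/(1 - r_n²),

    always nonnegative: the tendency to creep toward the oxygen source
    exists whenever the tumor has interior (quiescent/necrotic) regions.
    """
    rn, rq, rp = state.as_tuple()
    if rp == 0:
        return 0.0
    _, weight = _dext_factors(D_ext)
    z, y, x = rn**2, rq**2, rp**2
    return float(weight * (mu_death * z + y) / x * (x - z) / (1.0 - z))


def sigma_bound(k: int, r_p: float) -> float:
    """Upper bound r_p³ / (k (k² - 1)) on the stabilizing surface tension."""
    if k < 2:
        raise ValueError("k = 1 is the only mode unaffected by surface tension")
    return r_p**3 / (k * (k**2 - 1))


def sigma_stable(k: int, state: RadialState, mu_death: float,
                 D_ext: float = np.inf) -> float:
    """Surface tension required to neutralize mode k at stationarity.

    At Δ_θ = 0 the rate is affine in σ, so the Λ(k) = 0 root is closed
    form: σ_k = (1 - A_k) r_p³ / (k(k²-1)) ≤ sigma_bound(k, r_p).
    """
    if k < 2:
        raise ValueError("k = 1 is the only mode unaffected by surface tension")
    rn, rq, rp = state.as_tuple()
    A_k = inner_term(k, rn**2 / rp**2, rq**2 / rp**2, rp, mu_death)
    return float((1.0 - A_k) * sigma_bound(k, rp))


def spectrum(state: RadialState, mu_death: float, k_max: int = 8,
             D_ext: float = np.inf, sigma: float = 0.0) -> list[DispersionResult]:
    """Dispersion results for k = 1..k_max."""
    return [dispersion(k, state, mu_death, D_ext, sigma) for k in range(1, k_max + 1)]
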