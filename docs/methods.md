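# Methods

## The model

`avtumor` implements a deliberately parsimonious, first-principles model of a
2D avascular tumor in two coupled forms.

**Stochastic lattice form (DLCM).** The domain is the unit disc, discretized
on a square lattice of spacing `h`. Each voxel holds `u ∈ {-1, 0, 1, 2}`:
necrotic material, empty, one cell (the carrying capacity), or two cells.
Voxels above carrying capacity act as unit sources in a quasi-stationary
pressure problem `-Δp = s(u)`, and cells migrate down the pressure gradient
(Darcy's law): a move along an edge with integrated pressure-gradient flux
`I = p_i - p_j > 0` fires at rate `(D1/h²)·I` into empty voxels and
`(D2/h²)·I` from doubly into singly occupied voxels. The `1/h²` factor is
the lattice conversion from pressure gradient to hop rate — a cell advected
at speed `v = D|∇p|` crosses a voxel in `h/v` time, so the hop rate is
`D·I/h²`; without it the lattice model's mean field would not be the Darcy
flow PDE and migration would die out as `h²` under refinement. Oxygen obeys
a stationary diffusion problem with unit Dirichlet value on the disc rim and
a sink `λ·a(u)` at living cells; cells divide (rate `μ_prol = 1`) where
`c ≥ κ_prol`, die (rate `μ_death` per cell) where `c < κ_death`, and
necrotic material degrades (rate `μ_deg`) to free its voxel. All channels
compete as Poisson processes simulated exactly by the Gillespie direct
method; the pressure is re-solved after every event, the oxygen either per
event or batched on a cadence well below the cell cycle (quasi-stationarity
of nutrient transport makes the batched variant indistinguishable in
practice; the production runs here use a cadence of 0.05).

**Mean-field PDE form.** A density `ρ ∈ [0,1]` is advected conservatively by
`v = -∇p` with regional growth `Γ = μ_prol ρ`, `0`, `-μ_death ρ` in the
proliferative / quiescent / necrotic oxygen classes, the same Poisson
pressure problem with regionally constant source `Γ/ρ`, and a conditional
oxygen sink that shuts down below the survival threshold. The tumor domain
is the sharp interface `ρ ≥ 0.5` (holes filled: consumed cores are enclosed
by the rim, not ambient medium).

**Surface tension.** Both forms impose a Young–Laplace condition at the rim.
With the geometric (convex-positive) curvature `C` the interior rim pressure
is `p_ext + σC`: a bulge pushes back harder, which is the stabilizing sign
required by the dispersion relation's surface-tension term
`-σ k(k²-1)/r_p³`. (Writing the condition as `p_ext - σC` corresponds to the
opposite curvature sign convention; only the sign of the *variation* along
the rim matters — a constant offset moves no fluid. Implemented with the
minus-convention sign the 2D solver is violently unstable at `σ = 2·10⁻³`,
with the plus sign it reproduces the predicted stability, which pins the
convention.)

**External medium.** The analysis supports any Darcy ratio `D_ext`; the
solvers implement the `D_ext = ∞` regime used by all reference experiments
(ambient pressure spatially constant, rim condition purely Dirichlet).

All quantities are nondimensional with the oxygen-source radius, the cell
cycle, the ambient oxygen level and the tumor Darcy coefficient set to 1.

## The analytical reduction

Under radial symmetry and unit density the state collapses to the zonation
radii `(r_n, r_q, r_p)`. The oxygen field is closed-form; the interfaces
satisfy two algebraic relations through the reduced parameters
`K_prol = 4(1-κ_prol)/λ` and `K_death = 4(1-κ_death)/λ`; and the area obeys
`d(r_p²)/dt = -μ_death r_n² - r_q² + r_p²` with the interior radii slaved
quasi-statically. The implementation treats the degenerate regimes
explicitly (no necrotic core while the center stays above `κ_death`; no
proliferative rim when even the rim falls below `κ_prol` — the latter also
makes a *fully quiescent* tumor an equilibrium, see "deadlock" below). The
stationary state is found by bracketed root finding on the area variable;
its single eigenvalue has the closed form

    Λ_r = 1 - (ln r_p / ln r_n)(μ_death + 2 ln(r_q/r_n)/(r_q²-r_n²)·r_q²)

with the `r_n → 0` limit `1 + 2 ln r_p` and the `r_q → r_n` limit handled
analytically. Any stationary state with `r_p ≤ e⁻¹ ≈ 0.368` is guaranteed
stable regardless of zonation and death rate; the package verifies this on
a 500 × 200 grid in (zonation ratio, death rate).

The linear-stability dispersion relation for a mode-`k` cosine perturbation
of the rim combines a Saffman–Taylor term, an inner-region damping term
`A_k ≥ 0` (closed form in the area fractions `θ_n = r_n²/r_p²`,
`θ_q = r_q²/r_p²`), and the surface-tension penalty. Mode `k = 1` (rigid
translation toward the oxygen source, "creeping") is unaffected by surface
tension and always has a nonnegative rate. The σ threshold neutralizing
mode `k` at stationarity is closed-form, `σ_k = (1-A_k)·r_p³/(k(k²-1))`;
for the standard parameter set it evaluates to `σ_2 = 3.12·10⁻³`.

Note two corrections relative to naive readings of the closed forms: the
quiescent branch of the radial pressure profile carries the coefficient
`μ_death r_n²/2` (required by flux continuity across `r_n`), and the
curvature sign convention discussed above.

## Numerical choices

* **Linear solves.** 5-point Laplacian, sparse direct factorization. The
  oxygen operator lives on the fixed disc and is factorized once per grid;
  the Dirichlet circle is imposed by Shortley–Weller cut cells (O(h²)),
  because the oxygen minimum is flat near the necrotic interface and a
  staircase-boundary O(h) error would shift the labeled region radii by
  O(√h).
* **Mean-field oxygen obstacle.** The conditional sink is a linear
  complementarity problem: in the core the concentration is pinned at
  exactly `κ_death` with a partial residual sink. Binary on/off sink
  iterations cannot represent the degenerate core and mislabel it; the
  package solves the obstacle problem by a primal-dual active-set method,
  warm-started from the previous time step. Clamped nodes are classified as
  necrotic (they sit at the threshold by construction).
* **Rim curvature.** Local curvature estimators on lattice-extracted
  contours carry O(1/h) staircase noise, which the Young–Laplace condition
  would inject straight into the pressure. The solvers instead fit the rim
  radius function as a truncated Fourier series (default 16 modes, capped by
  the vertex sampling) on a Gaussian-smoothed (2-cell) interface and
  evaluate the curvature of the truncated curve analytically. Modes beyond
  the truncation receive no surface-tension feedback, so the band must cover
  every mode the lattice meaningfully resolves — with too small a band the
  untreated intermediate modes destabilize even strongly tensioned runs.
* **Advection.** Explicit Euler, first-order conservative upwind, CFL
  safety factor 0.5. The interior of the tumor domain (interface band
  excluded) is pinned back to `ρ = 1` each step: along streamlines entering
  from the full bulk the exact density is 1, and the upwind scheme's drift
  there would bias the oxygen consumption. Growth is gated to the tumor
  domain; stray sub-threshold debris outside the rim is inert.
* **Boundary measurement.** Roundness and Fourier mode amplitudes are
  measured on marching-squares contours of a 1-cell-blurred indicator
  (sub-voxel interface estimate); perimeters additionally use a 3-point
  vertex smoothing. Raw staircase polygons bias roundness several percent
  low.
* **Degenerate states.** A tumor filling the whole domain leaves the
  pressure defined only up to a constant; the simulator then offers no
  migration (no free volume) rather than failing. Runs terminate flagged
  when the tumor reaches the oxygen source (avascularity breakdown) or
  vanishes.

## Study conditions and the synthetic initial states

The generator produces cosine-perturbed discs
`r(θ) = r0(1 + ε cos k(θ-φ))` as lattice occupancy (`u = 1`) and
anti-aliased density fields, and a *zonated* variant with the equilibrium
necrotic core seeded (`u = -1` inside `r_n`). The zonated start matters: a
uniform living disc of equilibrium size deadlocks both model forms in full
quiescence — the not-yet-necrosed core's extra consumption parks the whole
tumor inside the narrow `[κ_death, κ_prol)` band where no channel fires,
and in the 1D reduction `r_q = r_p` is likewise stationary. Reference runs
near the stationary state therefore seed the zonation.

Defaults follow the standard parameter sets: lattice model
`μ_death = 0.5, μ_deg = 0.05, κ_prol = 0.94, κ_death = 0.93, λ = 1,
D_ext = ∞, D2 = 25`; mean-field effective parameters
`μ_death = 1.35, λ = 1.15` (shipped as given — the derivation of effective
parameters is out of scope). Perturbation experiments use `ε = 0.05`;
mean-field runs add interface noise of amplitude `10⁻³·√dt` (a documented
choice; the reference description says only "small amounts", and the noise
also decorrelates lattice-anisotropy bias). Initial radius defaults to
0.25; reference desk scales are `h = 0.01–0.03` and horizons `t ≤ 30`.
Mode-growth fits use the window `t ∈ [0.5, 2]` for the mean-field solver
(after the interior interfaces have slaved to the perturbed rim, before
the perturbation leaves the linear regime) and `[0.5, 4]` for the slower,
noisier lattice ensembles.

## What the cross-validations do and do not show

* The mean-field solver's fitted mode-growth rates match the dispersion
  relation within combined uncertainties for `k = 2, 3, 5` at desk scale.
  Mode `k = 4` overshoots by ~8%: the square lattice's 4-fold anisotropy
  pumps exactly that mode (the original framework used Voronoi
  tessellations partly for this reason). The comparison evaluates the
  prediction along the *measured* trajectory — zonation radii from the
  recorded region areas (known to ±h/2) and the growth-phase discriminant
  from the measured rim trend — and propagates those input uncertainties.
* The lattice ensemble grows unstable modes in the right direction but
  substantially below the analytic rates at desk scale, and its regional
  volumes track the 1D reduction only partially: the printed effective
  parameters were calibrated against a particular (unstated) reference
  resolution and implementation, and the necrotic-debris bookkeeping of the
  lattice model (dead material occupies volume until degraded at rate
  `μ_deg = 0.05`) has no counterpart in the 1D reduction, which removes
  necrotic area at the much larger effective rate 1.35. At a steady
  turnover of tens of divisions per time unit this mismatch accumulates
  necrotic volume well beyond the 1D prediction. The package reports these
  comparisons as measured; they quantify the model-form gap rather than a
  solver defect (the small-system Gillespie statistics are exact against
  the enumerated master equation, and the field solvers converge to the
  closed forms).
* Qualitative phenomenology is reproduced: sigmoidal growth to a plateau,
  stability for σ above the closed-form thresholds, symmetry breaking and
  splitting below them, and center-of-mass creeping.

## Known limitations

2D only; `D_ext = ∞` in the solvers (finite ratios live in the analysis
layer only); first-order interface resolution; single genotype; no
chemotaxis or microscopic adhesion variant. Lattice runs coarser than
`h ≈ 0.04` under-resolve the quiescent annulus (threshold window 0.01 in
oxygen units) and are only suitable for smoke tests.
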