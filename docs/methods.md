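# Methods

## Model

The state is a pair of nonnegative densities `(u₁, u₂)` (prey,
predator). Prey grow logistically toward a carrying capacity `κ` at
intrinsic rate `γ₁`, are consumed at rate `γ₂u₁^σ u₂`, and are harvested
with the saturating (Michaelis–Menten) term `ρ₁ρ₂u₁/(ρ₂ρ₃ + ρ₄u₁)`.
Predators convert consumed prey with efficiency `γ₄` and die at rate
`γ₃`. The exponent `σ` (examples use `0 < σ < 1`) encodes group defense:
the predation rate per prey falls as prey density rises. Time evolution
uses the Caputo derivative of order `θ ∈ (0, 1]`, which keeps classical
initial conditions while adding a power-law memory kernel; `θ = 1` is
the classical limit.

All ten constants must be strictly positive. The harvest constants enter
only through the products `ρ₁ρ₂`, `ρ₂ρ₃` and through `ρ₄`, a direct
consequence of the functional form; the composite config style
(`a, b, c_pred, c_gain, m, sigma, h_num, h_den0, rho4`) exists because
some parameterisations are stated only at that level and cannot be
resolved uniquely into ten constants.

A structural consequence of `σ < 1` worth knowing before simulating:
the predation term is non-Lipschitz in `u₁` at `u₁ = 0`, so a
sufficiently predator-heavy state can drive the prey to **exact
extinction in finite time** in the classical limit. This is genuine
dynamics, not numerical failure (a tight adaptive Runge–Kutta reference
reproduces it). The solver's positivity clamp absorbs such paths at a
floor of 1e−12 and counts every clamp in `Trajectory.clamped_count`, so
absorbed runs are always identifiable.

## Equilibria

- Extinction `(0, 0)` always exists.
- Predator-free states solve
  `γ₁(1 − u₁/κ) = ρ₁ρ₂/(ρ₂ρ₃ + ρ₄u₁)`, expanded from first principles
  into the monic quadratic
  `u₁² − (κ − ρ₂ρ₃/ρ₄)u₁ − κ(ρ₂ρ₃ − ρ₁ρ₂/γ₁)/ρ₄ = 0` with `κ`
  retained. A historically printed closed form for these roots is only
  dimensionally consistent at `κ = 1`; it is kept in
  `equilibria.printed_boundary_roots` purely as a `κ = 1` regression
  oracle. Negative or complex roots are filtered out as biologically
  inadmissible.
- Coexistence: the predator nullcline gives
  `u₁* = (γ₃/(γ₂γ₄))^{1/σ}`, and substituting into the prey nullcline
  gives
  `u₂* = u₁*^{1−σ}[γ₁(1 − u₁*/κ) − ρ₁ρ₂/(ρ₂ρ₃ + ρ₄u₁*)]/γ₂`.
  The state is admitted iff `u₂* > 0`; that positivity test *is* the
  existence condition used (printed inequality variants of it are
  algebraically inconsistent across sources for this model).

Every equilibrium the package returns is verified against the vector
field to an infinity-norm residual below 1e−9, and the closed-form
`u₁*` is cross-checked in the tests against an independent bracketing
root solve of the predator nullcline.

## Stability

Fractional linear stability follows the Matignon criterion: with
Jacobian eigenvalues `λ₁, λ₂`, the equilibrium is asymptotically stable
iff `|arg λᵢ| > θπ/2` for both, a saddle if the arguments straddle the
threshold, unstable if some argument falls strictly inside. Eigenvalues
come from the closed-form quadratic `(α ± √(α² − 4β))/2` (trace `α`,
determinant `β`) rather than a general eigensolver, for exact
reproducibility. Comparisons use absolute tolerance 1e−10 on arguments;
eigenvalues within 1e−12 of the origin, or arguments within tolerance of
the threshold, return `inconclusive` rather than a guess.

Structural identities at coexistence, asserted in the tests over
generated parameter sets: the lower-right Jacobian entry vanishes
exactly (by definition of `u₁*`), hence
`β = σγ₂²γ₄u₁*^{2σ−1}u₂* > 0` — the coexistence state is never a
saddle.

The boundary-state classifier generalises the printed case analysis,
which pairs "stable" with a *positive* second eigenvalue; a positive
real eigenvalue is unstable for every `θ` under Matignon, so
classification is by eigenvalue signs with the sign pattern recorded in
`theorem_branch` for traceability.

## Critical fractional order

For a complex pair `ϑ ± iψ` with `ϑ = α/2 > 0`,
`ψ = √(4β − α²)/2`, the crossing function
`p(θ) = θπ/2 − min|arg λᵢ|` is affine in `θ` with slope exactly `π/2`
(the transversality value, returned explicitly), and its root

    θ₀ = (2/π)·arctan(ψ/ϑ)

is the order at which stability is lost. The complex-pair condition is
`α² − 4β < 0`; a printed statement of this result carries the opposite
discriminant inequality, contradicted by its own derivation, and the
`HopfAnalysis.condition_note` records both readings. `θ₀ ≥ 1` would be
reported as out of range rather than clamped, though for a genuine
complex pair with `ϑ > 0` the arctangent keeps `θ₀ < 1` automatically.
`scan_theta` re-derives `θ₀` by grid search plus bisection on `p` to
1e−9 and serves as the independent oracle in the tests.

Both worked-example parameter sets have `α < 0` at coexistence
(−0.0155 and −0.0212), so no critical order exists for them and the
package reports exactly that, together with its own `α, β`. Their
simulated oscillations at `θ` near 1 are weakly damped transients of a
stable focus (`Re λ ≈ −0.0077` for the first example), not limit
cycles; the `scan` command reports tail amplitudes without asserting a
qualitative claim either way.

## Analytic constants

- `lipschitz_bound(params, K)` evaluates, term by term, the constant
  bounding the vector field's increments on the box
  `max(|u₁|, |u₂|) < K`. One factor appears in the source derivation as
  `ρ₁ρ₄/ρ₄` (trivially `ρ₁`); it is carried literally because the
  intended expression is unknowable and the constant is only reported,
  never consumed downstream. The bound is monotone nondecreasing in `K`
  for `K ≥ 1` (asserted on a grid).
- `asymptotic_bound` gives the long-time cap on the weighted biomass
  `U = γ₄u₁ + u₂`. Completing the square in
  `D^θU + γ₃U ≤ γ₄γ₁u₁(γ₁+γ₃)/γ₁ − …` yields the forcing constant
  `M = γ₄κ(γ₁+γ₃)²/(4γ₁)`, and the Mittag-Leffler comparison limit is
  `M/γ₃`, i.e. `γ₄κ(γ₁+γ₃)²/(4γ₁γ₃)` — the default, asserted
  dynamically against trajectories with 5 % slack. The variant
  `as_printed`, `γ₄(γ₁+γ₃)²/(4κγ₁)`, is retained for fidelity with the
  source derivation; for the first worked example it equals 0.09, which
  is *below* the equilibrium's own biomass 0.2604 and therefore cannot
  attract — it is exposed but never asserted.

## Numerical scheme

The solver is the Adams–Bashforth–Moulton predictor–corrector (PECE)
for the Volterra form of the Caputo problem, on a uniform grid with
full memory: fractional rectangle-rule predictor (weights
`(h^θ/θ)[(n+1−j)^θ − (n−j)^θ]`), fractional trapezoid corrector
(standard `a_{j,n+1}` weights with `Γ(θ+2)` normalisation), one
corrector sweep by default. Weight tables are precomputed as power
differences so each step costs one dot product with the stored
vector-field history. At `θ = 1` the weights collapse to the classical
Euler/trapezoid pair and the sums telescope, so that limit runs with
O(1) work per step. Expected accuracy for smooth solutions is order
`min(2, 1+θ)`; the tests measure empirical order ≥ 1 on the linear
benchmark at `θ ∈ {0.5, 0.78, 0.9}` and agreement with `E_{1/2}(−1) =
e·erfc(1)` to 2e−4 at `h = 1/2048`.

Defaults for model runs: `h = 0.05`, `t_end = 500`, initial state
`(0.3, 0.3)` — all config-overridable and recorded in every
`Trajectory`. The positivity floor is 1e−12; clamps are counted, and on
well-resolved runs inside the coexistence basin the count is zero
(asserted in the tests at `h = 0.0125`). The in-package Mittag-Leffler
series (`|z| ≤ 50`, term-ratio controlled) exists as a validation
oracle and for bound reporting, deliberately independent of the
time-stepping code.

## Synthetic parameter generator

`generate` draws the ten constants uniformly from per-parameter ranges
(defaults `γ₁, γ₂ ∈ [0.5, 1.5]`, `γ₃ ∈ [0.05, 0.5]`, `γ₄ ∈ [0.1, 0.5]`,
`κ ∈ [0.5, 3]`, `σ ∈ [0.2, 0.9]`, `ρ₁ ∈ [0, 0.3]`, `ρ₂ ∈ [0.5, 1.5]`,
`ρ₃ ∈ [0.1, 0.5]`, `ρ₄ ∈ [0.5, 1.5]`, chosen once to bracket both
worked examples) and keeps a draw when the trace/determinant pair at
coexistence satisfies the requested regime: stable node (`α < 0`,
`α² − 4β ≥ 0`), stable focus (`α < 0`, `α² − 4β < 0`), Hopf-capable
(`α > 0`, `α² − 4β < 0`, `θ₀ ∈ (0.05, 0.95)` so both sides of the flip
are admissible orders), or no coexistence (`u₂* ≤ 0`). Sampling is
deterministic per seed; a 1e5-draw budget guards against infeasible
range choices. Emitted certificates `(α, β, θ₀)` are never trusted by
the tests — they are re-derived through the analysis modules.

What the generator emulates is the *analytic* structure the theory
quantifies over (existence of coexistence, sign and discriminant of the
trace/determinant pair), not ecological field data: passing tests show
the closed forms, classifiers and solver are mutually consistent across
that structure, and say nothing about parameter values fitted to real
populations.

## Worked-example fixtures

The first example transcribes directly and reproduces its reported
coexistence state `(0.4096, 0.1580)` with `u₁* = 0.8⁴` exactly. The
second example's literal ten-constant list is internally inconsistent —
its implied predator gain `γ₂γ₄ = 2.5` forces `u₁* ≈ 5e−5`, far from
the reported `(0.4168, 0.1465)` — so the default fixture is the
reconciled composite reading (growth `0.999 − 0.998u₁`, `γ₂ = 0.9`,
`γ₂γ₄ = 0.25`, `σ = 0.255`, harvest products `0.22` and `0.25`,
`ρ₄ = 1`), the unique reading found that reproduces both reported
coordinates to 4 decimal places; `u₁* = 0.8^{1/0.255}` exactly. The
literal list ships as `example_7_2_literal` so the discrepancy remains
auditable, and the tests document it with values the package itself
computes.

Reported critical orders of 0.83 and 0.778 attached to these two
parameter sets are not recoverable from the trace/determinant analysis
under any consistent reading tried — both sets have `α < 0`, which
rules out a crossing order altogether. The package surfaces its own
`α`, `β` and a reason string instead of matching those values, and the
critical-order machinery is validated property-wise on generated
Hopf-capable sets (closed form vs bisection to 1e−8, Matignon label
flip across `θ₀ ± 0.01`).

## Problem sizes and tolerances in the shipped tests

Equilibrium residuals 1e−9; closed-form vs root-solve 1e−10; structural
identities 1e−12 over 500 generated sets; Matignon vs case-analysis
agreement over 1000 random matrices; critical-order equivalence over
300 Hopf-capable sets; solver benchmarks at `h = 1/2048` (value) and
`h ∈ {1/512, 1/1024}` (order); classical-limit comparison at
`h = 1e−3` over `t ∈ [0, 50]`; dissipativity over 50 stable scenarios
to `t_end = 500` at `h = 0.05` with the bound checked on the `t > 400`
tail at 5 % slack. These sizes keep the whole suite under a minute on
one core while exercising every closed form against an independent
route.

## Known limitations

- Full-memory ABM is O(N²) in the step count; no short-memory or
  adaptive variants are provided.
- The Mittag-Leffler series loses precision to cancellation for large
  negative arguments; the `|z| ≤ 50` cap is enforced and tests use
  moderate arguments.
- Marginal (`|arg λ| = θπ/2`) cases are reported `inconclusive`; the
  multiplicity-based refinement of marginal stability is out of scope
  for the 2×2 distinct-eigenvalue setting handled here.
- Global dynamics (basins, limit-cycle amplitudes, bifurcation
  direction/normal forms) are not computed; `oscillation_stats` is a
  descriptive tail summary, not a limit-cycle detector.
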