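# Methods

## Model and assumptions

The SNITR model is a mean-field compartmental ODE on the densities of
five user states — susceptible (S), neglected (N), infected (I),
transmitter (T), recovered (R) — in an open social network. Users join
and leave at the same constant rate μ, keeping the total density at 1;
joiners enter susceptible. All contact processes are mass-action
(bilinear): rumor exposure converts susceptibles to infected,
transmitter or neglected users at rates α₁, α₂, α₃; neglected users
convert onward at β₁, β₂, β₃; infected users recover at γ₁ or switch to
truth-telling at ε; transmitters recover at γ₂. All rates are
proportions per unit time in (0, 1]; ε may be zero (one published
configuration uses it). The sums α₁+α₂+α₃, β₁+β₂+β₃ and γ₁+ε are
nominally bounded by 1; because two published sweep configurations
violate the α-bound, the package treats these sum constraints as
warnings at construction and enforces them only in strict file loading.

The recovered equation is redundant (R = 1 − S − N − I − T), so all
analysis uses the reduced 4-D system. Summing the five right-hand sides
gives μ(1 − total), an exact algebraic identity the test suite checks;
it makes the simplex invariant.

The model is dimensionless in time. Where the synthetic data emulate
wall-clock series, model time maps to hours 1:1 by default
(configurable); nothing in the dynamics fixes this correspondence.

## Equilibria

`closed_form_equilibria` evaluates the published closed-form candidates
E0–E6, indexed by which of N, I, T are nonzero. Only E0 = (1,0,0,0) is
unconditionally a root. Several of the printed higher expressions carry
algebraic defects (the transmitter-free point E2 is written with the
transmitter rates α₂, γ₂; the E6 display references unsubscripted
symbols, for which S6 and N6 are substituted). They are therefore
evaluated exactly as printed, and every candidate carries the max-norm
residual of the vector field plus a feasibility flag; zero denominators
yield an "undefined" point rather than an exception. The numeric root
finder (`scipy.optimize.root`, hybrid Powell, residual < 1e−10) is the
source of truth; `consistency_report` tabulates, per candidate, whether
it is a genuine root and its distance to the nearest numeric root.
Numeric roots are labelled by their occupancy pattern, not by which
closed form seeded the search. In the published coexistence
configuration the long-run attractor has N = 0 (an E4-type root), not
the full-interior pattern its printed steady state suggests; the test
suite asserts what the dynamics actually do.

## Stability

Reproduction numbers come from the next-generation construction at the
rumor-free state in compartment order (I, T, N): F = diag(α₁, α₂, α₃),
V the transition matrix with the single coupling −ε, and K = FV⁻¹
lower-triangular, so its eigenvalues are the diagonal ratios R01, R02,
R03. Local stability uses the analytic Jacobian of the reduced field,
differentiated from the vector field itself rather than transcribed
from the published displays (which contain subscript typos); agreement
with the published rumor-free eigenvalues {−μ, α₃−β₃−μ, α₁−ε−γ₁−μ,
α₂−γ₂−μ} is a regression test. Classification is by eigenvalue real
parts with a ±1e−9 marginal band (configurable), cross-checked against
the Routh–Hurwitz determinants Δ₁ = a₃, Δ₂ = a₃a₂−a₁,
Δ₃ = a₃a₂a₁−a₃²a₀−a₁², Δ₄ = a₀Δ₃ of the characteristic quartic.

Global stability of the rumor-free state in the fully subcritical
regime is verified empirically, not symbolically (the published
Lyapunov derivative computation mixes compartments): the package
integrates from seeded uniform draws on the simplex and reports the
fraction converging to within 1e−4 of (1,0,0,0), together with whether
the quadratic distance function ½(k₀I² + k₁(1−S)²) — the
distance-to-equilibrium analogue of the quadratic Lyapunov candidate,
with k₀ = k₁ = 1 by default since only positivity is required — is
non-increasing over the final half of each trajectory.

## Numerical choices

Integration is adaptive Runge–Kutta (RK45) with rtol 1e−8 / atol 1e−10,
sampled on a uniform output grid (both configurable). Trajectories are
checked for conservation drift below 1e−6 and densities within 1e−9 of
[0, 1], then clipped. Steady state is declared when the reduced-field
max-norm at the endpoint falls below 1e−8. Equilibrium feasibility
tolerates 1e−9 excursions. The intervention experiment zeroes the
transmitter-generating rates by setting α₂ = β₂ = 1e−12 and ε = 0
(α₂, β₂ are constrained strictly positive elsewhere; 1e−12 is
dynamically indistinguishable from zero on these horizons).

## Simulation studies

The default initial condition for density experiments is
(S,N,I,T,R) = (0.90, 0.04, 0.04, 0.02, 0): a mostly susceptible network
with small seeds in every active compartment. The published analyses
never state their initial condition; closed-form quantities do not
depend on it and the convergence claims are robust to it (the test
suite uses random simplex starts as well).

Sweeps rerun the model for each value of one rate on a shared initial
condition and grid, summarising peak density, time of peak and final
density of a chosen compartment; values that break a sum constraint are
flagged in the summary rather than dropped, since two published sweep
bases already violate the α-sum bound. Sensitivity grids evaluate an
R0 component pointwise on 1- or 2-parameter grids; their
monotonicities (R01 rising in α₁, falling in ε, γ₁, μ; analogously for
R02, R03) follow directly from the closed forms and are asserted on
every grid.

The intervention experiment models delayed entry of truth-tellers: on
[0, t_enter) all transmitter-generating pathways are gated off, then at
t_enter the pathways are restored and a small fraction (default 1%) of
the susceptible density is converted to transmitters, conserving total
density; t_enter = 0 reproduces the unmodified model. This gating
mechanism is this package's own construction — the source analyses do
not specify one, nor the rates behind their figures — so only the
ordering claims are asserted: over an entry-time grid the peak infected
density is non-decreasing and the peak transmitter density
non-increasing (within 1e−4, the resolution of peak sampling on the
output grid). The default intervention configuration
(μ=0.05, α₁=0.6, α₂=0.25, α₃=0.1, β₁=β₂=0.3, β₃=0.1, γ₁=γ₂=ε=0.1,
start (0.9, 0.04, 0.06, 0, 0)) was chosen so the gated rumor genuinely
spreads (α₁ ≫ γ₁+μ) and the activated transmitter pathway suppresses
it; the unopposed infected peak (~0.48, stabilising for entries later
than ~12) mirrors the qualitative regime of the published
entry-timing figures, whose exact values are not reproducible.

## Synthetic data

The generator emulates the structure of the real validation data:
repost counts of rumor posts aggregated into 10-minute bins over 65
hours, an engaged population of 12,372 reposting users, and a 30 h
fitting / 35 h validation split. Ground truth defaults to the
data-derived rate estimates (μ=0.001, α₁=0.3553, α₂=0.1168, α₃=0.4315,
β₁=0.4772, β₂=0.07, β₃=0.2351, ε=0.0951, γ₁=0.4984, γ₂=0.0023) — the
only published data-derived configuration. The model is integrated
once on a grid containing the bin midpoints, so noiseless samples equal
the trajectory exactly; Poisson noise draws counts with mean
population × density and rescales; Gaussian noise adds seeded zero-mean
perturbations clipped at zero. Identical configurations (including
seed) produce identical bytes.

What the generator does not emulate: network topology, user-level
cascades, diurnal activity cycles, reporting delays, or any
model-misspecification error. Passing round-trip tests therefore show
that the pipeline recovers what the model can represent under counting
noise — not that the model is correct for any particular real corpus.

## Fitting

The observable is I(t)+T(t) — the density analogue of binned repost
activity. `fit_snitr` minimises the residual sum of squares over the
fitting window only, with every rate box-bounded to [0.001, 0.999],
using bounded trust-region least squares (`scipy.optimize.least_squares`,
trf, Jacobian column scaling). The initial state is co-estimated on the
simplex via a stick-breaking parameterisation (optionally pinned). The
optimiser screens 64 seeded Latin-hypercube candidates by objective
value, refines the best 16 (defaults; both configurable), then polishes
the best refined start in two stages with finite-difference steps 1e−6
and 1e−7. The objective is integrated at rtol 1e−8 precisely so those
steps stay above the solver noise floor; with looser integration the
numerical gradients degrade and convergence stalls. The returned
objective value never exceeds the objective at any start (monotone
improvement), and results are deterministic given the config seed.

"Fit coefficient" is defined here as the coefficient of determination
R² = 1 − SS_res/SS_tot on a stated window; the term is not otherwise
pinned down in the source analyses, and R² is the standard statistic
bounded near the reported magnitudes. `fit_and_validate` fits on the
fitting window, integrates forward and scores R² on the held-out
validation window only.

With only the I+T aggregate observed, the ten-rate model is not
practically identifiable: deeply converged fits reach residual sums of
squares below 1e−10 at rate vectors far from the generating truth.
Quality is therefore judged on curve recovery — fitted-curve RMSE over
both windows and held-out R² — never on recovering individual rates.
Extrapolation accuracy degrades along the objective's flat valley, which
is why the deep polish stages matter for noiseless round-trips.

## Problem sizes used in the test suite

The test and acceptance runs use the full observation design (390 bins,
180 in the fitting window). The noiseless round-trip fit refines 4
screened starts before polishing; the Poisson-noise replicate study
(population 12,372, 20 seeds) uses a reduced budget (2 refined starts,
no polish) since counting noise, not optimiser depth, dominates its
error. Property tests use 50–1,000 random draws per invariant.

## Known limitations

- Mean-field only: no network structure, degree heterogeneity or
  stochastic extinction.
- The printed closed forms for the higher equilibria are reproduced
  as printed, defects included; they are diagnostics, not truth.
- Global stability is checked empirically over random starts, which
  cannot prove the property.
- Rate estimates from I+T data are non-identifiable; only the fitted
  curve, not the rates, should be interpreted.
- The hours↔model-time convention in the synthetic generator is a
  choice, not an inference.
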