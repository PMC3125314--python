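# Methods

## The modeling framework

`robnet` analyzes biomolecular ODE networks whose right-hand sides are
sums of *property-tagged* interaction terms,

    dx_i/dt =  sum_j a_ij(.) x_j  -  sum_h b_ih(.) x_h
             + sum_s c_is(.)      +  sum_l d_il(.),

where `a` terms are production rates linear in a source species, `b` terms
degradation or conversion rates, `c` terms saturating production inputs and
`d` terms decreasing saturating production inputs.  A qualitative model
fixes only the *shape class* of each coefficient function — one of ten
tags: nonnegative or positive constants; sigmoids (zero value and slope at
the origin, finite limit, unimodal derivative) and their complements;
constant-plus-(complementary-)sigmoids; strictly increasing functions with
a finite limit and decreasing derivative; strictly decreasing functions
with a null limit and increasing derivative; decreasing functions that are
exactly zero above a threshold; and increasing unbounded functions.

The standing assumptions are: all functions are nonnegative and C¹;
production and degradation vanish when their driving species is absent;
conversion coefficients acting on an off-target species vanish when the
*target* is zero (so the nonnegative orthant is invariant); `c` terms are
non-decreasing with a positive saturation level and `d` terms
non-increasing with a positive value at zero.  `validate_model` checks the
structural part of these assumptions per term and names the violated
assumption in its diagnostics (labeled A1–A5: smoothness, vanishing
production/degradation at an absent driver, monotonicity in the driven
species, saturation of `c`/`d` terms, and vanishing conversion at the
target's lower saturation level); the functional part (e.g. that a conversion
coefficient truly vanishes at the lower saturation level) is spot-checked
numerically on every concrete instance.  As a deliberate degenerate
allowance, a `c` or `d` term may carry the nonnegative-constant tag even
though a zero constant violates the positive-saturation strictness; this
admits limiting cases (a switched-off input) without a separate model.

Inputs are constant pseudo-states appended after the states; a caller may
bind a time function instead.  Arguments of the form `total - sum(states)`
(affine arguments) express conserved totals in reduced models.

## Structural robustness, computationally

A property is structurally robust when every member of the family of
systems sharing the qualitative structure satisfies it.  The family is
realized by seeded sampling (`ensemble`): each term receives a parametric
family matching its tag — Hill sigmoids `A x^H/(K^H + x^H)` and their
complements, Michaelis–Menten saturations `A x/(K + x)`, hyperbolic decays
`A K/(K + x)`, C¹-smoothed threshold hinges, linear unbounded terms —
with rates, amplitudes and half-saturations drawn log-uniformly
(default range 10⁻²–10²) and Hill exponents integer-uniform on {2..4}
(exponent 1 is the Michaelis–Menten shape, which belongs to a different
tag).  Coupled terms (one reaction's outflow feeding another term) share
the identical function object.  Sub-seeds come from `SeedSequence.spawn`,
so inserting draws in one member never perturbs another.  Every sampled
function is re-verified against its tag before use.

The smoothed hinge (decreasing-exactly-null class) blends the linear ramp
into zero over `[theta - theta/20, theta]` with a cubic, keeping the C¹
smoothness assumption while preserving the exact-zero tail.

`verify_property` tests a tag's predicate list on a geometric grid
(default up to 10⁴ times the function's characteristic scale): sign,
monotonicity (strictness threshold 10⁻¹³ of the function's magnitude),
value and slope at the origin (a near-origin secant compared against the
characteristic slope, threshold 10⁻²), limits by two probes a decade apart
at relative tolerance 10⁻³, an exact-null tail at 10⁻⁹ relative, and
derivative unimodality by sign changes of increments with a 10⁻⁸ dead
band.  These grid checks are falsification tests, not proofs; all
packaged families pass their documented tags and fail the documented
mis-pairings.

## Certificates

All certificates are *sampling-based*: seeded Halton points at a
configurable density (defaults 20 000 interior samples, 2 000 boundary
samples per constraint).  Halton points form a deterministic prefix
sequence, so increasing the density can only worsen a reported margin —
a failing certificate can never be rescued by sampling more.

* **Piecewise-linear Lyapunov decrease.**  `V(x) = max_k g_k·(x - x*)`;
  the weighted 1-norm preset uses all `±w_i` gradient sign patterns.  The
  generalized derivative at a sample is the maximum of `g·f(x)` over the
  active pieces (within 10⁻⁹·(1+V) of the max).  The certificate holds
  when the derivative is negative at every sample outside an exclusion
  ball (default radius 10⁻³ of the box scale — the ratio `-dV/V`
  degenerates at the center); the estimated exponential rate is the worst
  sampled ratio, i.e. the linear comparison function.
* **Nagumo invariance.**  For a set `{s_i(x) <= sigma_i}`, boundary points
  of each constraint (projections of box samples, kept feasible for the
  other constraints) must satisfy `grad s_i · f <= 0` up to a slack of
  10⁻⁸ of the field's median magnitude.
* **Order sectors.**  The sector through an equilibrium given by a
  per-coordinate `>=` / `<=` pattern is checked on each face
  `x_i = x_i*`: the field must not point out of the sector.  A passing
  sector certificate rules out over- and undershoot, which is also
  checked directly by counting dead-banded sign changes of
  `x_i(t) - x_i*` along trajectories.
* **Decay rates** are least-squares slopes of `log V` over the window
  `V > 10⁻⁸ V(0)`, with a warning if `V` is non-monotone there.

## Dynamics and equilibria

Simulation uses LSODA with `rtol = 10⁻⁸`, `atol = 10⁻¹⁰` (certificate
margins are small; loose tolerances would alias as violations).  Negative
excursions within `10·atol` are clamped to zero; anything larger fails
the run as a model error rather than solver noise.  Steadiness is the
scale-free test `||f(x)||_inf < 10⁻⁹ (1 + ||x||_inf)`.

`invariant_box` propagates the saturation argument: each state's bounded
production ceiling divided by its linear degradation floor, iterated to a
fixed point through the dependency order, `+inf` where no bound is
derivable.  When every state has a constant degradation floor and a
state-independent production ceiling, the total concentration is also
trapped below (total production)/(min floor) — for the two-species
annihilation module this is the bound `kappa = (c1+c2)/min(b11,b22)`.

Equilibria are found by multistart root finding inside the (capped)
invariant box: scrambled-Halton starts, a Powell hybrid solve first, and —
because assembled fields are flat outside conserved-pool simplices, which
strands Newton steps — a bounded trust-region least-squares retry with a
Newton polish.  Roots are deduplicated within `10⁻⁶` of the box scale and
must re-verify `||f||_inf < 10⁻⁹ (1+||x||_inf)`.  Classification uses the
central-difference Jacobian (step `sqrt(eps)·(1+|x_j|)`) with a `10⁻⁶`
dead band on real parts; near-marginal equilibria are reported as
`marginal` and excluded from stability-pattern claims, which assume simple
equilibria.  Scans over an input accept informed extra starts from a
semi-analytic reduction where one exists; every accepted root is polished
and residual-checked identically regardless of provenance.

`detect_conserved_sums` samples random states, stacks right-hand-side
vectors, takes the SVD left null space, reduces the basis to row-echelon
form (so moiety generators come out sparse rather than as arbitrary
orthonormal mixtures) and rationalizes weights with denominator ≤ 12.

## Case studies

**L-arabinose feedforward.**  Two states, hierarchical; the equilibrium is
solved sequentially in closed form and cross-checked by multistart.
Claims: a unique stable equilibrium and steady states increasing in the
CRP input.  Defaults: unit degradation, basal rate 0.2, Hill activations
with `K = 1`, `H = 2`, an increasing Michaelis–Menten modulation of the
output by AraC (`K = 0.5`).

**sRNA silencing.**  `dx1/dt = c1 - b11 x1 - k x1 x2`,
`dx2/dt = c2 - b22 x2 - k x1 x2`, with the coupled conversion terms
sharing `k`.  The default instance is the unit one (all parameters 1),
whose equilibrium is the closed-form root of `1 - x - x² = 0`,
`x = (sqrt(5)-1)/2`, with Jacobian eigenvalues `-1` and `-sqrt(5)`.
Claims per ensemble member: unique stable equilibrium; 1-norm decrease on
`[0, kappa]²` at a sampled rate at least `min(b11, b22)`; fitted decay
rate at least 0.9 of that; at most one equilibrium crossing per
coordinate; invariant order sectors; and, after stepping `c2` up, a lower
`x1*`, higher `x2*`, and zero crossings of the new equilibrium
(monotone, no under/overshoot).  Strictness margins in the step check are
per-coordinate (10⁻¹² relative): the two steady states can differ by many
orders of magnitude.

**cAMP/PKA signaling.**  Active G protein `x1` relaxes to `xi(u)`, the
unique root of `a1u(x1)·u = b11·x1`; activation is exactly null at the
total amount `G_tot`, so `xi` is increasing in glucose `u` and saturates
at `G_tot`.  PKA `x2` tracks cAMP `x3` the same way below `PKA_tot`.
Production of cAMP, `d32(x2) + a31(x2)·x1`, is decreasing in PKA;
degradation is `b32(x3)·x2 + g33(x3)` with both routes increasing and
saturating.  Along the steady-state relation production decreases and
degradation increases in `x3`, so an equilibrium exists iff

    d32(th2) + a31(th2)·xi(u)  <  b32(inf)·th2 + g33(inf),

it is then unique, locally stable and increasing in `u`, and the flag is
monotone in `u` (once false, stays false).  Test instances are engineered
to *straddle* this condition by rescaling both phosphodiesterase
amplitudes to a factor of two above or below the worst-case production,
and the flag is compared with multistart emptiness.  When the saturating
route alone dominates worst-case production
(`g33(inf) > p(u) = d32(0) + a31(0)·xi(u)`), the level set
`{x3 <= g33⁻¹(p(u))}` is invariant, giving the spike bound
`x3(t) <= max(x3(0), g33⁻¹(p(u)))` for trajectories started at
`x1(0) = xi(u)`.  The packaged violating instance weakens `g33` and slows
PKA activation while keeping production; its spike is shown to exceed the
bound that holds for the compliant default — with the dominance condition
broken, the spike is limited only by PKA catching up and is not
structurally bounded.

**Lac operon (reduced).**  Three states; the beta-galactosidase readout
`x4* = gamma·f1(x3*)/delta4` is slaved and not a state; the direct
membrane-diffusion input term is neglected as in the reduced literature
model.  `f1` is a basal-plus-Hill (`H = 2`) expression rate, import
`f2(u)` and consumption `f3(x3)` are Michaelis–Menten.  The packaged
default (`f1 = 0.05 + 7 x²/(3.7² + x²)`, `f2 = 3.5 u/(1+u)`,
`f3 = 2 x/(4 + x)`, unit linear rates) is a bistability witness located
once by seeded search over the sampling ranges and frozen: equilibrium
counts along `u in [0.01, 100]` go 1 → 3 → 1, the three equilibria at
`u = 4` are stable/unstable/stable and componentwise ordered, order cones
are invariant, and convergence from below the low equilibrium has no
overshoot.

**MAPK cascade.**  Huang–Ferrell structure with positive feedback
`mu·a17(x1)·x7`: the analysis model eliminates the mono-phosphorylated
forms through the conserved pools `x2+x3+x4 = k`, `x5+x6+x7 = h`
(affine arguments); the full 7-state model is retained for conservation
tests.  Equilibria are the roots of the scalar residual
`Phi(x1) = c10 + mu·a17(x1)·x7*(x1) - b11(x1)·x1`, where `x7*(x1)` comes
from two nested monotone tier solves (each tier is one bisection, because
the total amount filled by the three phosphoforms is increasing in the
middle form).  `Phi(0) = c10 > 0` fixes the count parity: bounded feedback
at bounded gain gives odd runs (1 or 3, alternately stable/unstable, with
the phosphorylated coordinates ordered forward and the unphosphorylated
ones reverse along the branch order); an unboundedly increasing `a17`
forces `Phi(+inf) = +inf` and even counts (0 or 2, stable/unstable
pairs); a positively lower-bounded `a17` at large gain removes all
equilibria.  Without feedback the cascade has one stable equilibrium,
provided `c10` stays below the turnover ceiling `sup b11(x)·x`; the
ensemble sampling ranges enforce this existence condition (basal input
0.01–0.2 against a ceiling of at least 0.5).  The frozen default kinetics
are ultrasensitive (half-saturations 0.05 against unit totals,
phosphatase ceilings 0.25, turnover `x/(1+x)`, `c10 = 0.05`); the
constant-feedback gain window containing three equilibria includes
`mu in [0.2, 0.5]`, and `mu = 0.3` is the packaged bistable point.  The
scalar residual also sizes the multistart box (three times the largest
scalar root) and supplies informed extra starts.

## What the ensembles do and do not show

Sampled instances share exact tag shapes, perfect coupling, constant
inputs and no noise; they probe parameter robustness *within* the
qualitative structure, not robustness to structural mis-specification,
stochasticity, delays or time-varying inputs.  Passing ensembles
demonstrate that the claims hold across the sampled parameter decades at
the configured certificate densities — falsifiable evidence consistent
with the structural argument, not a proof over the uncountable family.

## Problem sizes

Default study sizes: 100 instances × 10 initial conditions per case for
orthant invariance; 100 instances for the annihilation-module claims; 50
instances straddling the cAMP existence condition; 20 instances for the
no-feedback cascade uniqueness with 200 multistarts each; simulation
horizons of 15–50 time units extended adaptively until steadiness.
Certificate densities are 20 000 interior / 2 000 boundary points by
default; ensemble claim sweeps use 800–2 000 boundary points per
constraint, which keeps a full run of the claim suites within a few
minutes on one core.
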