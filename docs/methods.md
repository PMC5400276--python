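# Methods

This note records the models, algorithms, numerical conventions and design
choices behind `crnt`, in the spirit of a model-description appendix.

## Scope and assumptions

All analyses presume:

* **A.1 — mass-action kinetics.** Every reaction rate is
  v_j = k_j ∏ᵢ c_i^{α_ij} with a single positive constant per reaction.
  General rate laws (Michaelis–Menten, Hill) are out of scope; in signaling,
  saturated kinetics can always be unfolded into elementary mass-action
  steps.
* **A.2 — positive steady states.** Searches and certificates live in the
  open positive orthant; boundary equilibria are excluded by construction
  (log-space parametrizations, positivity filters).
* **A.3 — uniterminal complex graph** (deficiency route only): every
  linkage class contains exactly one terminal strong linkage class. This is
  what makes the deficiency subspace dimension equal δ and the manifold
  equations well-posed.
* **A.4 — semi-diffusive structure** (injectivity route only): outflow
  (degradation) of every species, inflow (basal formation) of exactly one
  *key species* — the free form — per conserved moiety of the true-reaction
  subsystem. Fully diffusive (CFSTR-style) networks are the special case in
  which every species is a key species; they need no separate code path.

## Structural layer

* Ranks of integer matrices are decided two ways: exactly (fraction-free
  elimination) where the result feeds a discrete decision (conservation
  basis selection), and numerically via singular values with threshold
  `max(dim) · eps · σ_max` (exposed as `rank_tol`) for the saddle-node rank
  tests, where the inputs are floating point.
* **Closedness** is an LP feasibility problem: a strictly positive row
  vector θ with θS = 0 exists iff {θS = 0, θ ≥ 1} is feasible (scale
  invariance converts the open condition θ > 0 into the closed bound).
* **Conserved-moiety bases** are extreme rays of {b ≥ 0 : Sᵀb = 0},
  enumerated exactly by a double-description pass over the orthant with the
  combinatorial adjacency test (`crnt.cone`). The basis takes the first
  λ = N − s independent rays in lexicographic ray order; tests compare row
  spaces, never individual entries, because the basis is not unique. If the
  rays span less than λ dimensions the network carries a conservation
  relation that is not a conserved moiety and the basis constructor raises —
  such networks are outside the method's scope.
* **Environment node conventions.** The zero complex is an ordinary node of
  the complex graph (`zero_complex="shared"`). Because a shared environment
  node can merge otherwise disconnected subgraphs of an open network — and
  with them change ℓ and δ — the alternative convention
  (`zero_complex="split"`, one private environment copy per exchange
  reaction) is also exposed. Published deficiency values for open networks
  are convention-dependent, so the package asserts δ only where the
  convention is unambiguous (closed networks).
* **Complex ordering** follows first appearance in the input file; fixture
  builders permute to the conventional ordering of the case studies where a
  fixed ordering aids comparison.

## Deficiency route

With a basis ω of Ker(Y) ∩ Ker(Λᵀ) (computed exactly over the rationals),
the complex-space balance Aψ(c) = Σ αᵢωᵢ holds at equilibrium. Rows within
one linkage class sum to zero, so the package drops the first complex of
each class, leaving M − ℓ independent equations H(c, α, k) = 0. The choice
of dropped rows and of ω is a convention; the solution set is invariant
(tested explicitly).

**Inner solve.** Given decision variables (k, α, and for under-dimensioned
networks λ − δ fixed concentrations), H = 0 is solved for the remaining
concentrations by exploiting its bilinear structure:

1. the kept rows of Aψ = Ωα are linear in ψ with full row rank; their
   solution set is ψ = ψ₀ + W u;
2. strict positivity of ψ over that affine set is decided exactly by a
   Chebyshev-center LP — infeasible candidates are rejected in milliseconds
   without any iteration;
3. the toric consistency system Yᵀ log c = log(ψ₀ + W u) is square and
   mildly nonlinear; a damped Newton iteration (fraction-to-boundary steps
   keep ψ positive) solves it from the LP center or a warm start.

The fixed concentrations for under-dimensioned networks are chosen greedily
so that the remaining D_c H block keeps full generic rank (deterministic,
evaluated at a fixed reference point).

**Objective and certification.** F_def = det(G)² is evaluated on the
row-equilibrated G (each row scaled to unit ∞-norm) to tame the dynamic
range; certificates also report the raw determinant. For larger networks
the equilibrated determinant is numerically tiny even away from folds, so
the tolerance F_def ≤ 1e−16 is a necessary filter only: the deciding tests
are the rank conditions (D_c H full rank; rank G = N + δ − 1 via the
singular-value threshold above) and positivity, applied after the fact —
rank is discontinuous and is never penalized during the search. The
equilibrium test C.1 uses a residual scaled row-wise by the magnitude of
the equation terms, so it is meaningful across concentration scales.

**Search strategy.** Deterministic, seeded. Latin-hypercube exploration of
the decision box — rate constants and fixed concentrations on log₁₀ scale in
[1e−3, 1e3], deficiency parameters through the signed-log coding
α = sgn(t)(10^|t| − 1), t ∈ [−3, 3], because α takes either sign and spans
decades — in batches until both signs of det(G) have been seen (sign
changes can occupy ~1% of the feasible region on 20+-dimensional decision
spaces) or the exploration budget is spent. Opposite-sign pairs bracket a
zero along the connecting segment; Brent's method (with warm-started inner
solves for continuity) drives the determinant to machine zero, and the
conditions are then verified. Failure to certify is reported as
*not found*, never as proof of monostationarity.

## Injectivity route

The flux cone {μ ≥ 0 : (S_to μ)ᵢ = 0 for non-key i} is generated by its
extreme rays (same double-description code); the search runs over positive
log-scaled ray weights, which satisfies the equality constraints of p̄
exactly and keeps every flux positive — the positivity requirement
p̄ᵢ > 0 on key species is checked at candidates. det J̄(μ) is linear in
each flux and cheap, so exploration is dense (hundreds of samples per
multistart) before sign-bracketing and Brent refinement; C.6 (rank
J̄ = N − 1) and C.7 (sign pattern of p̄) are the acceptance filters.
Recovery places the steady state at c = 1 (so k_j = μ_j for true + outflow
reactions and the inflow constants equal the key components of p̄); the
scaling k_j = μ_j/ψ_source(j)(c*) relocates the same saddle-node to any
positive c*, and one pinned flux can be honored exactly by global rescaling
(the conditions are homogeneous in μ). The sign survey
`check_injectivity` is heuristic: constant sign across samples is evidence,
not proof, of injectivity.

## Continuation

`continue_branch` traces equilibrium curves in log coordinates (log c,
log p) — tangent components are then dimensionless, so one arclength step
policy works across branches spanning decades. The traced system is the
reduced one: s independent rows of S·v plus the conservation residuals
Bᵀc − σ, with fixed row scaling so rate and conservation residuals are
comparable. The parameter is either a rate constant or one conservation
constant σᵢ. Standard pseudo-arclength predictor–corrector with adaptive
steps (accept/reject on corrector iteration count); folds are detected by a
sign change of the tangent's parameter component, refined by bisection on
the arclength step, and confirmed as genuine local extrema of the parameter
(tangent jitter on near-flat segments would otherwise fabricate folds).
Stability comes from the eigenvalues of the Jacobian reduced to the
compatibility class (per moiety, the largest-coefficient species — ties to
the lowest index — is eliminated); |Re λ| below 1e−8 is flagged
*near-critical* rather than classified. The default parameter window is six
decades either side of the start, because the reduced system degenerates at
the boundary of the positive orthant and the trace would wander there. A
loop detector stops tracers that fall back onto an already-traversed sheet
after razor-thin folds.

`detect_bistability` pairs consecutive folds and requires the classic
S-shape: two stable segments overlapping in parameter with the unstable
segment between them. `find_equilibria` complements it with a
basin-respecting census: ODE relaxation (LSODA, then a Newton polish) from
randomized initial conditions projected onto the compatibility class by
iterative proportional fitting; starts alternate between perturbations of a
reference state and reference-independent log-uniform draws, because small
basins (the near-inactive state of a switch) are easy to miss with
perturbative starts alone. `quasi_static_sweep` implements the hysteresis
protocol: warm-started relaxation along an ascending then descending
parameter grid, which jumps at different parameter values when a bistable
window is crossed.

## Global optimizer

`crnt.optimize.minimize` is a seeded Latin-hypercube multistart with
Nelder–Mead polishing and a final Powell polish, plus the `sign_bisection`
accelerator used by both search routes when the objective exposes a signed
quantity whose zero is sought. Same seed ⇒ identical evaluation sequence
and result; the best-so-far trace is monotone. The evaluation budget and
multistart count are the only tuning knobs the searches expose.

## Case-study fixtures and the generator

Fixtures whose reaction lists are fully determined by published text carry
provenance `text` and their structural indices are asserted exactly. The
STAT-level networks are *figure-transcribed*: narrative-based
reconstructions (documented edge-by-edge in `data/PROVENANCE.md`) whose
tests assert internal consistency and qualitative outcomes only — namely
that saddle-node certificates exist for the closed and semi-diffusive early
STAT module and the feedback variant, and that the coupled receptor + STAT
module shows hysteresis in the IFN association constant with a shift of the
homodimer:heterodimer composition between the two stable branches. The
reconstruction places the documented pSTAT1 trans-activation step (a
transient mixed STAT1–pSTAT1 dimer) at the core, which is what lets the
module host bistability; an enzymatic phosphatase provides the saturating
deactivation a switch needs. The direction of which dimer dominates on
which side of the threshold is not asserted.

The coupled hysteresis experiment starts from a constructed operating
point: the STAT species at a certified saddle-node state, the receptor
periphery at detailed balance around the certified free-receptor level with
one association route kinetically suppressed, so that the association
constant k29 controls ternary-complex delivery
(`fixtures.receptor_stat_operating_point`). Quasi-static sweeps are used
rather than a single arclength trace because the coupled fold geometry is
extremely thin in state space.

`random_network` generates small structured networks by rejection sampling
(weak reversibility via random disjoint cycles; δ = 0, uniterminality,
moiety conservation and semi-diffusive structure as acceptance filters).
It emulates the combinatorics of small mass-action mechanisms, not any
biological rate realism: passing property tests on it validates the
algebraic identities and structural invariants, and says nothing about
parameter ranges of real pathways.

## Problem sizes and budgets

Default searches use 10 multistarts with an exploration phase of a few
thousand candidate evaluations; the packaged analyses (acceptance script and
test suite) run the motif and STAT searches at these defaults, the negative
controls at reduced budgets (certificates must *not* appear, so a bounded
search documents the attempt), 20 random δ = 0 control networks of N = 4,
and 9–11-point hysteresis grids. These sizes were chosen so a full
reproduction stays within a few minutes on one CPU while every qualitative
outcome is exercised; all of them scale up linearly through the exposed
options.

## Known limitations

* A failed search is inconclusive; precluding multistationarity requires
  conclusive methods (interval search, injectivity sign analysis of all
  minors, deficiency-type theorems) that are outside this package's scope.
* The deficiency route requires uniterminality and at least one conservation
  law; the injectivity route requires the semi-diffusive structure. Open
  networks with conservation laws that are not moieties are rejected.
* Only mass-action kinetics, and only text-format input (no SBML import).
* Continuation classifies folds only; Hopf and other codimension-one
  bifurcations are recorded at most as unexplained stability changes.
* The STAT-level fixtures are reconstructions; their edge lists live in
  plain-text files precisely so they can be corrected against the original
  figures without touching code.
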