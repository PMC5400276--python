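# crnt — saddle-node search and bistability analysis for mass-action reaction networks

Bistability — the coexistence of two stable steady states — is how signaling
pathways implement all-or-none cell decisions. Whether a given reaction
mechanism *can* be bistable, and for which rate constants, is hard to answer
by trial simulation: realistic signaling models are high-dimensional and
their parameters largely unknown. `crnt` implements two complementary
methods from Chemical Reaction Network Theory that turn this question into a
structured global search for **saddle-node (limit point) bifurcations**, the
generic gateway to bistability, followed by numerical continuation of the
equilibrium branches.

For a network of *N* species, *M* complexes and *R* mass-action reactions
with molecularity matrix *Y*, stoichiometric matrix *S* (rank *s*),
ℓ linkage classes and deficiency δ = *M* − ℓ − *s*:

* **Deficiency-oriented route** (networks *with* mass conservation,
  uniterminal graph). The equilibrium locus is written through a basis
  ω₁…ω_δ of the deficiency subspace Ker(*Y*) ∩ Im(*A*) as
  *A*ψ(c) = Σᵢ αᵢωᵢ, giving *M* − ℓ polynomial equations
  *H*(c, α, k) = 0 in the concentrations, the deficiency parameters α and
  the rate constants. With the conserved-moiety matrix *B* (columns span the
  nonnegative left nullspace of *S*), the square matrix
  *G* = [[D_c H, D_α H], [*B*ᵀ, 0]] of size *N* + δ tests for folds:
  a strictly positive point with *H* = 0, D_c H of full rank and
  rank *G* = *N* + δ − 1 is a saddle-node of the dynamics restricted to its
  stoichiometric compatibility class. The search minimizes
  F_def = det(*G*)² subject to *H* = 0.
* **Injectivity-oriented route** (semi-diffusive networks *without* mass
  conservation: every species degraded, one inflow per conserved moiety of
  the true subsystem). In terms of the steady-state fluxes μ of the true +
  outflow reactions, the Jacobian is J̄(μ) = S_to diag(μ) Y_rᵀ and the net
  consumption is p̄(μ) = −S_to μ. A positive flux vector with
  rank J̄ = *N* − 1 and the right sign pattern of p̄ (positive exactly on
  the inflow species) certifies a saddle-node; concentrations and rate
  constants are recovered in closed form by placing the steady state at
  c = 1. The search minimizes F_inj = det(J̄)² over the flux cone.

A certified saddle-node seeds a pseudo-arclength continuation that traces
the equilibrium branch in both directions, flags limit points, classifies
stability from the reduced Jacobian and reports the bistable parameter
interval enclosed by a fold pair.

The packaged case studies follow type I interferon signaling: the ternary
IFN–receptor complex formation (provably monostable — the searches correctly
find nothing), the early STAT1/STAT2 signaling module (bistable), STAT
signaling with transcriptional STAT1 feedback (bistability preserved), and
the coupled receptor + STAT module, which shows hysteresis in the
IFN–receptor association constant.

## Worked example

Networks are plain text, one reaction per line (`educts -> products`, `<->`
for reversible pairs, `0` for the environment, optional `label:` prefixes).
The built-in `motif_closed` fixture is an autocatalytic signal-transduction
motif: protein A is activated by kinase E1, deactivated by phosphatase E2,
and activates itself through the intermediate AA*.

```text
$ crnt analyze fixture:motif_closed
species N = 7, reactions R = 9, complexes M = 9
linkage classes l = 3, rank S = 4, rank Y = 7
conservation laws lambda = 3, deficiency delta = 2
uniterminal, not weakly reversible, closed
closedness certificate theta = [1, 1, 1, 1, 2, 2, 2]
  M1: E2 + A*E2
  M2: E1 + AE1
  M3: A + A* + AE1 + A*E2 + 2 AA*
```

Three conserved moieties (total phosphatase, total kinase, total A in all
its forms) and deficiency 2: the deficiency route applies.

```text
$ crnt find fixture:motif_closed --seed 1 --multistarts 10 --out cert.json
Saddle-node certificate (deficiency route)
--------------------------------------------
F_def = det(G)^2 = 1.314e-46   (raw det G = 0.000e+00)
C.1 |H| = 3.33e-09  C.2 rank DcH = 6/6  C.3 rank G = 8/8
steady state:
  [A] = 0.0978313
  ...
conservation constants sigma = [   163.243213 113261.491553  10166.958743]
```

The objective is numerically zero and all three saddle-node conditions hold:
the point (c, k) is a fold. Continuing the equilibrium branch in the total
amount of A (σ₃):

```text
$ crnt continue fixture:motif_closed --start cert.json --param sigma3 --out branch.csv
branch with 127 points, 2 limit points written to branch.csv
bistability region: sigma3 in [10167, 10227.5]
```

Two limit points enclose the bistable window: for σ₃ inside it the motif
has two stable steady states (a low-activity and a high-activity branch,
AA* ≈ 24 vs ≈ 1600 at the window midpoint) separated by an unstable one —
a switch with memory. The same workflow with `--method injectivity` on
`fixture:motif_semidiffusive` certifies the open variant and finds the
bistable window in the basal formation rate of A (`--param k17`).

The library API mirrors the CLI: `parse_network`, `structural_summary`,
`conservation_basis`, `make_semidiffusive`, `search_def` / `search_inj`
(returning certificate objects with a `summary()`), `continue_branch`,
`detect_bistability`, and `quasi_static_sweep` for hysteresis protocols.

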