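# Methods

## Scope and assumptions

All rate laws are initial-rate expressions: product rebinding and
reverse flux are neglected, so the only influence of products on the
enzyme is through the substrate/inhibitor roles they are explicitly
assigned. Enzyme concentration is constant and absorbed into the
maximal velocities V_j = k_j[E₀]. Every quantity is dimensionless —
arbitrary concentration and time units — because the underlying
parameter sets carry none; users can rescale to molar units by scaling
all concentrations, all K's and (jointly) the V's and K.

A single enzyme type acts on the whole glycoform lattice; heterogeneous
enzymes with different site preferences are out of scope, as are
spatial/compartmental transport, enzyme dynamics, stochastic
simulation, and Hopf/oscillatory analysis.

## Rate laws

Three mechanisms share one evaluation kernel (`rate_laws.edge_rate`):

- **random order** (rapid equilibrium):
  `v_j = V_j a b_j / (Ks_Ax Km_j (1 + AE′) + Km_j a (1 + AE))`.
- **inhibited** (abortive ternary complexes, either binding order):
  the first denominator group becomes `Ks_Ax Km_j (1 + AE′ + s_I)`.
- **compulsory order** (quasi-steady state, donor first):
  `V_j a b_j / (Ks_Ax Km_j (1 + s_Bj) + Km_j a + Km_Ax,j b_j + a b_j)`,
  where `s_Bj` is the Michaelis-weighted sum excluding the edge's own
  site. The first group uses the Km-weighted sum exactly as the law is
  stated; we implement it verbatim rather than substituting the
  Ks-weighted analogue of the rapid-equilibrium case.

The aggregate sums AE, AE′ run over every (species, site) pair carrying
the respective constant, so a bivalent substrate contributes two terms;
the aggregate forms then contain the edge's own-site terms and are
algebraically identical to the per-competitor forms with explicit
`Km_Ax,j b_j + a b_j` denominator entries. This identity requires the
substrate site of every edge to carry a Ks (the donor Michaelis
constant of the edge is derived as `Km_Ax,j = Ks_Ax · Km_j / Ks_j`);
the config validator enforces it. The inhibition sum is accumulated as
the explicit double sum over (K_I site, K_s site) pairs and equals the
factorised product `(Σ b/K_I)(Σ b/K_s)` by construction; the test-suite
checks both representations against literal transcriptions of the
per-competitor forms at 1e-12 relative tolerance on random states
(pure algebraic rearrangements at double precision), and limit
reductions (saturating donor, K_I → ∞) at 1e-6.

**Apparent Km.** For m sites with equal Vmax the half-saturation
concentration of the summed Michaelis terms solves
`1 = Σ_i Kapp/(Km_i + Kapp)`; the root is found by Brent bracketing
(the left side is monotone in Kapp). For m = 2 this is the geometric
mean and lies between the two Km values; for m ≥ 3 it does not (three
equal Km = x give Kapp = x/(m−1)), so no min–max bound is asserted
beyond the bivalent case. For m = 1 the relation has no finite root and
the lone Km is returned — the half-saturation point of a single
Michaelis term.

## Glycoform networks

Node identity is the site-occupancy tuple; display names B1…B_{2^m}
order nodes by step (number of filled sites) and then by position of
the filled sites, so for m = 2: B1 = (−,−), B2 = (site 1 filled),
B3 = (site 2 filled), B4 = (+,+). This fixes the mapping of tabulated
per-species constant lists onto sites. Enumeration (nodes, edges,
maximal paths) is capped at m = 12 since path counting is factorial;
the closed-form counts remain available through the formulas.

The closed-form pathway expression `P(m) = Σ_k C(m,k)·k·(m−k)` is
evaluated exactly as written and reported side by side with the
exhaustively enumerated count of maximal root-to-sink paths. The two
agree at m ≤ 2 but diverge from m = 3 (P(3) = 12 vs 3! = 6 enumerated
paths); the tool reports both without reconciliation, and the
enumerated count is the one used in documentation claims.

For the diantennary network the substrate/inhibitor role assignment is
taken from the tabulated constants as given: Ks on both B1 sites, on
B2's free site and on B3's free site; K_I on B2, on B3 and on both B4
sites — 4 × 4 = 16 summands in s_I. (The accompanying prose about
which species can act as substrate inhibitors is not fully consistent
with the scheme; the constants table is treated as authoritative.)
Which site index carries a lone K_I is presentational only — it never
enters the numerics — and we place it on a filled site, since the
inhibitor role is attributed to the newly added terminal sugar.

## Open-system models

Every species — including the terminal product B4 and the donor —
exchanges with the exterior at the same diffusion constant K, exactly
as the model equations are written (B4 has an inflow K(b₀ − b4) even
though it is never consumed). All four acceptors share one external
concentration b₀, with optional per-species overrides in the config;
the `b0` continuation parameter moves the shared value. Whether B4's
exterior level "should" be 0 instead of b₀ is not decidable from the
model statement; the printed form is the default and the override
covers the alternative.

The five-ODE model uses the inhibited rate law (it is identical for
random- and compulsory-order binding); the config's `mechanism` key
records the binding order and selects the law only when `inhibition`
is turned off. The one-dimensional model groups its denominator as
`Ka·Kb + Kb·a + Ka·b + (Ka/Ks)·b² + a·b` — the n = 1 inhibited law
with the donor Michaelis constant standing in for Ks_Ax and the
inhibition constant written Ks; with the bundled constants this gives
denominator 0.12 + 1.2 b + 12 b², and it is the only grouping
consistent with the published limit points, which is how the
typographic ambiguity in the model statement was resolved.

Integration uses LSODA at rtol 1e-8 / atol 1e-10; the small
dissociation constants (B2's Ks = 0.002) make the network systems
stiff. Trajectories started in the non-negative orthant stay there to
solver tolerance; rate evaluations clip transient negative excursions
at zero.

## Continuation

- **Steady states**: multi-start Newton (scipy `hybr`) from uniform
  quasi-random points in the search box, supplemented by a log-space
  Levenberg–Marquardt pass when the box is non-negative (concentrations
  at the active steady states span orders of magnitude, which defeats
  uniform starts), and by a dense sign-change scan + Brent refinement
  for one-dimensional models. Roots are accepted at ‖rhs‖ < 1e-9 and
  deduplicated at 1e-6 absolute distance in state space (below the
  physical resolution of interest, above solver noise). Stability comes
  from the eigenvalues of a central-difference Jacobian (relative step
  1e-7); leading eigenvalue = maximal real part.

- **One-parameter branches**: pseudo-arclength continuation with a
  secant predictor and Newton corrector (max 8 iterations, orthogonal
  arclength constraint), adaptive step in [1e-6, 5e-2] starting at
  1e-2. A corrector result farther than 3× the step from the previous
  point is rejected as a branch jump and the step halved — without this
  guard the corrector can hop between the closely spaced branches of
  the network model and silently skip a fold. Folds are flagged by a
  sign change of det J between accepted points and refined by Newton on
  the bordered system {F = 0, Jv = 0, ‖v‖² = 1} (parameter tolerance
  ~1e-8, and the refined point must have an eigenvalue within 1e-7 of
  zero); duplicate refinements of the same fold are merged.

- **Two-parameter fold curves**: the same predictor–corrector applied
  to the bordered system with both parameters free (2n + 2 unknowns,
  2n + 1 equations plus the arclength constraint), traced in both
  directions from a seed fold. `Jv` is evaluated as a central
  directional difference (two rhs calls), so no explicit Jacobian
  assembly is needed inside the corrector.

- **Cusps**: along the fold curve the quadratic normal-form coefficient
  `c = w · D²F(v, v)` is monitored, with v the continued null vector,
  w the left null vector from the SVD of J, sign-anchored by
  `w·v > 0` (the zero eigenvalue is algebraically simple on a fold
  curve, so w·v cannot vanish there — without the anchoring the
  arbitrary SVD sign produces spurious zero crossings). A sign change
  is refined by bisection along the curve, re-correcting each midpoint
  onto the fold locus. D²F(v,v) is a second central difference with
  relative step 1e-4 — accurate enough for a test function whose root
  is crossed transversally.

The continuation engine is validated against the saddle-node normal
form db/dt = μ − b² (fold at μ = 0 to 1e-8) and the cusp normal form
db/dt = μ₁ + μ₂b − b³ (fold locus 27μ₁² = 4μ₂³, cusp at the origin to
1e-6), and the 1-D model's folds are cross-checked against the
independent tangency derivation (solving dv_enz/db = −K via the exact
quartic companion matrix and mapping b₀ = b* + v_enz(b*)/K): the two
routes agree to better than 1e-4 relative.

## Config format

Hand-editable YAML (UTF-8, no anchors/aliases) validated by an explicit
schema checker whose errors name the offending key. Serialisation is
canonical (sorted keys), so save→load→save is byte-identical. Per-site
constants are written as length-m lists in site order with `null` for
absent constants. Three fixtures carry the published parameter sets:
`fig4_1d`, `table1_galt` and `fig5a_galt` (the latter differing only in
the shared acceptor external, 0.3 instead of 0.15).

## Problem sizes and runtimes

Everything is desk-scale: the largest state space is the five-ODE
diantennary model, the default branch continuations use a few hundred
corrector solves, and the two-parameter cusp computation completes in
a few seconds. Network enumeration tests run to m = 8 (40320 paths);
the cap of m = 12 keeps exhaustive path enumeration tractable.

## Known limitations

- Finite-difference Jacobians limit fold/cusp refinement to ~1e-8
  residuals; analytic Jacobians would sharpen this but are not needed
  at the published precision.
- The multi-start root finder offers no completeness guarantee in
  dimension > 1; the dense-scan guarantee applies only to 1-D models.
- SBML export is not provided; model exchange is via the YAML configs.
- Product inhibition, donor-side substrate inhibition and oscillatory
  dynamics are out of scope.
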