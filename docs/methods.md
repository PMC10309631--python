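# Methods

## Model and assumptions

The package implements the planar bilingual-competition system

    dx_A/dt = a1 (1 - x_A - x_B) x_A^a - a2 x_A x_B^a
    dx_B/dt = a3 (1 - x_A - x_B) x_B^a - a4 x_B x_A^a

on the simplex Ω = {x_A ≥ 0, x_B ≥ 0, x_A + x_B ≤ 1}, where x_A, x_B are
the monolingual shares of languages A and B and w = 1 − x_A − x_B the
bilingual share.  The system is the proportion-level closure of a
three-compartment transfer model: bilinguals adopt monolingual A at
per-capita rate I_wA·s_A·x_A^a (a language pulls in proportion to its
status s and its speaker share raised to the attractiveness exponent a),
monolingual A speakers become bilingual at rate I_Aw·s_B·x_B^a (driven by
the *other* language), and symmetrically for B; the coefficient μ ∈ (0, 1)
weights the bilingual→monolingual direction, 1 − μ the reverse.  The
reduction a1 = μ·I_wA·s_A, a2 = (1−μ)·I_Aw·s_B, a3 = μ·I_wB·s_B,
a4 = (1−μ)·I_Bw·s_A is exact; a property test asserts the identity between
the full and reduced fields to 1e−14 on random parameterizations.

Assumptions inherited from the model class: closed population of constant
size, a single well-mixed social structure, no age structure, no spatial
effects.  μ is treated purely as the reduction coefficient above, with no
demographic interpretation attached.  The bilingual share carries no
independent dynamics; w is stored redundantly and validated against
1 − x_A − x_B rather than integrated.

## Parameters

| parameter | meaning | default / built-ins | notes |
|---|---|---|---|
| μ | turnover weighting of the bilingual→monolingual flows | 0.02 in every built-in scenario | language loss across generations is much slower than individual learning; must lie in (0,1) so a1..a4 > 0 |
| a | attractiveness exponent on speaker share | 1.31 (time-series examples), 1 (control scenarios) | ≈1.31 is the cross-culturally estimated value; a < 1 accepted with a warning (all stability theory assumes a ≥ 1) |
| s_A, s_B | language statuses | scenario-specific | s_A + s_B = 1 is *not* enforced (built-ins always use complementary values; a warning is logged otherwise) |
| I_wA, I_wB | interaction, bilingual → monolingual A/B | scenario-specific | nonnegative |
| I_Aw, I_Bw | interaction, monolingual A/B → bilingual | scenario-specific | nonnegative |
| ET | endangerment threshold for the control | 0.3 in fig8b–d | switching line Σ = {x_B = ET} |

Time units are abstract; no calendar mapping is attempted.

## Equilibria and classification

Ω always contains the trivial fixed points E0(0,0), E1(0,1), E2(1,0).  For
strictly positive coefficients and a > 1/2 there is a unique interior point
E3, computed from the ratio identity (x_A/x_B)^(2a−1) = a2·a3/(a1·a4):
with ρ = r^(1/(2a−1)), x_B* = 1/(ρ + 1 + (a4/a3)ρ^a), x_A* = ρ·x_B*.  At
a = 1 this reduces to the rational form x_A* = a2a3/D, x_B* = a1a4/D,
D = a1a4 + a2a3 + a2a4; the implementation dispatches to the rational form
at a = 1 and tests assert agreement of the two routes to 1e−14 and
agreement with an independent bracketed 2-D root search to 1e−10.  The
exponent a = 1/2 makes 2a − 1 = 0 and is rejected as unsupported.

Stability uses the planar indicators p = −trace J, q = det J with the
taxonomy: q < 0 saddle; q > 0 ∧ p > 0 stable (node iff p² ≥ 4q, else
focus); q > 0 ∧ p < 0 unstable likewise; q > 0 ∧ p = 0 center-like
(degenerate); p = q = 0 degenerate/non-hyperbolic.  Numerical choices:

* zero tests on p, q use an absolute tolerance of 1e−12;
* the node/focus discriminant p² − 4q uses a relative slack
  (≥ −1e−12·max(1, p²)) so the repeated-eigenvalue boundary — which occurs
  exactly at the monolingual corners when a1 = a4 or a2 = a3 — counts as a
  node, matching the analytic discriminants (a1−a4)² and (a2−a3)²;
* x^(a−1) at x = 0 is defined as 1 for a = 1 and 0 for a > 1 (the limits
  the corner Jacobians require); for a < 1 it diverges and boundary
  evaluation raises;
* powers of zero: x^a := 0 at x = 0 for any a > 0, and coordinates in
  [−1e−12, 0) are clamped to 0 first (guards integrator overshoot).

E0 with a > 1 has a zero Jacobian, so linearization is silent there.  The
report separates the analytic label ("degenerate/non-hyperbolic") from a
numeric perturbation probe: trajectories started 1e−4 away in 8 directions
(clamped into Ω) are integrated for 10⁴ time units and the point is flagged
`numerically_unstable` when any of them moves measurably (> 1%) away.  The
growth near the degenerate corner is algebraic, hence the long probe
horizon and tight integrator tolerances (rtol 1e−10, atol 1e−14).

Positive invariance of Ω is exposed as an executable check: on each edge
the normal component of the field is sampled (zero tangential-flow identity
on the axes, nonpositive total flux across the hypotenuse), with failures
reported rather than raised.

One note on the closed forms: direct differentiation at E3 (a = 1) gives
p = a1·x_A* + a3·x_B* = (a1a2a3 + a1a3a4)/D.  A commonly printed variant
with numerator a1a2a3 + a2a3a4 disagrees with the Jacobian (and with
central finite differences); the package uses the Jacobian value.  q =
−a1a2a3a4/D is confirmed exactly.  Both routes agree that E3 is a saddle.

## Simulation

Smooth integration uses `scipy.integrate.solve_ivp` (LSODA) with defaults
rtol 1e−9, atol 1e−12, horizon t_max = 10⁴ and ≥ 500 evenly spaced samples;
initial states are rescaled to sum exactly to 1 (with a warning — one
built-in start is stated as 0.33 + 0.33 + 0.33).  States are clamped to the
simplex within tolerance on output, and trajectories are asserted to stay
within 1e−6 of it.  `attractor_of` integrates in restartable 2000-unit
chunks (budget 2×10⁵) until ‖f‖∞ < 1e−10 and the last-chunk displacement is
< 1e−8, then matches the limit against E0–E3 within 1e−4; non-convergence
is reported, never raised.  "Extinction time" is operationalized as the
first passage of a share below 0.01 (configurable; the flows only reach 0
asymptotically), located by integrator event detection.

## Sliding-mode control (Filippov construction)

The controlled model applies the free coefficients where x_B ≥ ET and the
"hat" (policy) coefficients where x_B < ET; the policy is purely a
parameter switch, never an added forcing term.  Let σ_free, σ_ctrl be the
x_B-components of the two fields on Σ.  A point of Σ is *sliding* iff
σ_free < 0 < σ_ctrl (both fields aim at Σ), *escaping* for the reverse
pattern, otherwise a crossing; exact zeros are tangencies.  Sliding motion
uses Filippov's convex combination — the unique convention for a planar
system with a scalar switching function that keeps the combined field
tangent to Σ: λ = σ_ctrl/(σ_ctrl − σ_free) ∈ (0,1) on a sliding segment,
combined x_B-component identically zero (asserted to 1e−14).  Segment
endpoints are roots of σ_free or σ_ctrl found by a 2048-point sign scan
plus Brent refinement to 1e−13; pseudo-equilibria are roots of
H = f_A^free·σ_ctrl − f_A^ctrl·σ_free inside a segment (400-point scan +
Brent), kept when λ ∈ (0,1).  For a = 1, H/x_A is a quadratic polynomial;
the test suite uses its `numpy.roots` solution as an independent oracle.

Hybrid trajectories are integrated regime by regime with a terminal event
at x_B = ET.  A hit is classified: sliding starts the 1-D motion along Σ;
otherwise the flow continues in the regime on the far side (the sign
pattern at a hit excludes re-entry into the regime that produced it).
Sliding integrates the 1-D field in 2000-unit chunks with terminal events
at the segment endpoints; it ends either at a pseudo-equilibrium
(|sliding field| < 1e−12 → converged) or at a tangency endpoint, where the
regime whose field points away from Σ resumes, nudged off Σ by 1e−13.  A
chattering guard aborts after 10⁴ regime switches.  Exactly on Σ, regime
attribution follows the sliding classification rather than the x_B ≥ ET
inequality.

### Built-in policy scenarios

With baseline (s_A, s_B, I_mono→bi) = (0.8, 0.2, 0.03), μ = 0.02, a = 1 and
ET = 0.3 (E3 at (0.0437, 0.6993), a saddle — no coexistence without
control):

* **status only** (0.6, 0.4, 0.03): sliding segment (0.1017, 0.2184) but H
  has no admissible root on it — the sliding motion exits; no coexistence.
* **interaction only** (0.8, 0.2, 0.06): the controlled σ-root (0.0549)
  lies left of the free one (0.1017), so the sliding sign pattern never
  occurs; no coexistence.
* **combined** (0.6, 0.4, 0.06): segment (0.10174, 0.12939) with a
  pseudo-equilibrium at x_A = 0.128915 (λ = 0.0268), i.e. the state
  (0.13, 0.30, 0.57) at display rounding — stable coexistence at the
  threshold.

The pseudo-equilibrium is *locally* attracting: perturbed starts on either
side of it along Σ return, and below-threshold starts near the segment
(e.g. (0.104, 0.25)) rise onto it.  It is not globally attracting: the free
flow from the near-uniform start (0.33, 0.33, 0.34) reaches Σ at
x_A ≈ 0.348, right of both the segment and the controlled regime's saddle
separatrix, and language B still dies from there.  The package reports
whatever the dynamics yield.

### A note on the interaction-only regime's printed x_B

For the interaction-only policy the closed form gives E3 = (0.0348,
0.5563).  A printed value of 0.5503 circulates for the x_B coordinate; it
is inconsistent with the closed form (whose x_A matches to all printed
digits) and with the independent root search, so this package reports
0.5563 and treats only x_A as externally corroborated.

## Time-series scenarios and known discrepancies

The time-series registry (μ = 0.02, a = 1.31, I_wA = 10 with remaining
interactions 1) encodes the standard examples: with (s_A, s_B) =
(0.6, 0.4) the dynamics from (0.33, 0.33, 0.34) converge to only-A (1,0,0),
faster when s_A is raised to 0.9; extinction time decreases monotonically
in I_wA ∈ {1, 5, 10, 30}.

Two narrated outcomes of this example family are **not** reproduced by the
equations, and the package deliberately reports the computed dynamics:

* with (s_A, s_B) = (0.4, 0.6) the start (0.33, 0.33, 0.34) converges to
  only-A (1,0,0), not only-B — the basin separatrix crosses x_B(0) ≈ 0.344
  at x_A(0) = 0.33, so that start lies barely on the A side (the B-heavy
  start (0.3, 0.5, 0.2) does converge to only-B, and faster);
* in the status sweep s_A ∈ {0.1, …, 0.95} (s_B = 1 − s_A), language B
  survives outright for s_A ∈ {0.1, 0.3}; the monotone decrease of B's
  extinction time holds on {0.5, 0.7, 0.95}.

These are properties of the printed parameter sets themselves, confirmed
with multiple independent integrators at tight tolerances; the
corresponding acceptance assertions are left failing rather than the
scenarios being altered.

## Synthetic-data scope

The package generates all of its own inputs (parameter sets and initial
states); there is no measured data anywhere in the pipeline.  The scenario
registry *is* the study-condition generator: it encodes the published
parameter tables and starts verbatim.  Consequently the tests demonstrate
internal correctness of the mathematics (closed forms, classification,
sliding construction, integration) and reproduction of the printed
analysis, but nothing about how well the model describes real
language-shift data — no fitting to census or minority-language records is
performed, mirroring the source analysis.  Real populations violate the
well-mixed single-community assumption (spatial structure, age structure,
migration), and the interaction values and statuses are not identifiable
from the model alone.

## Problem sizes and tolerances used by the test suite

Property sweeps use 1000 random positive coefficient draws for the
invariance and saddle checks, 50–200 draws for the oracle agreements, and
a handful of full integrations; the whole suite runs in a few seconds, and
the acceptance script (all closed-form or single-trajectory computations)
in about one.

## Known limitations

* The exponent a < 1 (sublinear attractiveness) is accepted for simulation
  but the equilibrium theory and boundary Jacobians exclude it.
* Degenerate-corner instability (E0, a > 1) rests on the numeric probe;
  no center-manifold analysis is attempted.
* Basins of attraction are explored only pointwise (no basin-boundary
  continuation), and the chattering guard is a hard abort, not a
  regularization.
* Three-or-more-language competition, spatial diffusion, stochastic or
  agent-based variants, and optimal/impulse control are out of scope.
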