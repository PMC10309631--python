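# lingslide

Quantitative analysis of **bilingual language competition with threshold
(sliding-mode) control**: can two competing languages coexist, and can a
policy intervention make coexistence possible once one of them becomes
endangered?

The package is aimed at researchers in cultural-evolution / population
dynamics modelling who want a small, well-tested toolkit for the planar
compartmental model of two monolingual groups plus a bilingual group —
its equilibria, their stability, forward simulation, and the
piecewise-smooth (Filippov) extension in which a policy switches the
parameters whenever the endangered language's share drops below an
endangerment threshold.

## The model

A closed population is split into monolingual speakers of languages A and B
and bilinguals, with proportions $x_A, x_B, w = 1 - x_A - x_B$.  Monolinguals
become bilingual at a rate driven by the *other* language's status and
speaker share; bilinguals drop one language at a rate driven by that
language's own status and share.  On proportions this closes into the planar
system on the simplex $\Omega = \{x_A \ge 0,\; x_B \ge 0,\; x_A + x_B \le 1\}$:

$$
\dot x_A = a_1 (1 - x_A - x_B)\, x_A^{a} - a_2\, x_A x_B^{a}, \qquad
\dot x_B = a_3 (1 - x_A - x_B)\, x_B^{a} - a_4\, x_B x_A^{a},
$$

with reduced coefficients
$a_1 = \mu I_{w\!\to\!A} s_A$, $a_2 = (1-\mu) I_{A\to w} s_B$,
$a_3 = \mu I_{w\to B} s_B$, $a_4 = (1-\mu) I_{B\to w} s_A$,
where $s$ are language statuses, $I$ interaction values, $\mu \in (0,1)$ the
turnover weighting, and $a$ the attractiveness exponent (about 1.31 across
cultures; $a = 1$ is the linear case).

Key facts the package computes and tests:

* $\Omega$ is positively invariant (checked numerically edge by edge).
* The corners $E_1(0,1)$ and $E_2(1,0)$ — one language wins — are always
  stable nodes; the all-bilingual corner $E_0$ and the interior coexistence
  point $E_3$ are unstable ($E_3$ is a saddle, $q = \det J < 0$).  Left
  alone, one language dies.
* $E_3$ has the closed form
  $x_A^* = \rho\, x_B^*$, $x_B^* = 1/(\rho + 1 + (a_4/a_3)\rho^{a})$ with
  $\rho = (a_2 a_3 / a_1 a_4)^{1/(2a-1)}$; at $a=1$ this reduces to
  $x_A^* = a_2 a_3 / D$, $x_B^* = a_1 a_4 / D$, $D = a_1 a_4 + a_2 a_3 + a_2 a_4$.
* **Sliding-mode control.** A policy replaces the parameters by "hat"
  values while $x_B < ET$ (the endangerment threshold).  On the switching
  line $\Sigma = \{x_B = ET\}$, wherever the free field points down and the
  controlled field points up, the flow *slides* along $\Sigma$ with the
  Filippov convex combination
  $\lambda f^{\text{free}} + (1-\lambda) f^{\text{ctrl}}$,
  $\lambda = \sigma^{\text{ctrl}} / (\sigma^{\text{ctrl}} - \sigma^{\text{free}})$.
  A zero of the sliding field is a **pseudo-equilibrium**: stable language
  coexistence pinned at the threshold, an equilibrium of neither smooth
  regime.

## Worked example

The built-in `fig8d` scenario is the combined policy: baseline statuses
$(s_A, s_B) = (0.8, 0.2)$ and monolingual-to-bilingual interactions 0.03
switch to $(0.6, 0.4)$ and 0.06 while $x_B < ET = 0.3$ (with $\mu = 0.02$,
$a = 1$).

```sh
lingslide sliding --scenario fig8d --out out/
```

prints (abridged):

```json
{
  "scenario": "fig8d",
  "sliding_segments": [[0.10174418604651163, 0.12939001848428835]],
  "pseudo_equilibrium": [0.12891443416162324, 0.3, 0.5710855658383767],
  "final_state": [1.0, 0.0, 0.0],
  "converged": true
}
```

Reading: on the threshold line the two regimes' fields oppose each other for
$x_A \in (0.1017, 0.1294)$ — the sliding segment — and the sliding flow
vanishes at $(x_A, x_B, w) \approx (0.13, 0.30, 0.57)$, the
pseudo-equilibrium: 13% monolingual A, 30% monolingual B (held exactly at
the endangerment threshold), 57% bilingual.  The `final_state` line is the
hybrid trajectory from the default near-uniform start $(0.33, 0.33, 0.34)$:
that start lies outside the pseudo-equilibrium's basin, so language B still
dies from there — the policy stabilizes coexistence only locally around the
threshold (starts such as $(0.104, 0.25)$ do converge to it; see
`docs/methods.md`).

The uncontrolled baseline shows why intervention is needed at all:

```sh
lingslide equilibria --scenario fig8a --out out/
```

```json
{
  "equilibria": {
    "E0": {"point": [0.0, 0.0],       "classification": "unstable node"},
    "E1": {"point": [0.0, 1.0],       "classification": "stable node"},
    "E2": {"point": [1.0, 0.0],       "classification": "stable node"},
    "E3": {"point": [0.0437, 0.6993], "classification": "saddle (unstable)"}
  }
}
```

The coexistence point $E_3$ is a saddle: almost every trajectory ends with
one language extinct.  The single-lever policies (`fig8b`: status only;
`fig8c`: interaction only) fail — `fig8b` has a sliding segment but no
pseudo-equilibrium on it, `fig8c` has no sliding segment at all.

The same analyses are available as library calls
(`lingslide.interior_equilibrium`, `lingslide.pseudo_equilibrium`,
`lingslide.integrate_hybrid`, ...) and on user parameter sets via flat
key-value config files (`--config`).

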