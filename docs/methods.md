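# Methods

## Model

The two-compartment model tracks the drug concentration in a central (plasma)
compartment `c(t)` and a peripheral (tissue) compartment `p(t)`:

```
dc/dt = k21·p − k12·c − k10·c + I(t)
dp/dt = k12·c − k21·p
```

Assumptions: both compartments are well-stirred and homogeneous; transfer
between them and elimination (central compartment only) are first-order with
constant rates; the infusion, when present, is a constant zero-order input.
In state-vector form `u = (c, p)`, `u' = A·u + b` with

```
A = [ −(k10+k12)   k21 ]        b = (I0, 0)
    [   k12       −k21 ]
```

The column sums of `A` are `(−k10, 0)`: with no infusion, total drug
`c + p` decreases at rate `k10·c` — mass leaves only through central
elimination. `det A = k10·k21 > 0` and `tr A < 0`, so both eigenvalues are
real and negative for every admissible parameter set: the equilibrium
(`(0,0)` for a bolus; `c* = I0/k10`, `p* = k12·I0/(k10·k21)` under infusion)
is an asymptotically stable node. The discriminant
`(k10+k12+k21)² − 4·k10·k21` reduces to `(k10−k21)²` when `k12 = 0`, so a
repeated eigenvalue occurs only in that no-transfer case with `k10 = k21`;
it is handled by explicit confluent-limit formulas rather than rejected.

Two sign conventions coexist downstream: positive decay rates
`lam1 ≥ lam2 > 0` (closed forms written with `e^{−lam·t}`) and the matrix
eigenvalues `mu = −lam < 0`. `EigenSystem` carries both, and every formula
documents which it consumes; the NSFD weights in particular must be built
from the negative `mu` values (decaying exponentials) — building them from
the positive rates produces a growing, non-exact scheme.

## Closed-form solutions

The homogeneous propagator of a 2×2 system has the Lagrange–Sylvester form
`e^{At} = φ(t)·I + ϕ(t)·A` with scalar weights

```
ϕ(t) = (e^{μ₁t} − e^{μ₂t})/(μ₁ − μ₂),   φ(t) = (μ₁e^{μ₂t} − μ₂e^{μ₁t})/(μ₁ − μ₂)
```

and confluent limits `ϕ = t·e^{μt}`, `φ = (1 − μt)·e^{μt}`. The general
solution with constant infusion is `u(t) = u* + e^{At}(u0 − u*)`, where
`u* = −A⁻¹b` is the steady state. This form is used for all evaluation
because it is uniformly well-conditioned: the transient is a pure product of
decaying exponentials, so the `t → ∞` limit is exact in floating point and no
large terms are subtracted.

The familiar modal forms are exposed as coefficient objects and a
cross-validation evaluator:

- bolus: `c(t) = E·e^{−lam1·t} + (1−E)·e^{−lam2·t}`,
  `p(t) = k12/(lam2−lam1)·(e^{−lam1·t} − e^{−lam2·t})`, with
  `E = (lam1−k21)/(lam1−lam2)`;
- infusion: `c(t) = I0/k10 + A1·τ1·e^{μ₁t} + A2·τ2·e^{μ₂t}`,
  `p(t) = k12·I0/(k10·k21) + A1·e^{μ₁t} + A2·e^{μ₂t}`, with eigenvector
  components `τ = (k21+μ)/k12` and amplitudes fixed by the zero initial
  condition.

The modal infusion amplitudes scale like `1/k12` and cancel catastrophically
for small transfer rates (absolute errors ~1e−10 already at `k12 ≈ 1e−3`),
which is why `infusion_solution` routes through the propagator form and the
modal evaluation (`infusion_solution_modal`, requiring `k12 > 0`) is kept only
as an independent algebraic cross-check. Tests verify both routes against a
scipy `expm` oracle.

## Schemes

- **SFD** — explicit forward Euler, `u_{n+1} = u_n + h(Au_n + b)`, exactly as
  conventionally written. First-order accurate; oscillates once
  `h > 2/lam1` (≈ 26.5 min for the Subject 1 rates) and blows up for larger
  steps. This behavior is intentional — it is the phenomenon being measured.
- **NSFD (bolus)** — `(u_{n+1} − φ(h)u_n)/ϕ(h) = A·u_n`, i.e.
  `u_{n+1} = (φI + ϕA)u_n = e^{Ah}u_n`: node-exact for any `h`.
- **NSFD (infusion)** — the exact affine flow over one step,
  `u_{k+1} = M·u_k + (M−I)A⁻¹b` with `M = e^{Ah}`; its fixed point is the
  steady state. An equivalent formulation — substituting the current node
  into the general closed form over an interval `h` — is implemented
  separately and tested to agree to rounding.
- **RK45** — scipy's adaptive Dormand–Prince pair with dense output sampled at
  the grid nodes, as the conventional-solver reference. Defaults are
  `rtol = 1e−6`, `atol = 1e−9`, chosen so the reference tracks the closed form
  at the ~1e−8 level on the benchmark problems; at `rtol = 1e−3` scipy's
  controller leaves errors near 5e−5 on these slowly varying systems, which
  would misrepresent a production-quality reference. The RK45 error column is
  reported structurally but is solver-implementation-specific; no exactness
  or cross-implementation agreement is claimed for it.

Exactness of the NSFD schemes is dynamical consistency in the strongest
sense: iterates inherit positivity, boundedness (infusion iterates never
exceed `c*` from below), monotone approach to the steady state, and the
continuous stability classification, for every step size.

## Benchmarks

Error tables integrate over the fixed horizon `T = 20` min on a doubling
ladder `N ∈ {2, 4, …, 1024}` with `h = T/N` computed exactly (printed step
sizes like 0.01953 are rounded displays of 20/1024). The error statistic is
the **maximum absolute node error** over nodes `n = 1..N` against the closed
form, per compartment; for these decaying/saturating systems the first node
dominates, which a hand evaluation of the one-step `h = 10` run confirms
(bolus: Euler gives `(0.501, 0.405)` vs analytic `(0.64591, 0.27873)`, errors
0.144913386 and 0.126270717). Convergence order is estimated per ladder rung
as `log₂(err(N)/err(2N))`; schemes whose errors sit at the double-precision
floor (< 1e−12) are flagged exact instead. Long-horizon infusion runs
(`T = 2000` min) report the final-node distance to `c*` and the number of
sign changes of successive increments — a nonzero count detects the spurious
Euler oscillation at large `h`.

## Parameters and defaults

| parameter | units | default | meaning |
|---|---|---|---|
| k10 | min⁻¹ | — (>0) | central elimination rate |
| k12 | min⁻¹ | — (≥0) | central→peripheral transfer |
| k21 | min⁻¹ | — (>0) | peripheral→central return |
| I0 | mg/(min·mL) | 1.0 | infusion rate (optionally D/Vp) |
| c0, p0 | mg/mL | 1, 0 (bolus) / 0, 0 (infusion) | initial concentrations |
| T | min | 20 (tables) / 2000 (long runs) | horizon |

The four built-in subjects are sisomicin serum-kinetics estimates; random
parameter sets for property tests are drawn log-uniformly from
`[1e−3, 1e−1]` min⁻¹, bracketing those values, and are admissible (hence
stable) by construction. Units are carried as metadata strings only; no
runtime dimensional analysis is attempted because the bolus case uses a
normalized concentration (`c(0) = 1`) alongside mg-based infusion units.

## Numerical choices

- All arithmetic in double precision; CSV serialization at 17 significant
  digits (bitwise round-trip; reading uses pandas' `round_trip` float parser,
  whose default parser is off by one ulp).
- Exactness comparisons for the infusion case are normalized by the
  problem's intrinsic scale `max(1, c*, p*)`: both the scheme and the closed
  form represent `u* + transient`, so either carries rounding of order
  `eps·|u*|` (up to ~1e−11 when `u* ~ 1e5`), which an early-time
  trajectory-value normalization would misread as scheme error.
- Grid construction validates that `T` is an integer multiple of `h` (1e−9
  relative slack for binary representation).
- Repeated eigenvalues take the confluent `ϕ, φ` limits; `k12 = 0` disables
  the modal (τ-based) forms, and all evaluation falls back to the propagator.

## Limitations

- Linear kinetics only: no saturable (Michaelis–Menten) elimination, no
  nonlocal discretizations of nonlinear terms, and only two compartments.
  Exactness is a property of linear constant-coefficient systems; for
  nonlinear models an NSFD scheme is dynamically consistent but not exact.
- The benchmark inputs are printed parameter sets, not concentration data;
  the package performs no parameter estimation.
- The RK45 error column depends on the underlying solver implementation and
  should not be compared across libraries.
- No figure rendering: phase portraits and trajectories are exported as CSV
  for external plotting.
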