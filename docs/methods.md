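# Methods

## Model

The simulator integrates a three-state cubic regulatory system for the
glucose–insulin axis. The states `(y1, y2, y3)` are abstract
physiological coordinates (the literature that introduced this family of
models labels them glucose, insulin and β-cell activity, though not
consistently; `cfglucose` carries the labels as metadata only and never
uses them in computation). The field is polynomial of degree three with
21 kinetic constants `a1..a21`; the shipped defaults are the published
Shabestari-type parameterization (e.g. `a1 = 2.04 min⁻¹` baseline glucose
decay, `a20 = −0.19 mmol·L⁻¹·min⁻¹` basal influx, `a21 = −0.56
μU·mL⁻¹·min⁻¹` basal insulin generation). With these values the
uncontrolled classical (`α = β = 1`) system evolves on a bounded chaotic
attractor with maximal Lyapunov exponent ≈ +0.2.

Two printed variants of the insulin equation circulate, differing in the
sign of the `a8·y1·y2` cross term. The canonical form here uses `−a8`;
`ModelParameters.gamma2_sign_convention = "existence"` selects the `+a8`
variant. Both are wired through the RHS and the analytic Jacobian.

Linear state feedback subtracts `d1·(y1+y2)` from the first equation and
`d3·(y1+y3)` from the third. Gains must be non-negative; the
tuning-multiplier range `k ∈ [0.1, 0.3]` of the proportional rule
`d_i = k_i·|Re(λ_max)|` is advisory (a warning, not an error), because
the gain pairs conventionally applied to this model exceed what the rule
yields.

## Operators

The Caputo–Fabrizio (CF) derivative replaces the power-law kernel of the
classical Caputo operator with the non-singular exponential kernel
`exp(−α(t−μ)/(1−α))`, normalized by `B̂(α) = 1 − α + α/Γ(α)` (equal to 1
at both `α = 0`, as a continuous limit, and `α = 1`). The
fractal-fractional (FF) extension differentiates with respect to `t^β`;
variable order (VO) lets `β(t)` evolve. This is the only kernel
implemented: an exponentially tempered variant that appears in some
descriptions of the same scheme is redundant with the CF kernel the
update rules are actually derived from, and is deliberately omitted.

Shipped `β(t)` profiles: `const:<v>`, `cos_slow` (`0.97 + 0.03 cos(t/10)`,
circadian-like), `cos_fast` (`0.95 + 0.02 cos t`, the worked-example
profile), `tanh1p` (`tanh(1+t)`, gradual memory accumulation), `sigmoid`
(`1/(1+e^{−t})`). Values are clipped to `[1e−3, 1]` so `t^{β−1}` stays
finite; on `t ∈ [0, 120]` no shipped profile ever touches either clip
bound (`cos_slow` equals exactly 1.0 at `t = 0`, which is allowed).
Custom profiles may be passed as callables, optionally with an analytic
derivative.

`β′(t)` is evaluated in one of two modes. `forward_difference`
(`(β(t+Δt)−β(t))/Δt`) is the default everywhere because it is exactly the
slope appearing in the discrete kernel coefficient
`κ_n = t_n^{β(t_n)}·(slope·ln t_n + β(t_n)/t_n)`, which makes the
identity `g_n = κ_n·ℏ_n` hold to machine precision and makes the VO
scheme collapse exactly onto the fixed-order scheme for constant `β`.
`analytic` mode uses closed forms and is available for all shipped
profiles.

The CF-FF integral is provided as a validation utility. Its integrand
`μ^{α−1} f(μ)` is weakly singular at 0, so the "trapezoid" is realized as
product integration: exact moments of `μ^{α−1}` against the
piecewise-linear interpolant of the samples. It is not on the solver hot
path.

## Fixed-order scheme

With constant `β`, the RHS is scaled once per node,
`U_n = β t_n^{β−1} f_n`, and the update is

```
y_{n+1} = y_n + (1−α)/B̂(α) · (U_n − U_{n−1}) + α/B̂(α) · P_n(U) · Δt
```

with the third-order Newton (Adams–Bashforth) polynomial
`P_n = (5/12)U_{n−2} − (4/3)U_{n−1} + (23/12)U_n` for `n ≥ 2`, the
two-point polynomial `(3/2)U_1 − (1/2)U_0` at `n = 1`, and the
single-point value at `n = 0`. Two conventions deserve note:

* **The factor `β t^{β−1}` is applied exactly once**, inside `U`. Some
  printed forms of this update show an additional `β` in the prefactor of
  the memory difference; applying both would square `β` and break the
  classical limit. Under the convention used here, `α = β = 1` recovers
  classical 3-step Adams–Bashforth coefficient-for-coefficient, which the
  tests verify to machine precision, with measured global order ≈ 3 on
  `y′ = −y` when the stepper is seeded with exact starting values.
* **The initial node**: `t^{β−1}` is singular at `t = 0` for `β < 1`, and
  the short-memory convention zeroes the scaled sample there. The zeroing
  is applied **only when `β < 1`**; at `β = 1` the weight is exactly 1
  and `U_0 = f_0` is used. Zeroing unconditionally would make the first
  step a no-op in the classical limit and silently degrade the method to
  first order — measurably wrong, so the package restricts the convention
  to the singular case it exists for.

Consequences of the zeroed initial sample at `β < 1`: the first step
leaves the state unchanged, so the sup-norm stopping rule
(`‖y_{n+1}−y_n‖∞ < 10⁻⁸`, configurable) is evaluated only from the
second step onward to avoid a spurious immediate stop.

The Euler-type start caps the composite method at global order 2
(measured); this is inherent to the printed startup, not an
implementation artifact.

Divergence handling: any state exceeding `1e6` in magnitude (or going
non-finite) terminates the run; the trajectory is truncated at the last
finite state and flagged `diverged`. Chaotic escapes must fail loudly,
never overflow silently.

## Variable-order scheme

For time-varying `β(t)` the scaling weight becomes the kernel coefficient
`κ_n` above (the discrete form of `d/dt t^{β(t)} = t^{β(t)}(β′ ln t +
β/t)`), and the update over `[t_n, t_{n+1}]` is the two-point rule

```
u_{n+1} = u_n + (1−α)/B̂(α) · (κ_n ℏ_n − κ_{n−1} ℏ_{n−1})
        + α/B̂(α) · ((3/2)g_n − (1/2)g_{n−1}) · Δt
```

applied component-wise with `ℏ` the corresponding (controlled) RHS
component. Three design choices were genuinely open:

* **Parse of the update.** The one-line printed form of this rule is
  typographically ambiguous. The parse above — a memory *difference*
  `κ_n ℏ_n − κ_{n−1} ℏ_{n−1}` mirroring the fixed scheme's
  `U_n − U_{n−1}` — is the unique reading under which the VO scheme
  reduces to the fixed-order two-point scheme for constant `β`
  (verified: ≤ 5e−14 sup-norm difference over 5000 steps) and respects
  the CF operator structure (local non-singular term + integral term).
* **Component coupling.** The source update is written for a scalar
  auxiliary variable "inserted into the governing system"; it is applied
  here component-wise to all three states, matching the fixed scheme.
* **First node.** `κ` requires `t > 0`; node 0 uses the fixed-order
  bootstrap with the short-memory convention, and the node-0 kernel
  products are initialized to the scaled sample `U_0`.

The VO quadrature is two-point by construction (a three-point VO variant
is out of scope), so against the *three-point* fixed scheme the
constant-β difference is O(Δt²) ≈ 1e−6 at Δt = 1e−3 — the exact
equivalence is with the fixed scheme's `poly_order = 2` variant, which is
what the reduction tests use. The scheme is consistent and stable when
`β′(t)` is bounded, which holds for all shipped profiles.

**Memory-direction behavior.** The qualitative claim "rising `β`
(weakening memory) stabilizes faster" is regime-dependent under this
scheme: the fractal weight `β t^{β−1}` *increases* with falling `β` for
`t < 1` and *decreases* with it for `t > 1`. On `y′ = −y` with mirrored
linear ramp profiles (0.7 ↔ 1.0), the falling profile wins a sprint to
`|y| < 0.1` (t ≈ 2.7 vs 3.5), while the rising profile reaches the
settled regime `|y| < 10⁻³` sooner (t ≈ 10.7 vs 12.4) because the
falling profile's weight collapses at late times. The property test
asserts the asymptotic (stabilization) direction, which is what the
claim is about.

## Simulation settings

Defaults: `Δt = 0.001`, `T = 120` (dimensionless time units), relative /
absolute accuracy targets `10⁻⁶ / 10⁻⁸` (used by the self-convergence
check and the equilibrium solver — the explicit one-pass scheme itself is
not iterative), stopping threshold `10⁻⁸`, blow-up threshold `10⁶`,
default gains `(d1, d3) = (0.2, 0.1)`, initial state `(0, 1.5, 1)` with
`(0.5, 1, 1)` and `(1.4, −1.5, 1.31)` as the published alternatives.

Self-convergence on the controlled chaotic system is second order
(startup-limited); at `T = 10` the endpoint change under halving falls
below `10⁻⁶` relative once `Δt ≤ 1.25e−4`, because discretization error
is amplified by the flow (max Lyapunov ≈ +0.13) before that. The tests
measure both the order and the threshold.

## Scenario presets

Twelve presets (figure ids 2–13, equal to the published gain-table rows
1–12 shifted by one) bundle `(α, β-profile, d1, d3)` with the default
grid. The constant-order family (figs 2–4, 8–10) uses gains
`(0.20, 0.10)`; the oscillatory VO family (5, 11) uses `(0.22, 0.12)`
with `α = 0.98`; the `tanh` family (6, 12) `(0.25, 0.12)`; the sigmoid
family (7, 13) `(0.25, 0.15)`. Which published initial triple belongs to
which figure is not recorded anywhere; presets default to `(0, 1.5, 1)`
with the others selectable.

**What the presets do and do not show.** The presets are simulation
configurations, not data: passing runs demonstrate properties of the
discretized model under exactly these parameters, and say nothing about
fit to clinical IVGTT measurements (no such data is bundled; the NRMSE
metric is provided for future comparisons). Moreover, not all published
configurations are reproducible as described:

* With gains `(0.20, 0.10)` at `α = β = 1` the feedback tightens the
  late-window (`t ∈ [20, 120]`) sup-norm of the attractor from 1.878 to
  1.799, and the maximal Lyapunov exponent drops from ≈ +0.20 to ≈ +0.13
  (horizon 400) — a reduction, but *not* a transition to a stable
  steady state: the controlled equilibrium's linearization is unstable
  (spectral abscissa +0.67) and the controlled system remains chaotic.
* With `α = 0.98, β = 1` and the same gains, both runs are bounded but
  the controlled late-window sup-norm (1.640) slightly *exceeds* the
  uncontrolled one (1.619).
* The larger tabulated gain pairs `(0.22, 0.12)`, `(0.25, 0.12)` and
  `(0.25, 0.15)` push the state out of the attractor basin into a
  finite-time blow-up (t ≈ 8–15) from **every** published initial
  condition, at every tested order combination, under **every** reading
  of the ambiguous printed terms. This was cross-checked with an
  adaptive RK oracle at tight tolerances, which blows up at the same
  time to three decimals — it is a property of the equations, not of the
  scheme. These runs terminate with the `diverged` flag.

The corresponding acceptance checks are therefore split: the presets
whose configurations behave as described pass, and the others fail
honestly with the divergence/ordering evidence in the assertion message.

## Control design

`closed_loop(A, B, K)` assembles `A − BK` with gain row `[d1, 0, d3]`;
`spectrum` uses a dense eigensolver and cross-checks nothing silently —
the trace identity is asserted in tests, and the worked three-state
example's eigenvalues are validated against its characteristic
polynomial (`λ³ + 0.3λ² + 2.02λ + 1` for gains `(3, 2)`). Published
eigenvalue tables for this example are inconsistent with the trace of
the printed matrices and are never asserted; the computed spectra show
the printed example's open loop is in fact stable (abscissa −0.080) and
the printed gain sequence monotonically *destabilizes* it (abscissa
−0.080 → −0.050 → +0.088 → +0.299).

## Diagnostics

* **Lipschitz / contraction constants**: the closed forms
  `γ1 = a1 + a2 K_y3`, `γ2 = a8 K_y1 + a11(1 + 2K_y2)`,
  `γ3 = a18 + a19 K_y2` are evaluated verbatim — no absolute values are
  inserted even though `γ3 < 0` with the default constants, and the
  contraction requirement `M = max γ_i < 1` fails for any bounds because
  `γ1 ≥ a1 = 2.04`. The report states what the formulas give.
* **Hyers–Ulam constants**: `λ = (β(1−α)t^{β−1} + αβT^{β−1})/B̂(α)`,
  identical for all three components. The `β = 1` branch returns
  `1/B̂(α)` directly so the collapse is exact in floating point; at
  `α = 1` the local term vanishes, leaving `βT^{β−1}`.
* **Lyapunov exponents**: Benettin QR re-orthonormalization along the
  simulated base trajectory (early stopping disabled). The variational
  flow uses the analytic Jacobian of the controlled field with a
  frozen-Jacobian second-order step `Q ← (I + ΔtJ + Δt²J²/2)Q`,
  re-orthonormalized every 10 steps by default, with the leading 20% of
  the horizon discarded. On linear diagonal systems the estimates match
  the eigenvalue real parts within 2% at `Δt = 0.002, T = 30`. On the
  chaotic regulatory system the estimates converge slowly; horizon 400
  is used for the controlled-vs-uncontrolled ordering (at horizon 100
  the two estimates are not yet separated). A random orthonormal initial
  frame is available via `seed`; the default is the identity.
* **NRMSE**: `sqrt(mean((ref − model)²)) / (max(ref) − min(ref))`;
  affine-invariant, undefined (error) for a constant reference.

## Known limitations

* The integrators are explicit one-pass schemes: no adaptive stepping,
  no implicit or predictor–corrector variants, no dense output.
* Only the exponential (CF) kernel is implemented — no Mittag-Leffler
  (Atangana–Baleanu) or power-law (Caputo) kernels.
* The fractal exponent acts through the operational update rules; the
  package does not attempt a quadrature of the continuous FF derivative
  definition beyond the validation-grade CF-FF integral.
* Parameter estimation from patient data, unit conversion and
  physiological re-parameterization are out of scope.
* As detailed above, several published gain configurations are
  dynamically inconsistent with the printed equations; the package
  reproduces the equations, reports the inconsistencies, and does not
  silently "correct" either.
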