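# Methods

## Model

The package models the entropy-driven amplifier (EDA) strand-displacement
circuit with mass-action kinetics over seven species
(x, a, y, b, c, d, e) = (substrate, catalyst, intermediate, block waste,
fuel, spine–fuel product, ThT signal). The network topology is fixed: a
reversible catalyst-exchange step (rates k1, k−1) and an irreversible fuel
step (rate k2). Three linear conservation laws — substrate
(x + y + e = x0 = x + b), catalyst (a + y = a0) and fuel (c + e = c0) —
hold exactly along the flow because the corresponding derivative sums
cancel symbolically; they reduce the system to the two dynamic species
(x, y). Since d and e are produced one-for-one by the fuel step and both
start at zero, reconstruction sets d = e.

All parameters are treated as dimensionless numbers exactly as given.
The source material mixes mol/L, minutes and rate constants of order 1e4
without dimensional bookkeeping, so the package does none either; only
ratios and products of the parameters are ever meaningful here.

### The sign ambiguity and the `mode` flag

Substituting the conservation laws into the full model yields an
x-equation cross-term (k1 − k−1)·x·y, while the published reduced system
uses c1 = k−1 − k1, i.e. the opposite sign. Both are implemented:

* `paper_literal` (default) reproduces the published reduced system
  verbatim and is what the stochastic extension and threshold formulas
  are stated for;
* `corrected` uses c1x = −c1 and is the only mode for which the reduced
  model is trajectory-equivalent to the projected full model (verified to
  relative sup-norm 1e−6 in the tests; the paper-literal discrepancy is
  measured and asserted to be nonzero whenever k1 ≠ k−1).

Only the x-equation differs between modes; the y-equation agrees with the
published form in both.

### Invariant region

The published invariant region is {x, y > 0, x + y < K} with
K = k2(x0−c0)/(2k−1−k2), which requires x0 > c0 and 2k−1 > k2. Under the
corrected drift, d(x+y)/dt = k2·y·((x0−c0) − x − y), so the natural sum
bound in corrected mode is x0 − c0 instead; both bounds are reported.
Membership tests take all inequalities strictly.

## Stochastic extension

Disturbances enter as one shared channel, −x·y(σ dB + ∫γ dÑ) on x and the
same with + on y, where Ñ = N − λ(du)dt is a compensated Poisson random
measure with finite total intensity λ(Y) and mark amplitude law γ(u).
Two mark dialects are supported — constant γ and uniform on [low, high] —
both with closed-form mark integrals ∫γ λ(du) and ∫γ² λ(du), so the
compensator and the effective noise intensities need no quadrature.
Infinite-activity (α-stable) noise is out of scope by construction
(λ(Y) < ∞).

### Discretisation

Explicit Euler–Maruyama with per-step Poisson jump batches: per step, the
Brownian increment is drawn first, then the Poisson count, then any marks
(this order is a fixed contract so seeds are portable); all marks apply at
step end and the compensator is subtracted analytically. Jump times within
a step are not resolved. Defaults are dt = 1e−3 and t_end = 100, both
config-overridable; integration is fixed-step only, so runs are
bit-reproducible and grids stay aligned for time-average diagnostics
(adaptive stepping was rejected for that reason).

The exact solution stays positive, but the explicit scheme can overshoot;
the policy is clamp-to-zero with a per-step flag and a logged event count.
Step halving and implicit schemes were considered and left as extensions.
Because the noise enters x and y with equal magnitude and opposite sign,
the per-step x+y increment equals the drift-only increment exactly (up to
rounding); this identity is checked on every step of a 1e5-step run.

Scheme correctness is established two independent ways: a
strong-convergence experiment against a shared-noise dt/64 refinement, and
a moment oracle on the linear test equation
dX = μX dt + σX dB + X⁻∫γ dÑ, whose exact mean x0·e^{μt} is independent
of σ and γ because both noise terms are mean-zero martingales.

## Thresholds

All threshold quantities are evaluated exactly as printed, with margins
reported next to every boolean so near-boundary classifications are
auditable; strict inequalities are taken literally (margin 0 ⇒ condition
false). Two documented source inconsistencies are surfaced rather than
repaired:

* R0 is never defined in the source. The package adopts
  R0 := (c1/b2)·K by structural analogy with extinction condition (b)
  (whose expression is (c1/b2)K − (σ′²/2b2)K² < 1; persistence is posited
  as the > 1 counterpart with σ″²). The definition is overridable per
  call and flagged in every report.
* The persistence lower bound's prefactor is (2k−1+k2)/k2 in the theorem
  statement but (2k−1−k2)/k2 at the end of its proof; both variants are
  computed and reported, with the statement variant as the default scalar.

The regime verdict is a pure function of the condition booleans:
condition (a) → `end_a`; condition (b) and not (a) → `end_b`; R0* > 1
alone → `persistent`; an extinction condition together with R0* > 1 →
`conflict` (the printed sufficient conditions are not mutually exclusive);
none → `indeterminate`. The jump-size assumption |K·γ(u)| ≤ δ < 1 is
evaluated and reported with its margin but does not change the verdict —
when it fails, a warning states that the theorems' hypotheses do not
apply. The source's own printed check values for its three simulation
cases could not be recovered from its printed parameters under any
reading tried; every report therefore carries a standing discrepancy
warning, and the printed values ship only as `not_reproducible`
annotations on the case fixtures.

## Diagnostics

Running time averages use left-endpoint quadrature, matching the
left-limit (t⁻) convention of the jump dynamics; the difference from the
trapezoid rule is O(dt). The correction series
φ(t) = −[(x(t)−x(0))/t + (y(t)−y(0))/t] / ((2k−1−k2)·⟨y⟩(t)) is exposed
with NaN (not exceptions) where ⟨y⟩ = 0. The mean-balance relation
⟨x⟩ = K − (k2/(2k−1−k2))⟨y⟩ + φ(t) is exposed only as a diagnostic
residual: its derivation replaces ⟨xy⟩/⟨y⟩ by ⟨x⟩, so the residual
quantifies that gap and is never a correctness assertion.

Growth-rate estimation returns both the endpoint estimator ln y(T)/T and
a tail regression slope of ln y versus t; the tail slope is the preferred
comparator against the closed-form bounds. The estimate uses the segment
before the first y ≤ 0 and flags truncation. Extinction detection
requires y ≤ tol sustained through the end of the horizon (a dip with
recovery is not extinction); tol defaults to 1e−6 × max y and the tail
fraction for tail statistics defaults to 0.5 — the source specifies
neither, so both are exposed in the configuration.

## Fixtures and study conditions

**Published cases.** The three published noise settings share
k1 = 2e4, k−1 = 1.8e4, k2 = 2.1e4, a0 = 2.8e−4, c0 = 1.4e−4, λ(Y) = 1 and
start (x(0), y(0)) = (1.5e4, 0). That starting value sits five orders of
magnitude above every other concentration and makes b2 < 0, which renders
the dynamics divergent at any explicit step size; it is very likely a typo
for 1.5e−4. Both readings are exposed (`as_printed`, `rescaled`) and
neither is asserted as intended. The `reproduce` command runs both; the
as-printed path is truncated at the last finite state and flagged instead
of failing.

**Regime fixtures.** Because the published parameters land in no provable
regime, the empirical theorem tests use parameter sets found by uniform
random search inside per-regime bounding boxes, committed together with
the search seed, bounds, budget and hit index (the suite re-runs the
search and checks it regenerates the committed set bit-for-bit). The boxes
were chosen analytically, before any ensemble was run, so that the
closed-form condition and the dynamics agree:

* extinction boxes (conditions a and b): the catalyst loading is set to
  a0 ~ 1e−29, making the feed a1 = k1·a0 negligible, so the
  intermediate's quasi-equilibrium floor a1·x/b2 lies far below its decay
  range over the horizon and the log-drift −b2 + c2·x (with b2 > 0 and
  c2 = c1 − k2 < 0 throughout the box) is uniformly negative. The
  condition-(a) box uses k1 ≈ k−1 (c1 ≈ 0, so the threshold c1²/(2b2) is
  tiny) with strong white noise; the condition-(b) box uses k−1 > k1
  (c1 > 0) with moderate noise.
* persistent box: c1 > 0 with k2 > 2c1 (so the paper-literal x+y drift
  stays bounded), a substantial catalyst feed sustaining a positive
  quasi-equilibrium of y, and small noise so R0* > 1 with the jump-size
  assumption satisfied.

Fixture ensembles use 200 replicates (replicate r at seed base+r) on
grids dt = 1e−3 with horizons 25 (extinction fixtures) and 20
(persistent) — long enough for the extinction fixtures to decay from
y(0) = 0.2 to well below the detection tolerance, short enough that the
whole suite stays at desk scale.

**Synthetic decay.** The estimator ground truth is
y(t) = exp(−rate·t + noise_level·W(t)) with W a seeded Gaussian random
walk. The tail-slope estimator is unbiased with sampling error ≈ 0.025 at
noise_level = 0.1 over T = 50, so single replicates sit within 5% of the
programmed rate only about half the time; the recovery checks therefore
use a committed replicate plus a 10-replicate average.

What the generators do not emulate: real fluorescence data (measurement
noise, baseline drift, photobleaching), parameter uncertainty, and any
jump structure beyond finite-activity compensated Poisson noise with
constant or uniform marks. Passing tests show internal consistency of
model, scheme and theory at these conditions — not agreement with wet-lab
EDA kinetics.

## Numerical choices

* RK4 (default) or forward Euler, fixed step; non-finite states abort
  with the offending time (or truncate, where explicitly requested).
* Admissibility of reconstruction is checked to −1e−12 per species, with
  the violated species named; tiny negatives are clipped to zero.
* Degenerate denominators (2k−1 = k2, b2 = 0, K = 0, c1 = 0 where
  divided by) raise named errors rather than returning infinities.
* Trajectory CSV floats use shortest round-trip representation and are
  read back with exact parsing, so artifact round-trips are bit-exact;
  stochastic artifacts embed their seed and a config hash.

## Known limitations

* No jump-adapted grids, Milstein or implicit schemes; step control is
  the user's responsibility and blow-ups are reported, not repaired.
* The threshold module evaluates the printed formulas (plus the two
  documented variants); it does not attempt to re-derive or repair the
  theorems, and defers empirical truth to simulation.
* The paper-literal reduced model is not consistent with the full model
  (that is the point of the mode flag); results produced in that mode
  inherit the published sign convention and its consequences.
* No fitting to experimental data and no general reaction-network
  parser; the topology is fixed to the EDA circuit.
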