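# edacircuit

Kinetics of the entropy-driven DNA amplifier (EDA) circuit under Lévy jump
noise: a deterministic mass-action model, its conservation-law reduction, a
jump-diffusion stochastic extension, and the closed-form
extinction/persistence threshold theory — together with the simulation and
trajectory diagnostics needed to test that theory empirically.

## The problem

The EDA circuit is a catalytic DNA strand-displacement network used for
enzyme-free signal amplification: a catalyst strand reversibly displaces
the blocking strand of a `Spine–ThTSignal–Block` substrate, and a fuel
strand then irreversibly releases the Thioflavin-T-binding signal strand
while regenerating the catalyst. Net reactions (x = substrate,
a = catalyst, y = intermediate, b = block waste, c = fuel, d = spine–fuel
product, e = ThT signal):

```
x + a  ⇌(k1, k-1)  y + b
y + c  →(k2)       d + e + a
```

Mass action gives a seven-species polynomial ODE; substrate, catalyst and
fuel conservation (`x + y + e = x0 = x + b`, `a + y = a0`, `c + e = c0`)
reduce it to the two dynamic species:

```
dx/dt = −a1·x + b1·y + c1x·x·y
dy/dt =  a1·x − b2·y + c2·x·y − k2·y²
```

with `a1 = k1·a0`, `b1 = k−1·x0`, `b2 = k−1·x0 + k2·(c0−x0)`,
`c2 = k−1 − k1 − k2`. Sudden disturbances of a running reaction (thermal
shock, a catalyst bolus) enter as one shared noise channel with opposite
signs on x and y:

```
dx = f_x dt − x·y [ σ dB + ∫_Y γ(u) Ñ(dt,du) ]
dy = f_y dt + x·y [ σ dB + ∫_Y γ(u) Ñ(dt,du) ]
```

where B is Brownian motion and Ñ a compensated Poisson random measure of
finite intensity λ(Y). The theory expresses when y is driven to zero (the
reaction ends and ThT fluorescence saturates) or persists in time average,
in terms of effective noise intensities
`σ′² = σ² + ∫γ²/(1+δ)² λ(du)` and `σ″² = σ² + ∫γ²/(1−δ)² λ(du)`, the
coefficient `c1 = k−1 − k1`, and the invariant-region bound
`K = k2(x0−c0)/(2k−1−k2)`: extinction if `σ′² > c1²/(2b2)` (condition a) or
`σ′² ≤ c1/K` with `(c1/b2)K − (σ′²/2b2)K² < 1` (condition b); persistence
if `R0* = R0 − (σ″²/2b2)K² > 1`.

Two documented quirks of the source theory are handled explicitly rather
than papered over: the reduced x-equation's printed cross-term sign is
inconsistent with its own derivation (both conventions are implemented via
a `mode` flag — `paper_literal` and `corrected`), and R0 is never defined
in the source (the package adopts `R0 := (c1/b2)·K` and flags this in every
report). The source's printed numerical check values are not reproducible
from its printed parameters; they ship as annotations, never as
expectations, and every report carries discrepancy warnings. See
`docs/methods.md` for the full account.

## Worked example

Evaluate the thresholds and simulate one stochastic path for the mildest
published noise setting (σ = 0.2, γ = 0.15, δ = 0.2) at the rescaled
reading of the published starting value:

```python
from edacircuit import (
    RateConstants, InitialConditions, NoiseSpec, MarkLaw, SimOptions,
    derive_coefficients, classify_regime, simulate_sde, detect_extinction,
    tail_mean_y,
)

rates = RateConstants(k1=2e4, k_minus1=1.8e4, k2=2.1e4)
init = InitialConditions(x0=1.5e-4, a0=2.8e-4, c0=1.4e-4)
noise = NoiseSpec(sigma=0.2, lambda_Y=1.0,
                  mark=MarkLaw(type="constant", gamma=0.15), delta=0.2)

coeffs = derive_coefficients(rates, init)
report = classify_regime(coeffs, rates, init, noise)
print(f"sigma'^2  = {report.sigma_prime_sq:.6f}")
print(f"sigma''^2 = {report.sigma_dprime_sq:.6f}")
print(f"R0*       = {report.r0_star:.6f}")
print(f"regime    = {report.regime}")

traj = simulate_sde(rates, init, noise, SimOptions(dt=1e-3, t_end=50.0, seed=1))
extinct, t_ext = detect_extinction(traj)
print(f"extinct   = {extinct}")
print(f"tail <y>  = {tail_mean_y(traj):.3e}")
```

prints

```
sigma'^2  = 0.055625
sigma''^2 = 0.075156
R0*       = -0.011245
regime    = indeterminate
extinct   = False
tail <y>  = 8.779e-06
```

Reading this: the effective noise intensities are small, but with
`c1 = −2000` the adopted persistence index is negative, so none of the
sufficient conditions fires — the classification is honest about the fact
that the printed parameter set does not land in any provable regime
(`report.warnings` spells out the discrepancies). The simulated path
itself neither dies out nor is driven extinct over the horizon, and its
tail time-average of the intermediate stays at the scale of the (tiny)
concentrations involved.

Parameter sets that *do* land provably in each regime — extinction via
condition (a), via condition (b), and persistence via R0* > 1 — are
committed under `src/edacircuit/fixtures/` with the search seeds that
produced them, and ensembles on them behave as classified (that is what
the acceptance suite checks).

A CLI wraps the same functionality:

```
eda-circuit conditions --config run.json --out report.json
eda-circuit simulate   --config run.json --seed 42 --out traj.csv
eda-circuit ensemble   --config run.json --n 200 --seed 1 --out summary.json
eda-circuit reproduce  --case 3 --seed 1 --outdir out/
eda-circuit search     --regime persistent --seed 1 --out found.json
```

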