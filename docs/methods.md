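# Methods

## Carbonate-system solver

The engine solves the surface-seawater CO₂ system on the **total pH
scale** at 0 dbar. Equilibrium constants: K₁/K₂ from Lueker et al.
(2000), K₀ from Weiss (1974), borate from Dickson (1990b), bisulfate
from Dickson (1990a, free scale), total boron from Lee et al. (2010),
HF from Perez & Fraga (1987), water, phosphate and silicate from the
Millero (1995)/Yao & Millero (1995) fits (seawater-scale, converted to
total), aragonite solubility from Mucci (1983), and calcium, sulfate and
fluoride proportional to salinity. Constants published on the seawater
scale are converted with (1 + S_T/K_S)/(1 + S_T/K_S + F_T/K_F).

Total alkalinity is expanded fully: carbonate, borate, water, phosphate,
silicate, free H⁺, bisulfate and HF. Nutrients default to
[Si(OH)₄] = 50 and [PO₄³⁻] = 0.5 µmol kg⁻¹ when unspecified.

Given (TA, DIC) or (TA, pCO₂), the solver brackets the alkalinity
residual — a strictly decreasing function of [H⁺] — on pH ∈ [2, 12] and
finds the root with Brent's method to machine precision; the residual at
the solution is far below the 10⁻³ µmol kg⁻¹ contract. Reported pCO₂ is
**fugacity-corrected**: CO₂* is converted to fCO₂ via K₀ and then to
pCO₂ with the Weiss (1974) virial coefficients at 1 atm. The correction
is below 0.5 % at surface conditions; users comparing against tools that
report fCO₂ should note the distinction.

Validity guards: the Lueker fit covers T 2–35 °C, S 19–43. Conditions
moderately outside raise a warning (constants extrapolated); fresh or
hypersaline water is refused with an error naming the carbonic-acid
constants.

Validation is dual-route: an independently coded reference
implementation (different constant transcription, bisection in pH on an
explicitly assembled proton condition) lives in the test suite, and the
two paths agree over a 1000-point Latin hypercube (TA 2000–2500, DIC
1700–2400, T 0–30 °C, S 30–38) to better than 0.0005 in pH and 0.1 % in
pCO₂; carbonic-acid pK values are also pinned to their published check
values at S = 35, 25 °C (5.847, 8.966).

## Maximum uptake efficiency ηmax

ηmax = [DIC(TA + ΔTA; pCO₂) − DIC(TA; pCO₂)]/ΔTA at fixed pCO₂ — the
full-equilibration DIC gain per unit alkalinity. The default probe is
ΔTA = 1 µmol kg⁻¹ (a near-derivative; 10 and 100 are exposed for
finite-dose efficiencies). ηmax falls with temperature, so polar water
out-absorbs subtropical water. Regional area-weighted means use
cos(latitude) weights; on synthetic grids the "coastal" cells carry a
boolean flag (real distance-to-coast computation is out of scope) and
"polar" means |lat| ≥ 60°. Analysis defaults adopt the regional means of
the observational reconstruction era: 0.832 (coastal) and 0.904 (polar).

## Response models

Calcification rate *y* versus TA−DIC *x*, per species, single rate unit:

* **linear**: y = a + bx, closed-form OLS; p-value from the two-sided
  t-test on the slope.
* **threshold**: y = c − b·exp(−kx), b ≥ 0, k > 0 — flat at plateau *c*
  for high x, dropping steeply below a critical region. The verbal
  description ("plateau, then decline below a critical value") admits
  several parameterizations; this three-parameter form is the simplest
  monotone one and is isolated behind `threshold_model()` so alternates
  can be swapped. Fitting is nonlinear least squares with deterministic
  multi-starts: c₀ slightly above max(y), b₀ = range(y), k₀ from a
  log-linearization, times {0.5, 1, 2}. The p-value is the F-test of the
  fitted model against the intercept-only model (which reduces to the
  OLS F-test in the linear case). A fit whose plateau is numerically
  flat over the design span is canonicalized to (mean(y), 0, k).

**Selection**: the model with the lowest p-value wins; species with
neither p < 0.05 are excluded. Failed fits count as p = 1.

**Prediction intervals** (α = 0.1, 90 %): linear —
ŷ ± t₀.₉₅,dof·s·√(1 + 1/n + (x*−x̄)²/Sxx); threshold — the delta-method
analogue, half-width t·s·√(1 + gᵀ(JᵀJ)⁻¹g) with g the parameter gradient
at x*. Empirical coverage is verified at 0.90 ± 0.03 over 2000
replicates.

**Decline** = 100·(1 − ŷ(x_now)/ŷ(x_PI)). Negative declines (rates
higher now) are reported as-is, not clamped; the positive-responder
selection makes them rare.

## Preindustrial state and scenarios

The preindustrial target holds TA constant (observations and models show
little industrial-era TA change), subtracts 142 µatm from the solved
current pCO₂ (420 − 278 atmospheric rise, preserving the local air-sea
disequilibrium), and re-solves at unchanged T, S and nutrients. With TA
constant, Δ(TA−DIC) = −ΔDIC identically.

Scenario factors d(TA−DIC)/dTA: NaOH 1 (unequilibrated) and 1 − f·η
(equilibrated); Na₂CO₃ ½ and ½ − f·(η − ½) — the reagent delivers two
TA-equivalents and one DIC per mole. Defaults f = 0.8, η regional as
above. The factor algebra is not free-standing: the test suite verifies
it against the packaged table's printed columns (Na₂CO₃ doubling;
equilibrated/unequilibrated ratios equal to the factor for every linear
responder). A factor ≤ 0 (f·η too large) means the scenario cannot
restore TA−DIC and raises.

`required_ta_exact_equilibrated` is the exact nonlinear counterpart at
f = 1: it root-finds the TA addition whose re-equilibrated state (at
constant current pCO₂) reaches the target, and agrees with the
η-linearization to first order; the discrepancy grows with dose.

**Responsiveness** is the percent rate gain for a fixed ΔTA = 50
µmol kg⁻¹ probe — in the range of natural coastal alkalinity variability
yet large enough to matter — evaluated through the scenario factor.

Rounding for summary tables: TA−DIC and doses to integers, percentages
to two decimals, all half-away-from-zero. The packaged fixture stores
the compilation's printed values; its unequilibrated-NaOH column carries
unrounded intermediates, so derived scenario doses use that column
rather than differencing the rounded TA−DIC columns (the two can differ
by 1 µmol kg⁻¹).

## Mitigation time

On monthly series, both the unperturbed and treated series are smoothed
with a **centered 12-month window** ([t−6, t+5], ends trimmed) — the
alignment convention (centered vs trailing) is immaterial for the
statistic since both series shift identically; centered is used and the
properties tested are alignment-insensitive. The treatment adds ΔTA to
TA and factor-consistent DIC each month (an offline equilibrated
perturbation, not a gas-exchange simulation). Mitigation time =
mean(treated − unperturbed)/|slope| of the smoothed unperturbed series,
reported as positive "years rolled back" (declining trend, positive
offset). Both mean and slope are computed on smoothed series. A slope
below 10⁻⁶ units yr⁻¹ makes the statistic undefined (raised as an
error), except when the offset is exactly zero (untreated or inert
variable), which reports 0 years.

For calcification, the fitted response is applied to the TA−DIC series
month by month. Mitigation time is invariant under affine maps of the
variable, so every linear responder shares the TA−DIC mitigation time;
threshold responders entering their plateau mitigate in no more time
than TA−DIC. It is exactly proportional to ΔTA for TA−DIC but not for pH
or Ω (buffered, nonlinear chemistry) — both asserted in tests.

## Synthetic data

* **Experiments**: 6 TA−DIC levels (120–420 µmol kg⁻¹) × 3 replicates by
  default, matching typical OA perturbation designs; rates are the true
  model plus additive Gaussian noise with σ = 2 % of the mean rate (a
  lognormal option exists; published compilations give no error model,
  so additive Gaussian is the default). Chemistry is realized as
  (TA = 2300, DIC = TA − x) pairs checked against the solver.
* **Monthly series**: 1982–2022, TA−DIC trend −0.73 µmol kg⁻¹ yr⁻¹
  (the magnitude shown by observational surface-ocean reconstructions
  over these decades; it makes a ΔTA = 50 equilibrated treatment worth
  ~23 years), seasonal amplitude 8, monthly noise 2 µmol kg⁻¹, constant
  TA with the signal in DIC.
* **Grids**: cell-centered lat-lon with a warm-equator/cold-pole
  temperature profile, salinity and TA−DIC falling toward the poles,
  cos-latitude weights, boolean coastal columns and |lat| ≥ 60° polar
  mask.

All generators are pure functions of their spec including the seed.

What the synthetic data does *not* emulate: spatial covariance of real
reconstructions, autocorrelated monthly noise, species-specific
experimental designs, or real coastline geometry. Tests passing on
synthetic data therefore demonstrate correctness of the statistical and
chemical machinery under known ground truth, not skill on any real
reconstruction; mitigation times on real data depend on the actual
regional trend slope and will differ from the synthetic values.

## Problem sizes and determinism

The validation suite uses a 1000-point hypercube for solver
equivalence, 2000 replicates for interval coverage, and 500 for
parameter recovery — sizes chosen so every check is exact enough to be
meaningful while the whole suite stays interactive. Everything
stochastic is seeded; reruns are bit-identical.

## Known limitations

* No pressure/depth dependence, CO₂ isotopes, or Revelle-factor
  diagnostics; surface ocean only.
* The threshold parameterization is one of several consistent with a
  plateau-and-drop description; fitted plateau positions are robust but
  the decay constant k is design-sensitive at small n.
* Scenario algebra treats η as constant per region; species-level η
  variation and the time dependence of CDR efficiency are not modeled.
* Only NaOH and Na₂CO₃ are supported; no dosing logistics, dilution or
  plume transport.
* Rate units are never converted between species; cross-species
  aggregates are therefore unitless summaries (percent declines,
  doses), never pooled rates.
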