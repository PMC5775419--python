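# Methods

## Actuator model

The actuator is a sealed cavity of PF-5060 (perfluorohexane; boiling
56 °C, density 1.68 g/ml, specific heat 1.05 J/(g·K)) under a resistive
heater. Its thermal behaviour is reduced to a single-lump RC circuit:
heater power `Q = V²/R` flows into the fluid heat capacity
`C1 = v·d·c` and leaks to the surroundings through two parallel paths —
free convection from the membrane to still air, `R21 = 1/(h·A)` with
`h = 20 W/(m²K)` and `A = 5.31×10⁻⁴ m²` (94.2 K/W), and conduction
through the 9 mm PMMA cavity wall, `R22 = L/(k·A)` with
`k = 0.2 W/(m·K)` (84.75 K/W). The fluid temperature then follows the
first-order step response

    T(t) = T_surr + Q·R2·(1 − exp(−t/(R2·C1))),   R2 = R21·R22/(R21+R22),

which the package inverts in closed form for the time to reach any
reachable temperature. Assumptions: the fluid is one isothermal lump, the
heater couples to it through a resistance that does not appear in the
solved response (it is stored for completeness only), ambient is constant,
and phase change is not modelled — the design question is only *when*
boiling is reached, not what happens after.

Vapor pressure uses the Clausius–Clapeyron integral form with constant
ΔH_vap. The packaged PF-5060 preset sets the boiling-point vapor pressure
to one atmosphere (true by definition at the standard boiling point) but
deliberately leaves ΔH_vap unset, because no reliable value ships with the
device documentation; `vapor_pressure` raises until the user supplies one.

### Volume selection

A candidate fluid volume is feasible when (a) its time-to-boiling meets
the design deadline (larger volumes mean larger C1, hence slower heating)
and (b) it can supply the swept volume of the membrane stroke, taken as a
cylinder π·(d/2)²·stroke over the 13 mm membrane — 0.398 ml for a 3 mm
stroke. The selector returns the smallest feasible candidate. The worked
default deadline is 16 s: with the documented parameters the 0.4 ml design
point reaches 56 °C in 15.36 s, so a 15 s deadline would (just) exclude
it; the 16 s budget reflects that the nominal design is quoted to the
nearest few seconds.

Three heater-resistance presets (20, 23, 50 Ω) are carried because the
device is documented with all three in different operating contexts;
`design_20ohm` is the default since it reproduces the nominal 1.8 W drive
at 6 V. Note the documented parameter list also quotes C1 = 1.4 J/K, which
is inconsistent with v·d·c = 0.7056 J/K at 0.4 ml; the package always
computes C1 from the product.

`battery_life` divides capacity by the mean current of the duty-cycled
drive at constant supply voltage. It ignores voltage sag, DC conversion
losses and capacity derating, so it is an upper-bound estimate (3.6 h for
the 2 min cycle on 240 mAh at 6 V, 5.4 h for a 3 min cycle).

## Synthetic traces

`simulate_trace` emulates one measurement cycle per 120 s period:

* approach (0–15 s): residual humidity from the previous cycle relaxes
  exponentially toward the ambient baseline;
* contact (15–30 s): the sealed chamber accumulates humidity; capacitance
  rises linearly at `wind_factor · sensitivity · sweat_rate` pF/s from the
  level at sealing, clipped at the saturation capacitance;
* release (30–120 s): exponential relaxation toward baseline with time
  constant `recovery_tau`.

i.i.d. Gaussian noise (default sd 0.05 pF) is added per sample at 8 Hz.
Defaults and their reasons:

| parameter | default | why |
|---|---|---|
| sensitivity | 0.0050 (pF/s)/(g/m²h) | the wind-experiment regime of the device; configurable because the device's own sensitivity is quoted inconsistently (0.039 vs 0.0039) across contexts |
| humidity sensitivity | 0.6 pF/%RH | documented sensor constant |
| baseline | 0.6 × 50 %RH = 30 pF | 50 %RH ambient operating condition |
| saturation | baseline + 0.6 × 50 = 60 pF | the 100 %RH ceiling of a sealed chamber |
| temp. coefficient | 0.16 pF/°C | documented sensor constant |
| chamber warm-up | 3.4 °C (23.4 → 26.8 °C) | documented per-cycle heating |
| noise sd | 0.05 pF | small relative to the detection-window signal at physiological sweat rates; the device documentation states no noise figure |
| recovery_tau | 42.2 s | 80/ln(1/0.15): the actuator recovers 85% of its travel in 80 s, repurposed as the ventilation analogue — an assumption, surfaced in config |

The chamber temperature ramps during the approach phase, holds during
contact, and decays after release. This makes the thermal contribution a
*constant offset* inside the detection window, mirroring the physical
claim that heater-induced warming shifts the capacitance level but not the
rising rate. A temperature ramp continuing into the detection window
would instead bias the slope by `0.16 × (3.4/30) ≈ 0.018 pF/s`; the
within-cycle temperature waveform is not documented, so the offset-only
model was chosen to match the stated behaviour.

What the generator does **not** emulate: humidity transport physics in the
chamber (the linear rise is imposed, not derived), skin physiology,
wind-field effects beyond a per-bin sensitivity multiplier, sensor
hysteresis, and day-scale drift. Passing recovery tests therefore show
that the *pipeline arithmetic* is faithful and unbiased under the stated
noise model — not that a physical sensor meets these numbers.

## Study generator

Subject-level mean sweat rates per thermal status are drawn log-normally
around the design means (defaults 13.40, 26.04, 50.95, 109.57 g/m²h for
statuses 0…+3) with a between-subject CV of 0.323, the mean inter-subject
CV of the reference study; readings then scatter log-normally around the
subject mean with a within-subject CV of 0.10 (the documentation gives no
within-subject figure; 10% keeps replicate spread visibly smaller than
between-subject spread, as in the study's per-subject plots). Log-normal
was chosen because sweat rates are positive; the moments are parametrized
so the arithmetic mean and CV are exactly the design values, making the
generator mean-unbiased for recovery tests. The distribution family is
otherwise an assumption.

## Signal pipeline

Segmentation is purely schedule-driven (the cycle timing is always known
from the heater drive): cycle k contributes the samples in
`[k·120 + 17, k·120 + 30)` s, i.e. 104 samples at 8 Hz. A partial trailing
cycle is dropped; windows retaining under 50% of their expected samples
are rejected (threshold configurable). The rising rate is an unweighted
OLS slope with time re-zeroed to the window start — the simplest estimator
consistent with "slope", and invariant to offsets and time shifts. A
constant-capacitance window is reported as slope 0 with R² 0 and a
`degenerate` flag rather than an error.

Saturation (the chamber hitting 100 %RH mid-window at very high sweat
rates) is flagged by a two-half slope-ratio rule: saturated when the
second-half OLS slope is below 0.1 × a positive first-half slope. The
phenomenon is documented but no detector is, so this rule is a
reconstruction; the threshold is a parameter.

## Calibration metrics

Sensitivity is the OLS slope of rising rate on reference sweat rate.
The other metrics are reconstructions of conventions the device's quoted
figures are consistent with, and all are configurable:

* **linearity** = 100·R² — the only bounded, scale-free convention
  consistent with a "linearity of 97.9%";
* **uncertainty** = residual standard error of the rising rate divided by
  |slope|, expressed in g/m²h;
* **LOD** = 2.12 × uncertainty — the multiplier recovered from the quoted
  uncertainty/LOD pair (27.6/13.01 ≈ 2.12).

Wind robustness reports `100·(max−min)/min` over per-bin sensitivities
(the minimum-denominator convention reproduces the quoted 8.2% from the
quoted triple 0.0049/0.0050/0.0053) and the maximum pairwise linearity
difference. The quoted linearity spread of 0.7% is *not* reproducible from
the quoted per-bin linearities (99.4/98.6/98.8 give 0.8 under any obvious
convention); the package reports the computed 0.8.

Rounding half-up to the quoted decimal places is applied only in
reporting (`round_half_up`), never inside computations. The
temperature-offset arithmetic follows the quoted chain: 0.16 pF/°C ×
3.4 °C = 0.544 → 0.5 pF at one decimal, then 0.5/0.6 = 0.83 → 0.8 %RH —
i.e. the %RH equivalent is computed from the *rounded* offset, which is
how the quoted pair is arithmetically consistent.

## Comfort statistics

Every standard deviation is the n−1 sample sd; this convention exactly
reproduces all quoted per-subject and pooled ± values from the quoted
difference lists (population sd does not). Adjacent differences are taken
between consecutive statuses actually present, signed later minus earlier.
Per-status summaries aggregate subject-level *means* of the ≥3 readings
(whether the reference protocol used mean or median is unstated; mean is
assumed), and the overall inter-subject CV is the unweighted average of
the per-status CVs, which reproduces the quoted 32.3%. One known
inconsistency in the source tables: the quoted CV list pairs 31.7% with
status +1 and 66.5% with +2, but sd/mean of the quoted moments gives 66.6%
for +1 and 31.7% for +2 — the set matches, the order does not; the package
reports the computed order. The nearest-mean classifier breaks ties toward
the lower status code.

Readings below a calibration LOD are included by value (not truncated);
the below-detection flag is propagated in reports.

## Problem sizes and numerics

Recovery studies use 200 seeded 12-point sweeps of one cycle each
(~960 samples per trace), enough for the slope estimator's sampling
distribution to be resolved (standard error of the mean sensitivity
≈ 0.02% of truth) while keeping the whole acceptance run in seconds.
The closed-form time-to-temperature is validated against Brent bisection
on the forward response (agreement 1e-6 s over 1000 random circuits) and
the step response against high-tolerance `solve_ivp` integration of the
governing ODE (1e-3 °C over ten time constants). All randomness flows
from a single seed through named `SeedSequence` substreams, so every
stage is independently reproducible.

## Known limitations

* The actuator model stops at "boiling reached"; membrane mechanics,
  two-phase dynamics and chamber position are out of scope.
* The trace generator's linear-rise/exponential-recovery shape is imposed;
  it validates the estimator chain, not chamber physics.
* The calibration metric conventions (linearity, uncertainty, LOD
  multiplier) are reconstructions and cannot be confirmed from the
  available tables.
* `battery_life` is an idealized upper bound.
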