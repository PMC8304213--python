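# Methods

## Disposition model

Each drug follows a linear mammillary two-compartment model: a central
(plasma) compartment with volume Vd1 (mL) exchanging drug with a tissue
compartment (Vd2) by first-order transfer (k12, k21, min⁻¹), and
first-order elimination from plasma with k10 = CL/Vd1. Units are fixed
internally to mg, mL, min; concentrations are reported in µg·mL⁻¹
(mg/mL × 1000), the scale of the published tables. The hybrid rate
constants λ1 ≥ λ2 are the roots of s² − (k10+k12+k21)s + k10·k21 = 0; λ2
is computed as (k10·k21)/λ1 to avoid cancellation when the roots are far
apart, and λ1 = λ2 (to 1e-12 relative) switches the analytic solution to
its t·e^(−λt) degenerate form.

Intravenous input is either a bolus — an instantaneous jump of the
central amount at the administration time, so the post-dose
concentration Dose/Vd1 appears at t = 0⁺ — or a constant-rate infusion.
Repeated administrations are part of the forcing function and are
integrated directly; nothing restricts a regimen to a single dose.

**Integration.** The fixed-step integrator (Euler or classical RK4,
default RK4 with h = 0.02 min) mirrors the accumulator-and-flow
construction of graphical system-dynamics tools. The infusion rate is
held constant over each step (dose boundaries should lie on the grid, as
they do for all shipped regimens), which keeps the right-hand side
smooth within steps; RK4 then tracks the analytic biexponential solution
to ~2×10⁻⁹ relative at h = 0.02. Euler at the same step is first-order:
its error is ~2×10⁻⁴ of Cmax, but grows to ~0.8% *pointwise relative* on
the decayed tail of a 400-min run — a bound of 10⁻³ only holds on the
Cmax scale, which is how the test asserts it. Mass balance
(plasma + tissue + eliminated − administered) holds to ~10⁻¹³ relative
because the three flow derivatives sum to the input rate identically at
every RK4 stage.

**AUC.** The running plasma AUC uses the rectangle accumulator
AUC(t) = AUC(t−dt) + C(t−dt)·dt, exactly the accumulator-compartment
rule of the simulation environment being emulated; a trapezoidal variant
is available because most literature AUCs are trapezoidal. For an
infusion the two rules agree to ≪0.1%; for a bolus the rectangle rule
overstates the total by ≈ h·C0/2 (0.09% for the 5-FU case at h = 0.02).
Total AUC to elimination is validated against the closed form Dose/CL.
"To elimination" means 25 terminal half-lives past the last input;
`elimination_grid` coarsens the step (doubling from 0.02 min) when that
horizon would exceed 2×10⁵ nodes — relevant only for itraconazole
(terminal t½ ≈ 9.3 h), where RK4 at the coarsened step is still accurate
to ~10⁻¹⁰.

## Effect model

% cell-growth inhibition is the four-parameter Hill (4PL) response to
the *tissue* concentration. The literal expression contains
(c/EC50)^(−n), singular at c = 0; the analytic limit (Bottom) is
returned there, and the harmless overflow/underflow of the power for
c ≪ EC50 / c ≫ EC50 saturates to Bottom/Top. Effects are deliberately
not clamped to [0, 100]: fitted Bottoms can be negative (net growth
stimulation at sub-threshold exposure) and clamping would bias
AUC_effect; trajectories carry a flag for negative-effect intervals
instead. AUC_effect accumulates with the same rectangle rule as the
plasma AUC, so a constant effect integrates exactly to effect × duration.

The eight shipped dose-response parameter sets (two drugs × itraconazole
co-incubation at 0/2/4/6 µM) come from 4PL fits of A549 MTT assays. For
combination scenarios, Top, steepness and EC50 are arithmetic means over
the co-incubation rows with two published exclusions (the gemcitabine
2-µM Bottom and the gemcitabine 0-µM steepness, the latter fitted with a
standard error of 4.2×10⁵ — including it would shift the mean from 4.67
to 9.29). Bottom is never averaged: it becomes the quadratic
Bottom(x) = a·x² + b·x + c in the itraconazole tissue concentration x
(µg·mL⁻¹), obtained by exact interpolation through the Bottoms fitted at
0, 4 and 6 µM (converted to mass units with MW 705.64 g·mol⁻¹). The
calibration spans 0–4.23 µg·mL⁻¹; evaluation outside warns but proceeds.
Both published coefficient sets are reproduced to two decimals by this
interpolation. Note the quadratic decreases until x ≈ 0.4 µg·mL⁻¹: at the
tissue exposures produced by 100-mg single doses (≤0.5 µg·mL⁻¹) more
itraconazole slightly *lowers* the post-collapse floor, and only higher
doses or sustained dosing reach the rising branch.

**Effect collapse.** While tissue concentration is high the Hill divisor
term f(c) = (c/EC50)^(−n) is negligible and the effect sits at Top; once
c falls through a threshold, f grows exponentially and the effect drops
to Bottom. The drop-onset is defined as the first post-peak crossing of
the threshold (the rising phase of an infusion also sits below it but is
not a collapse). With the shipped parameters the gemcitabine crossing of
0.008 µg·mL⁻¹ lands at minute 248, within 5% of the published reading
(minute 260). The 5-FU crossing of 0.5 µg·mL⁻¹ lands at minute 91.9,
about 31% after the published minute 70: the tissue-amount solution
A2(t) = D·k12·(e^(−λ2·t) − e^(−λ1·t))/(λ1−λ2) with the published
constants puts the tissue concentration at ~1.7 µg·mL⁻¹ at minute 70 and
does not reach 0.5 until minute 92, while the *visible* inflection of
the effect curve (≈1% below plateau) does occur near minute 70. The
published onset appears to be read from the curve, not from the stated
threshold; the threshold-crossing test is kept faithful to the stated
definition and is expected to disagree for 5-FU.

## Combination scenarios and multiple dosing

The two PK systems never exchange mass (the drug pairs share neither
metabolic pathways nor transporters, so interaction-free linear kinetics
are assumed); the only coupling is Bottom(x(t)). With itraconazole dose
zero the coupled model reproduces the single-drug effect trajectory
bit-for-bit. Scenario comparison reports AUC_effect and percent change
versus a named control, with the integration window an explicit
parameter — AUC_effect ratios are strongly window-sensitive because the
post-collapse tail contributes bottom-level area proportional to the
window length. For this reason the published relative gains of the
fixed-curve scenarios are reported by `analysis/03` but not asserted;
the robust qualitative finding — AUC_effect(6 µM) > AUC_effect(4 µM) >
control > AUC_effect(2 µM) for both drugs — is asserted.

Repeated itraconazole dosing (e.g. 100 mg q24h) is supported three ways,
which agree where applicable: direct ODE integration of the repeated
regimen; superposition of time-shifted analytic single-dose solutions
(exact for a linear system; matches the ODE route to ~10⁻¹² of Cmax);
and a steady-state approximation that pins plasma at Css and integrates
dA2/dt = k12·(Css·Vd1/1000) − k21·A2, relaxing tissue toward
(k12·Vd1)/(k21·Vd2)·Css. The Css value is a free input (no published
value exists for the original workaround).

## Estimation

Two-compartment fits minimize unweighted least squares between the
analytic solution and the concentration samples, with parameters on the
log scale to enforce positivity, multi-start (a data-driven start —
clearance from the trapezoidal AUC, k10 from the terminal slope — plus
lognormal perturbations; a user-supplied start is always backed by the
data-driven one to escape shallow local minima). Vd2 cancels out of the
plasma solution and is therefore not estimable from plasma data; it is
reported through the standard definition Vd2 = Vd1·k12/k21, which
matches the published tissue volumes to 0.08–0.5% (the residual being
rounding of the printed rate constants). CV% comes from the asymptotic
covariance at the optimum, σ²(JᵀJ)⁻¹ with σ² = RSS/(n−p); on the log
scale the standard error is already the relative error, and Vd2's CV is
propagated by the delta method. An optional 1/ŷ² ("relative") weighting
is exposed: besides matching constant-CV assay noise, it guards bolus
designs without sub-minute samples, where the unweighted global optimum
can be a spiked profile with an unobservably small central volume (one
synthetic noise realization of the 5-FU design does exactly this; the
weighted fit recovers CL and Vd1 to a few percent on every seed tested).

Hill fits estimate Bottom/Top on the natural scale and EC50/steepness on
the log scale, reject flat (zero-variance) responses and designs with
fewer than four distinct concentrations. The Bottom quadratic uses exact
interpolation for three points and least squares beyond; duplicate
abscissae are rejected.

## Synthetic data

No raw concentration-time or plate data are deposited with the source
study, so the generators emulate their statistical shape: plasma samples
are the analytic solution under multiplicative lognormal noise (default,
PK assays have roughly constant CV; σ = 0.05 in the recovery studies,
i.e. 5% CV, at 14 literature-style sampling times over 0–210 min for the
gemcitabine design), and dose-response replicates are Hill values plus
additive Gaussian noise (σ = 3 percentage points, 3 replicates × 8
log-spaced concentrations, matching "at least three independent
experiments"). Generation is deterministic under a fixed seed. What the
generators do *not* emulate: between-subject PK variability, sampling
below the quantification limit, plate-position or day effects, and any
real-data model misspecification — so passing recovery tests demonstrate
correctness of the fitting machinery under the assumed model, not
robustness to real-world violations of it.

## Problem sizes and numerical defaults

Default grids follow the source analyses: RK4, h = 0.02 min, 400 min for
gemcitabine scenarios and 200 min for 5-FU (2×10⁴ and 10⁴ steps).
AUC-to-elimination runs extend to 25 terminal half-lives (≈440, 310 and
14,000 min; the itraconazole run coarsens to h = 0.08 min, 1.75×10⁵
steps). Multiple-dosing comparisons use h = 0.1 min over 4,400 min.
Optimizer tolerances are xtol = ftol = gtol = 10⁻¹⁵ with at most 4,000
function evaluations per start.

## Known limitations

- The tumor tissue is assumed to behave like the pooled tissue
  compartment; no tumor-specific vascularization or permeability.
- No drug-drug PK interaction, protein-binding correction, oral
  absorption or physiologically based structure.
- The Bottom quadratic is an empirical interpolation over 0–4.23 µg·mL⁻¹;
  its rising branch beyond the calibration range drives the
  high-exposure predictions and is an extrapolation (flagged at runtime).
- AUC_effect comparisons depend on the integration window; percent-gain
  figures are only meaningful with the window stated.
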