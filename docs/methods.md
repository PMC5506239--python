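# Methods

## Survival model

Whole-cell clonogenic survival is modelled as a multi-target process over
`n_units` genome copies (default 4, the *D. radiodurans* genome copy number;
configurable because the exponent is a structural assumption, not a fitted
quantity):

    S(D)     = exp(−α·D·exp(−β·exp(−δ·D)))          single genome unit
    S_cfu(D) = 1 − (1 − S(D))^n                     colony formation

Parameters and units: α (kGy⁻¹, DSB induction; must be > 0), β
(dimensionless repair capacity; ≥ 0), δ (kGy⁻¹, repair-protein inactivation;
≥ 0). The exponent α·D·exp(−β·e^{−δD}) is strictly increasing in dose for
α > 0, so S_cfu is strictly decreasing and iso-effect doses are unique.
Numerics: S_cfu uses `expm1` so that values near 1 (the shoulder) keep full
relative precision; for extreme parameters the curve saturates at exactly 1.0
or underflows to 0.0 in double precision, and the property tests restrict
strict-monotonicity assertions to the representable band.

Two high-dose approximations are exposed: the first-order expansion
exp(−αD·[1 − β·e^{−δD}]) and the asymptote exp(−αD). Their error decays like
α·β²·D·e^{−2δD}, so both are excellent once δ·D ≳ 3.

`dose_at_survival` inverts S_cfu by Brent's method on [0, 100 kGy]
(absolute tolerance 10⁻⁶ kGy); monotonicity guarantees the bracket. On the
flat shoulder the inverse is ill-conditioned in dose even though it is exact
in survival — round-trip tests therefore compare in survival space there.

The sensitization enhancement ratio is defined on the CFU-level curve
(50% *CFU* reduction), not the single-unit curve. Amplification at a fixed
dose is the relative survival reduction (S_ref − S_test)/S_ref; negative
values (protection) are reported, not rejected.

## Staged fitting

Stage 1 estimates α from the exponential tail: records at doses in the upper
half of the observed range with survival < 0.9 (override with a numeric
threshold) are converted to single-unit survival via the exact inverse
1 − (1 − S_cfu)^{1/n}, and a through-origin regression of −ln S on dose gives
α̂ = Σ D·(−ln S) / Σ D². Stage 2 fits (β, δ) by nonlinear least squares with
α fixed (`paper_staged` mode). The default `staged_refine` mode adds a joint
refinement of (α, β, δ) initialised at the staged solution, because the tail
of a 0–8 kGy experiment is not fully asymptotic — the correction factor
exp(−β·e^{−δD}) is still 0.85–0.89 at 8 kGy for typical parameters, biasing
the stage-1 slope low by ~15–18% — and only the joint fit is self-consistent
on noiseless data (recovery to better than 10⁻³ relative, verified in the
tests).

Loss is least squares on ln(survival) by default (variance-stabilising for
exponential decay; linear scale available). Zero-dose records anchor
normalization but are excluded from the log-scale loss (ln 1 ≡ 0 carries no
information). Survival ratios up to 1.1 are clipped to 1 with a warning
(replicate noise routinely pushes shoulder ratios past 1); larger values are
rejected as data errors. Optional inverse-variance weights use replicate SDs.
Bounds α ∈ (0, 10], β ∈ [0, 50], δ ∈ [0, 10] kGy⁻¹ are physically generous;
a solution resting on a bound is flagged in the result, never silently
accepted. Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·s², and the adjusted R² is computed on the loss scale.

### Identifiability under noise

On noisy triplicate data (β, δ) sit on a shallow likelihood ridge: over
0–8 kGy the data mainly constrain the combination β·e^{−δD} through the
shoulder position, so individually β and δ wander (and occasionally pin at
bounds) while the *fitted curve* remains close to the truth. This is
information-theoretic, not an optimizer defect — for such datasets the
least-squares optimum has a lower residual sum than the generating
parameters. Consequently parameter-space recovery claims are only reliable
for α (tail-identified); the package's stochastic tests assert
function-space closeness of the fitted curve plus median stability of α.
With noiseless or very-low-noise data all three parameters are recovered
exactly. Users needing stable β on noisy data should hold it fixed at a
prior value (`paper_staged` with a literature β, or narrow bounds).

## Dosimetry arithmetic

Per-particle mass = atoms × atomic mass / N_A, with CODATA
N_A = 6.02214076×10²³ mol⁻¹ and IUPAC Pt mass 195.084 g mol⁻¹ (both
overridable). Exposure concentration (mg/L) = particles-per-cell × cell
density × particle mass; the inverse conversion is exact, and round-trip
identity is property-tested. Uptake reports convert an ICP-MS total metal
mass into particle counts, per-cell mass (pg) and the per-cell volume
fraction; headline values are rounded to 2 significant figures (1 for the
volume fraction) for presentation while full precision is retained on the
report object. Note the commonly quoted per-particle mass 3.25×10⁻¹³ µg for
a 1000-atom Pt particle is a rounding of the exact 3.2394×10⁻¹³ µg; the
~0.3% difference propagates into concentration conversions, which is why the
MIC conversion is quoted to within 2%.

## Toxicity and growth

CFU ratios are normalized per incubation time to the concentration-0 control
mean, with first-order error propagation of replicate SDs. The MIC is
operationalised as the lowest tested concentration whose mean ratio drops
below 1 − threshold (threshold 0.20 by convention) at any incubation time;
an optional significance gate additionally requires a Tukey-adjusted
difference from the same-time control, because a mean drop and a significant
drop are distinct claims and both behaviours are useful.

Doubling time is 1/slope of a least-squares fit of log₂(OD600) vs time over
the exponential window. The automatic window is the longest run of
consecutive points whose local log-slopes are positive and within 20% of the
run's median — a rule that excludes lag and plateau without user input; a
flat curve raises a no-growth error rather than returning a number.

The toxicity grid is analysed as a two-factor fixed-effects ANOVA
(concentration × incubation time) with interaction, type-II sums of squares
for unbalanced cells, via statsmodels; Tukey HSD (studentized range,
Tukey–Kramer for unequal group sizes) compares concentration levels within
each time. Significance flags mirror the *p < 0.05 / **p < 0.01 convention.

## Synthetic data

The clonogenic generator draws, per plate, a Poisson count around
cells_plated × plating_efficiency × S_cfu(dose), multiplied by a unit-mean
lognormal plate factor. Defaults: doses 0–8 kGy in 0.5 kGy steps (denser
than a typical experiment so the 2.7–3.5 kGy shoulder is resolvable by the
fitter), 250 cells per plate at plating efficiency 0.8 (≈200 control
colonies, the upper end of the countable range), triplicates, 10%
plate-factor CV — counting statistics plus plating-efficiency variation are
the dominant noise sources of a real CFU assay. Survival is normalized to
the same-replicate dose-0 plate (pooled normalization available), matching
how independent experiments are normalized in practice. The generator does
*not* emulate day-to-day batch effects shared across doses (which cancel in
per-replicate normalization), serial-dilution pipetting error, or colony
miscounting; passing tests therefore demonstrate estimator behaviour under
idealised counting noise, not under every real-world artefact.

Growth curves are logistic after a lag with multiplicative lognormal noise;
presets use doubling times of 144 min (unloaded) and 455 min (heavily
loaded). The toxicity generator reproduces the reference means of 42% (±8%)
survival after 3 h and 18% (±3%) after 12 h at the 3×10⁶ particles-per-cell
level. All generators take a mandatory seed and are bit-reproducible.

## Pipeline and interface

The CLI is a thin layer over the library. CSV schemas:
`dose_kGy,survival[,sd,n]` for survival data,
`concentration,time_h,replicate,cfu_count` for toxicity,
`time_min,od600` for growth. Structured results are JSON with a
`schema_version` field; every stochastic output embeds its seed, and an
identical configuration reproduces the results file byte for byte (the
output directory is excluded from the provenance hash for that reason).

## Problem sizes

The test suite fits noiseless 17-point curves (seconds), 200 seeded
triplicate assays for the stochastic-recovery batch (~1 minute), and
hand-sized ANOVA designs; the acceptance script runs only deterministic
desk-scale computations.

## Known limitations

- β is weakly identified on realistic noisy data (see above); report it with
  its SE, or fix it.
- No dose-rate dependence: the model describes a fixed dose-rate protocol.
- Uncertainty is not propagated through the dosimetry conversions (ICP-MS
  calibration error, adsorbed-vs-internalized partitioning are out of scope).
- The MIC is a grid value: it is the lowest *tested* concentration
  qualifying, not an interpolated threshold.
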