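# Methods

## Model and procedure

Baseline `x` and follow-up `y` are paired measurements of the same
quantity on `n` subjects; percentage change is the fraction
`(x − y)/x` (positive = reduction). The correlation
`r_obs = corr(x, (x − y)/x)` cannot be tested against zero, because the
two variables share the component `x`. The package derives the correct
reference value from the first-order (Pearson) approximation to the
correlation of ratio variables,

    r(x/z, y/w) = (r_xy V_x V_y − r_xw V_x V_w − r_yz V_y V_z + r_zw V_z V_w)
                  / [√(V_x² + V_z² − 2 r_xz V_x V_z) · √(V_y² + V_w² − 2 r_yw V_y V_w)],

with `V = s/m` the coefficient of variation. Every special case in
`ratio_null` (corr of `x` with `−y/x`, the `k`-parameterised surface,
Chayes' zero-correlation null, the appropriate null) is evaluated through
this one formula, so there is a single source of truth for the algebra.

Writing `k = V_x/V_y`, "no relation between percentage change and
baseline" is the statement that treatment leaves the CV unchanged,
`k = 1`. Substituting `k = 1` gives the appropriate null

    ρ₀ = √((1 − r_xy)/2),

a strictly decreasing function of the pre/post correlation with range
(0, 1). The hypothesis `r_obs = ρ₀` is tested with Fisher's z:
`z = (arctanh r_obs − arctanh ρ₀)√(n − 3)`, two-sided standard-normal
p-value. `ρ₀` is computed from the *sample* `r_xy`; a `rho0_override`
exists for sensitivity analysis against a population value.

Assumptions inherited from the approximation: no expected mean near zero,
CVs small (warnings at CV ≥ 0.5, hard error at ≥ 1 where the underlying
series diverges), and `|r_xy| < 1`. At `r_xy = 1` the null is singular;
exact proportionality (`y = c·x`) is reported as "no relation by
construction" rather than tested. The `k`-surface singularities at
`r_xy = 1` (undefined at `k = 1`, ±1 for `k ≶ 1`, detected at
tolerance 10⁻¹²) are explicit signals, not NaNs.

## Parameters that matter

- `alpha` (default 0.05): two-sided level; one-sided testing is not
  exposed as a default anywhere.
- Sample SDs use the `n − 1` denominator (this is what reproduces the
  printed toy SD 15.14; the `n` denominator gives 14.36).
- Percentage change is held as a fraction internally; reports render it
  as needed. Correlations are invariant to the ×100 rescaling.
- CVs are refused when `|mean| < 10⁻¹² · SD` — the approximation's
  "means away from zero" condition surfaces as an explicit error.
- Fisher machinery requires `n ≥ 4` (`SE = 1/√(n−3)`), and `|r|` within
  10⁻¹² of 1 is treated as degeneracy rather than fed to `arctanh`.

## Synthetic data

The generator draws bivariate-normal pairs with configurable mean/SD of
baseline, population CV ratio `target_k`, and population correlation
`target_r_xy`; follow-up mean is 0.8 × baseline mean (a 20% average
reduction, matching the built-in toys; immaterial, since every statistic
used is scale-free). The empirical-null simulator enforces `k = 1` by
scaling both follow-up moments by a common factor `c = 0.8`
(scale-invariance is asserted by test). Defaults are mean 100, SD 10
(CV 0.1): at this CV the simulated null depends essentially only on
`r_xy` and `n`, which is what makes the periodontal-style configuration
reproducible without the study's unpublished means.

What the generator does *not* emulate: skewed or truncated follow-up
distributions (a treatment that genuinely acts multiplicatively produces
non-normal `y`), heteroscedastic measurement error, missing data, and
non-positive measurements beyond the improbable tail of the normal
(draws with non-positive baselines are retained but counted in
`proportion_invalid`). Passing tests therefore demonstrate correctness
under the bivariate-normal model, not robustness to those features.

## Empirical null and Monte-Carlo p

Each of `reps` (default 100,000) replicates draws `n` fresh pairs and
records `corr(x, (x − y)/x)`; drawing fresh pairs per replicate is
equivalent to subsampling one large pool. Centiles use linear (type-7)
interpolation — the difference from other conventions is far below the
Monte-Carlo error at these replicate counts. The two-sided Monte-Carlo
p-value is `2·min(tail proportions)` with the +1 continuity convention
(`p ≥ 1/(reps+1)`). At CV ≤ 0.1 the simulated median agrees with the
closed form within ~0.01; as the CV grows the normal model generates
non-positive baselines and the median drifts away from the closed form —
a monotone divergence asserted by test (this is the mechanism behind the
CD4-style discrepancy, whose exact moments are unpublished and therefore
covered qualitatively only).

## Measurement-error study

Latent `X ~ N(100, 10²)`; follow-up `Y = 0.8X` under the null or
`Y = 0.8X − cX²`, `c ∈ {0.001, 0.002, 0.003}`, under genuine relations;
observed `x = X + e_X`, `y = Y + e_Y` with independent mean-zero normal
errors of equal SD ∈ {1..5}; `n ∈ {20, 50, 100, 200, 500}`; both the
proposed test and the zero-null ("usual") test — implemented as Fisher z
against 0, recorded in the output metadata — at `alpha = 0.05`;
10,000 replicates per cell by default (MC SE ≤ 0.5 percentage points near
5%), one spawned substream per cell so cells are independently
reproducible. Added error inflates the observed baseline CV more than
it can be compensated in the follow-up: at error SD 5 the observed CVs
are `√125/100` and `√89/80`, so the induced `k ≈ 0.95 ≠ 1` — the
analytic source of the type-I inflation, asserted against empirical
moments by test. Latent or observed negatives are not truncated
(`P(x ≤ 0) ≈ 0` at these moments); replicates where a correlation is
degenerate (e.g. zero error under exact proportionality) are tallied as
"undefined", never as rejections.

## Calibration of the proposed test

Because `ρ₀` is derived from the sample `r_xy`, which co-varies with
`r_obs`, the test is *conservative* at moderate pre/post correlation
(measured type-I ≈ 1.6% at `r_xy = 0.207`, `n = 100`) and approaches the
nominal 5% as `r_xy → 1` — precisely the regime of error-free repeated
measurements, where the measurement-error study starts (≈ 5.5% at error
SD 1, `n = 20`). The suite asserts never-anti-conservative behaviour
across `r_xy` and nominal calibration at high `r_xy`, rather than exact
`α`-calibration everywhere.

## Numerical choices

- Floating-point overshoots of the closed forms beyond ±1 by ≤ 10⁻⁹ are
  snapped to ±1; genuinely out-of-range approximation values are returned
  as-is with a warning, never silently clamped.
- A percentage-change vector whose SD is ≤ 10⁻⁹ of its mean magnitude is
  treated as constant (degenerate), so float rounding of `y = 0.8x` does
  not manufacture a correlation out of noise.
- Replicate sizes in the shipped tests are scaled to keep the suite quick
  (2,000–20,000 replicates for property checks; the full 100,000-replicate
  null simulation and 10,000-replicate study cells run in the acceptance
  checks); Monte-Carlo tolerances are set at ≥ 3 binomial SEs of the
  chosen sizes.

## Known limitations

- The null derivation is first-order in the CVs: above CV ≈ 0.2 the
  closed form and the truth diverge visibly (the package warns at 0.5).
- No measurement-error correction is provided — the study quantifies the
  damage but the test itself assumes error-free measurements.
- Complete-case handling only for file input; no missing-data model.
- The conventional test is deliberately included for comparison despite
  being the practice the package exists to replace.
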