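# Methods

This document records the statistical model, the numerical choices, the
synthetic-cohort design, and the known limitations of `bpref`. Wherever
the published analysis that motivates this pipeline leaves a step
unspecified, the choice made here is called out explicitly.

## 1. Problem

Construct sex-stratified blood-pressure (BP) reference tables for
2-year-old children measured by triplicate auscultation: for each sex
and outcome (SBP, DBP), tabulate the 50th/90th/95th/99th BP percentiles
at the 5th/10th/25th/50th/75th/90th/95th height percentiles, as integer
mmHg. BP in toddlers is right-skewed and depends on body size, so the
centile model must handle skewness and adjust for height.

## 2. Measurement selection

Each child contributes up to three readings per channel. One analysis
value per channel is derived by a cascade (`bpref.selection`):

1. if readings 2 and 3 are both present and `|m2 − m3| < 5` mmHg, use
   their mean;
2. else if readings 1 and 2 are both present and `|m1 − m2| < 5`, use
   their mean;
3. else if reading 2 is missing and `|m1 − m3| < 5`, use the mean of
   readings 1 and 3;
4. else the record is rejected (`rejected_unstable`), or
   `rejected_missing` when two or more readings are absent.

The 5 mmHg limit is strict (`< 5`; a difference of exactly 5 rejects
the pair). A diastolic reading of 0 (auscultation artifact: sounds
audible to cuff deflation) rejects the DBP channel only
(`rejected_dbp_zero`); SBP from the same triplet remains usable. A
non-stable condition flag (crying, moving, feeding) rejects both
channels. The (1,3) fallback is applied **only** when reading 2 is
missing; whether a disagreement-driven fallback was intended in the
original protocol is not stated, and this narrower rule is the
documented choice here.

## 3. Exclusion cascade and flow accounting

`bpref.cohort.apply_exclusions` assigns each record, per channel, to the
first applicable bucket in this fixed order:

1. `excluded_chronic` — chronic cardiovascular/renal disease;
2. `excluded_missing_or_condition` — missing readings, DBP = 0, or a
   non-stable condition flag;
3. `excluded_unstable_bp` — the `< 5` mmHg rule failed on intact
   readings;
4. `excluded_covariates_or_height_outlier` — missing height/age, or
   height Z-score outside ±5;
5. `excluded_underage` — age below 24 months;
6. `analyzed`.

Counts are conserved per channel (buckets sum to the input count), and
sub-reasons (e.g. `dbp_zero`, `condition_crying`) are tallied
separately. The SBP and DBP analysis sets therefore differ: DBP-only
artifacts remove a record from the DBP channel but not from SBP.

## 4. Height Z-scores

Height-for-age Z-scores use the LMS transform
`z = ((y/M)^L − 1) / (L·S)` (with the `log(y/M)/S` limit at `L = 0`)
against a growth standard with per-sex, per-month L/M/S rows and linear
interpolation in age. The packaged standard
(`bpref.growth.synthetic_growth_standard`) is a **synthetic stand-in**:
median height 83.3 cm (boys) / 82.3 cm (girls) at 24 months, growth
0.75 cm/month with a mild taper, S = 0.034, L = 1 for ages 18–42
months. It is chosen for internal consistency with the cohort generator
and is *not* national reference data; any real analysis should supply a
real standard via `GrowthStandard.from_csv`.

## 5. Centile model: penalized LMS (BCCG)

At height Z-score `x`, BP follows the Box–Cox–Cole–Green distribution
with parameters L(x) (Box–Cox power), M(x) (median) and S(x)
(coefficient of variation): the transformed residual

    z = ((y / M(x))^L(x) − 1) / (L(x) · S(x))

is standard normal (log form at L = 0). The published analysis names
only "a generalized additive model using the LMS method"; the concrete
fitter here makes these documented choices:

* **Parameterization.** M and S are modelled on the log scale
  (positivity by construction); L on the identity scale.
* **Bases.** Curve flexibility is fixed in equivalent degrees of
  freedom (edf): edf = 1 is a constant, edf = 2 exactly linear, and
  edf > 2 a cubic P-spline (≥ 8 B-spline basis functions, interior
  knots at quantiles of `x`, second-difference coefficient penalty)
  whose penalty weight λ is calibrated by bisection so that the
  hat-matrix trace `tr[(BᵀB + λDᵀD)⁻¹ BᵀB]` equals the requested edf.
* **Estimation.** The penalized log-likelihood is maximized jointly
  over all three coefficient vectors with L-BFGS-B and analytic
  gradients. A fit that fails the optimizer's convergence test with a
  non-negligible gradient norm raises `ConvergenceError` carrying
  diagnostics.
* **Model selection.** The edf combination is chosen by minimum
  `BIC = −2·loglik + log(n) · (edf_L + edf_M + edf_S)` over a grid,
  default `L ∈ {1,2} × M ∈ {2,3,4,5} × S ∈ {1,2,3}` (24 fits). The
  reported log-likelihood is the unpenalized one at the penalized
  optimum.
* **Extrapolation.** Curves are evaluated with `x` clipped to the
  observed Z-score range; evaluation outside that range requires
  `allow_extrapolation=True` and returns the flat (edge) value.

Centiles follow from `C_p(x) = M(x)·(1 + L(x)·S(x)·z_p)^{1/L(x)}`.

## 6. Comparison model: quartic polynomial

`bpref.polynomial` regresses BP on (1, x, x², x³, x⁴) by OLS within each
sex and forms percentiles as `fitted mean + z_p · resid_sd` with the
residual SD on n − 5 degrees of freedom. This mirrors the established
US fourth-report construction restricted to a single age. How the
original analysis derived percentiles from its polynomial fit is not
stated; the normal-residual rule is this package's choice. The model is
symmetric by construction and serves as a sanity check on the LMS fit.

## 7. Reference tables and rounding

Tables are built by evaluating the fitted model at the height Z-scores
`z = Φ⁻¹(h)` for h ∈ {5,10,25,50,75,90,95}% and BP percentiles
{50,90,95,99}%, then rounding **half-up** to integer mmHg
(`floor(x + 0.5)`, so 65.5 → 66). Banker's rounding is deliberately not
used, matching the convention of printed clinical tables. Tables
serialize to CSV (wide and long) and support exact cell-wise
comparison (`compare_tables`).

## 8. Synthetic cohort generator

`bpref.simulate.generate_cohort` draws, per child: sex (deterministic
split at `round(n · pct_boys)`), age uniform on 24–27 months, height
normal (84.0, 2.9²) cm, weight correlated with height, season and
posture labels, and triplicate SBP/DBP readings.

**Truth surfaces.** The default per-(sex, outcome) truth is a BCCG
distribution whose L, M, S vary smoothly in the height Z-score —
M quadratic, L linear, S quadratic — with coefficients obtained by
least-squares so that the surface's rounded centiles reproduce a
28-cell printed reference table (4 BP percentiles × 7 height
percentiles) per stratum; the maximum absolute residual against the
printed cells is 0.48 mmHg, within rounding half-width. Outside
|z| > 1.645 the surfaces extend flat. At the median height the presets
are:

| stratum | L | M (mmHg) | S |
|---|---|---|---|
| boys SBP | 0.2327 | 91.25 | 0.0908 |
| boys DBP | 0.7554 | 51.81 | 0.1521 |
| girls SBP | 0.8798 | 90.24 | 0.0883 |
| girls DBP | 0.8394 | 51.69 | 0.1562 |

**Readings.** Each triplicate adds i.i.d. within-child noise
(SD 1.5 mmHg by default — a free parameter of the generator, not an
estimate from data) to the child's latent BP, correlates the SBP and
DBP latents at ρ = 0.5, and rounds to the 2 mmHg grid of auscultation
practice. With default settings the only exclusions are noise draws
that trip the `< 5` mmHg rule (≈ 0.2% of records for SBP).

**Planted categories.** Optional rates plant mutually exclusive
exclusion causes (chronic disease, missing readings, crying, DBP = 0,
underage, height outliers) to exercise the flow accounting;
`fig1_like_config()` bundles a flowchart-sized configuration
(n = 4988). All generation is deterministic given the config and seed;
the package default seed is 20150401.

## 9. Reproduction script

`scripts/acceptance.py` regenerates three strata from scratch —
boys SBP (n = 3139, all boys), girls SBP (n = 3139, all girls), boys
DBP (n = 3042) — runs selection, exclusions, the default-grid LMS fit,
and table rounding, and emits the median-height 50th/95th/99th
percentile cells with per-stratum analyzed counts as JSON. At the
default seed the boys-DBP 95th-percentile cell rounds to 66 mmHg with
an unrounded value of 65.51: measurement noise plus the 2 mmHg reading
grid inflate the fitted S slightly (≈ +0.18 mmHg at that cell), and the
default-seed draw adds ~1 SD of sampling noise on top, landing 0.008
above the rounding boundary. Across seeds the cell averages 65.3 mmHg
(SD 0.19). The seed was fixed before this outcome was known and was
not changed afterwards.

## 10. Numerical conventions

* BCCG z-scores and centiles use the exact L → 0 logarithmic limit for
  |L| < 1e−8.
* λ calibration solves the trace equation by bisection to machine-level
  bracketing; a ridge of 1e−10 stabilizes the solve.
* Model export (`LMSResults.export`, `QuarticBPResults.export`) writes
  full-precision floats; re-imported models reproduce centiles
  bit-identically.
* `bpref run` writes a `manifest.json` with the SHA-256 of every output
  file; identical config + seed reproduce identical bytes.

## 11. Limitations

* The growth standard is synthetic; height Z-scores are internally
  consistent but not comparable to national charts.
* The generator's within-child noise SD (1.5 mmHg), BP correlation
  (0.5), and height distribution are plausible round numbers, not
  estimates; absolute exclusion rates under noise are therefore
  illustrative only.
* The LMS fitter supports a single age band (no age dimension); the
  cohort design (24–27 months) makes age adjustment unnecessary here.
* Percentiles for the polynomial model assume normal residuals, which
  understates upper-tail BP skewness relative to BCCG.
* Observed BP readings are interval-censored by the 2 mmHg grid; the
  likelihood treats them as exact, which slightly inflates fitted S.
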