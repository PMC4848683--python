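# Methods

## Study design being modeled

Two rat strains (DR, dietary-obesity resistant; DS, sensitive) receive MNU
at 21 days of age; mammary tumors are detected by twice-weekly palpation
from day 24 post-carcinogen and the study terminates at 63 days (9 weeks),
when every tumor is excised and weighed. A tumor's *detection week prior to
study end* (0–4 by default) is therefore the length of its observed growth
window: week 0 means the tumor appeared at termination, week 4 that it had
four weeks to grow past the ~100 mg palpation threshold.

## Growth stage

Necropsy mass is regressed on week-prior-to-end by ordinary least squares,
separately per strain; tumors are treated as independent even when one rat
bears several (rat-level clustering is a known caveat of the design, not
modeled here). The DS-vs-DR contrast is the strain×week interaction t-test
in a pooled model; when only summary (slope, SE) pairs are available a
normal z-test on the slope difference is used instead. The fold ratio is
always slope_DS/slope_DR.

## Kinetic deconvolution

Cell-cycle duration is P_d = P_n / mitotic index. Two unit modes exist
because the division is dimensionally ambiguous:

- `as-published` (default): mitotic index in **figures per field**. With the
  group means (P_n ≈ 9%, ~0.45 figures/field) this gives durations of ~20 h,
  the scale of a mammalian cell cycle.
- `per-cell`: mitotic index as a per-cell percentage
  (100 × figures/total cells). Dimensionally strict but yields durations
  ~8.5× longer (total cells / 100 ≈ 8.5 at 850 cells/field).

Both are computed per tumor and then averaged (mean of ratios). Note that a
mean of ratios with a noisy denominator exceeds the ratio of means (Jensen
effect): at 10 fields/tumor the per-strain mean P_d runs ~25% above
P̄_n/mitotic-mean, while the *between-strain percent difference* is nearly
unaffected — which is why the pipeline reports contrasts rather than
absolute durations as its primary kinetic readout.

Apoptotic duration inverts the balance model:
D_d = D_n / ((P_n/P_d) − (ΔS/n)), with ΔS the per-tumor growth rate
(necropsy mass / hours between palpation and termination, converted to
cells/h at 10⁻⁹ g per cell) and n the strain slope in cells gained/h. Two
caveats are inherent to the estimator and surfaced rather than patched:

- n enters as a rate although the balance equation defines it as a cell
  number; the estimator is implemented as specified.
- For a tumor growing at or above its proliferative supply the denominator
  is ≤ 0 and D_d is undefined. Under the default conditions
  E[ΔS/n] = mass/(slope·week) ≥ 1 exceeds the mitotic index for most
  tumors, so most per-tumor D_d values are flagged undefined (NaN), excluded
  from group means, and counted in the summary. Week-0 tumors have a zero
  growth window and are likewise undefined.

## Count models

Mitotic figures and apoptotic bodies per high-power field are modeled as
gamma-mixed Poisson: the field's latent rate is Gamma(shape k, mean μ),
giving a negative binomial with variance μ + μ²/k. The NB ML fit profiles
the likelihood over log k (the mean MLE is the sample mean for any fixed k);
samples with variance ≤ mean return the Poisson-boundary fit flagged
`poisson_limit` instead of failing. Overdispersion is tested with the
index-of-dispersion statistic Σ(y−ȳ)²/ȳ against χ²(n−1), one-sided for
variance > mean; simulation puts its size at ~5.6% at the study scale.
Group comparison uses an NB GLM (log link) with a group indicator and a
Wald test, with the NB alpha fixed at the pooled profile-ML estimate;
per-cell event probabilities are reported as mean events per field divided
by mean cells per field.

## Field-sampling planner

Total 400× fields by section long axis: <10 mm → 5, 10–15 → 10, 15–20 → 15,
≥20 mm → 20. The category table as stated leaves exactly 20.0 mm unassigned;
it is placed in the 20-field category so coverage is monotone. Hotspot
fields are ceil(total × hotspot%/100); the remainder are typical fields.

## Multivariate stage

PCA is computed by NIPALS on mean-centered, unit-variance-scaled data
(convergence: relative score change < 1e-9 or 500 iterations; each
loading's largest-magnitude element is made positive for reproducibility).
R²X per component is the captured fraction of total scaled sum of squares.
Q² uses contiguous 7-fold row-wise cross-validation with per-component
PRESS: Q²_a = 1 − PRESS_a/SS_{a−1} and Q²cum = 1 − Π PRESS_a/SS_{a−1}, with
centering/scaling estimated once on the full data. Commercial element-wise
CV schemes differ in detail, so published R²X/Q² values from such tools are
scheme- and data-dependent and are not reproduction targets. The two-group
test on scores is the exact-F two-sample Hotelling T²; in one dimension it
equals the squared pooled t. PLS1 uses the one-component NIPALS closed form
(w ∝ X'y) on UV-scaled X and y; coefficients are reported on the scaled
scale, so their magnitudes are comparable across analytes.

## Synthetic-cohort generator

The generator's defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| rats per strain | DR 103, DS 101 | study cohort sizes |
| incidence | DR 0.65, DS 0.91 | reported cancer incidence |
| multiplicity (mean, ≥1 truncated Poisson) | DR 2.14, DS 2.82 | chosen so expected tumor yields ≈ 143 / 259 |
| slope (g/week) | DR 0.533, DS 0.968 | reported regression slopes |
| detection threshold | 0.1 g | palpation detection mass |
| detection week | uniform on 0–4 weeks prior to end | detection-window readout; distribution unspecified, uniform chosen |
| mass noise sd | 0.6 g | matches the regression scatter implied by the reported slope SEs at the cohort sizes |
| cells/field | N(850, 85) clipped to [500, 1500] | census of 700–1000 cells; strain means 838.7/863.2 |
| mitotic mean (per field) | DR 0.448, DS 0.571 | reported group means |
| apoptotic mean (per field) | DR 1.877, DS 2.616 | reported group means |
| NB dispersion k | 1.5 | no field-level dispersion is printed; k=1.5 reproduces per-tumor SDs of ~0.65–0.85 at 10 fields/tumor, the reported scale |
| Ki67 (%) | DR N(9.0, 3.1), DS N(9.4, 4.0), truncated to (0,100) | group SEMs × √20 |
| fields per tumor | 10, 30% hotspot | planner output for a mid-size (10–15 mm) section |
| panel | 29 analytes: 23 checkpoint/apoptosis protein variables (baseline 1.0, sd 0.25; DS shifts of ±15–40% oriented as observed) + 6 count/IHC/kinetic variables at the strain means | named proteins; full list of 29 not enumerated in the source, panel configurable |

Necropsy mass is linear in expectation: threshold + slope × week, with
Gaussian noise truncated below at the detection threshold. Naive truncation
would bias E[mass|week] upward most at short windows and flatten fitted
slopes, so the truncated normal's location is solved (Brent root-finding)
to keep the conditional mean exactly on the configured line; week-0 tumors
sit at the threshold. An exponential-growth mode (per-cell kinetics,
matched to the linear endpoint) is available for simulator-style property
tests. All draws descend from a single seed through fixed `SeedSequence`
spawn keys, so every generator is individually and jointly reproducible.

What the generator does **not** emulate: rat-level clustering of tumor
growth rates and counts (fields and tumors are independent given strain),
spatial hotspot structure within sections, body-weight/diet trajectories,
measurement error in Ki67 image analysis, and correlation among panel
analytes (variables are drawn independently). Passing tests therefore
demonstrate estimator correctness and calibration under the assumed
sampling model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- NB profile ML: bounded scalar minimization over log k ∈ [−12, log 1e8];
  k above ~1e8 is reported as the Poisson limit.
- Truncated draws (mass, Ki67) use `scipy.stats.truncnorm` driven by the
  stage RNG; sd = 0 short-circuits to the exact mean.
- Regression preconditions: ≥3 tumors and ≥2 distinct weeks, else a
  singular-design error; groups need ≥2 tumors for a SEM.
- PCA rejects constant columns by name; Hotelling requires each group to
  exceed the score dimension and raises on a singular pooled covariance.
- Report JSON is NaN-free (undefined values serialize as null) and
  timestamp-free; the wall-clock timestamp lives in `run_manifest.json`
  outside the determinism contract.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to make their bands sharp while the
suite stays fast: slope-recovery coverage over 200 seeds at the full cohort
sizes; NB ML recovery at 1e5 draws; dispersion-test and Hotelling
calibration at 500–1000 replicates; count-group comparisons at 20 tumors ×
10 fields per group. The kinetics percent-difference check uses 40 seeds at
~20 tumors/group, where the across-seed spread (sd ≈ 23 percentage points,
driven by Ki67 between-tumor variability) permits a location check
(median/mean in [−25, −8]) rather than a tight per-seed band.

## Known limitations

- The two Eq.-level unit irregularities described above are reported, not
  resolved; `per-cell` mode exists for dimensional consistency.
- Cohort-level published statistics (R²X = 0.98 / Q² = 0.66, Hotelling
  p = 0.025, count-test p = 0.063/0.028, r² = 0.554) depend on unreleased
  raw data and are covered by parameter-recovery and calibration properties
  rather than value reproduction.
- The NB GLM treats fields as independent; with per-tumor rate sharing the
  test would be anticonservative. The generator draws field rates
  independently, so calibration results here do not certify clustered data.
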