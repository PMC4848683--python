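# tumorkinetics

Growth-kinetics analysis for chemically induced rat mammary carcinomas in a
premenopausal obesity model: two Levin strains, dietary-obesity **resistant
(DR)** and **sensitive (DS)**, develop MNU-induced tumors that are palpated
twice weekly (detection at ~100 mg) and weighed at necropsy 63 days
post-carcinogen. The package estimates how fast tumors accumulate mass in
each strain and deconvolves that difference into cell-cycle and apoptotic
kinetics, for biostatisticians and cancer-prevention researchers working
with detection-week/necropsy-mass designs.

## The model

Tissue size is a balance between proliferation and death,

> ΔS = n (k_P − k_D),

so a growing tumor has ΔS > 0. The pipeline quantifies each side of the
balance:

- **Growth rate** — OLS of necropsy mass *M_T* (g) on the week the tumor was
  first palpated prior to study end gives a strain slope (g/week); the DS/DR
  contrast uses a pooled strain×week interaction t-test.
- **Cell-cycle duration** — P_d (h) = P_n / mitotic index, with P_n the Ki67
  immunoreactive percent and the mitotic index in figures per field
  (`as-published` mode) or per-cell percent (`per-cell` mode).
- **Apoptotic duration** — D_d (h) = D_n / ((P_n/P_d) − (ΔS/n)), with D_n the
  apoptotic index, ΔS the per-tumor growth rate (cells/h at 10⁻⁹ g/cell) and
  n the strain slope converted to cells gained/h. Non-positive denominators
  are flagged undefined, never returned negative.
- **Count models** — per-field mitotic/apoptotic figures are overdispersed;
  they are fit as gamma-mixed Poisson (negative binomial, variance =
  μ + μ²/k) with a profile-likelihood ML, an index-of-dispersion score
  test, and an NB-GLM two-group comparison.
- **Ki67 field planning** — 5/10/15/20 image fields by section long axis
  (<10, 10–15, 15–20, ≥20 mm), hotspot share rounded up.
- **Multivariate stage** — from-scratch NIPALS PCA with per-component R²X
  and 7-fold cross-validated Q², a two-sample Hotelling T² on scores, and
  single-component PLS1 of tumor mass on a 29-variable protein/count panel.

A synthetic-cohort generator reproduces the study's statistical structure
(strain sizes, incidence, detection window, slopes 0.533/0.968 g/week,
700–1000-cell fields, Ki67 ≈ 9%, panel mean shifts), so the whole pipeline
is testable without any raw data.

## Worked example

```python
from tumorkinetics import CohortConfig, run_pipeline

CohortConfig(seed=7).to_yaml("study.yaml")   # defaults = study conditions
report = run_pipeline("study.yaml", "out/")
g = report["growth"]
print({s: round(f["slope"], 3) for s, f in g["per_strain"].items()})
print(round(g["comparison_ds_vs_dr"]["ratio"], 2),
      g["comparison_ds_vs_dr"]["p_value"] < 0.01)
print(round(report["kinetics"]["percent_difference_vs_DR"]["DS"]["pd_hours"], 1))
```

prints

```
{'DR': 0.544, 'DS': 0.963}
1.77 True
-17.5
```

i.e. the fitted growth slopes recover the generating 0.533 and 0.968 g/week
within sampling error, DS tumors grow ~1.8-fold faster than DR (interaction
p < 0.01), and the estimated DS cell-cycle duration is ~17% shorter than DR.
The same run reports the per-field count overdispersion (NB dispersion
k ≈ 1.5, dispersion-test p ≪ 0.001), the NB-GLM mitotic rate ratio
(1.33, p ≈ 2×10⁻⁷), the PCA R²X/Q² profile with a Hotelling test separating
the strains on the score space, and PLS1 coefficients whose strongest
positive mass predictors include cytochrome c and XIAP.

The same stages are available from a shell:

```bash
tumorkin run-all --config study.yaml --out out/
tumorkin fields-plan --axis-mm 12 --hotspot-pct 30
tumorkin growth --tumors out/tumors.csv
```

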