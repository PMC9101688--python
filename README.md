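# mrpipe

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, allele harmonization, five causal estimators with
pleiotropy/heterogeneity diagnostics, and a synthetic summary-statistic
generator so the whole pipeline is verifiable by parameter recovery
without downloading anything.

## The problem

Observational associations between a modifiable exposure (e.g. body mass
index) and a disease outcome (e.g. atrial fibrillation) are confounded
and subject to reverse causation. Two-sample MR uses genetic variants as
instrumental variables: for each variant *j*, one GWAS supplies its
per-allele effect on the exposure (γ̂ⱼ, SE σ_γⱼ; SD units) and a second,
non-overlapping GWAS supplies its effect on the outcome (Γ̂ⱼ, SE σ_Γⱼ;
log-odds). If the variants satisfy the instrument assumptions (predictive
of the exposure, independent of confounders, no pathway to the outcome
except through the exposure), the per-variant Wald ratio bⱼ = Γ̂ⱼ/γ̂ⱼ
estimates the causal log-odds ratio β per 1-SD of exposure.

The package implements the standard estimator battery around that idea:

- **IVW** — inverse-variance-weighted meta-analysis of the bⱼ
  (equivalently, weighted regression of Γ̂ on γ̂ through the origin),
  with fixed or multiplicative random-effects SEs;
- **MR-Egger** — the same regression with a free intercept; the
  intercept estimates average directional pleiotropy, with the I²_GX
  statistic for measurement-error (NOME) attenuation and a **SIMEX**
  extrapolation that corrects it;
- **Weighted median (WME)** — consistent while valid instruments hold
  more than half the weight;
- **RAPS** — maximizes an error-in-variables profile likelihood,
  removing the regression-dilution bias of IVW under weak instruments;
- **GSMR** — inverse-variance pooling with both sampling errors in the
  weights, preceded by the HEIDI single-instrument heterogeneity screen.

Instrument QC covers genome-wide significance filtering, greedy LD
pruning (r² < 0.001 within 1000 kb), user-supplied exclusion lists
(e.g. phenome-scan hits), radial Cochran's-Q outlier removal, MR-PRESSO,
and first-stage strength via R² and F = R²(n−1−K)/((1−R²)K). Diagnostics
include Cochran's Q with I² = (Q−df)/Q, leave-one-out, and figure-ready
scatter/funnel/forest tables.

## Worked example

Simulate a BMI→AF-scale study (303 genome-wide-significant instruments,
exposure n = 681,275; outcome 60,620 cases / 970,216 controls, true
causal log-OR 0.354) and run the full pipeline:

```bash
mrpipe run --simulate paper_like --seed 7 --out results/demo
```

prints (plus the QC ledger in the log):

```
        method  nsnp     beta       se         pval      or_   ci_low  ci_high  intercept  intercept_se  intercept_pval
           IVW   291 0.372271 0.024773 4.886410e-51 1.451026 1.382253 1.523221        NaN           NaN             NaN
      MR-Egger   291 0.383205 0.117209 1.077738e-03 1.466978 1.165878 1.845841  -0.000161      0.001689        0.923967
           WME   291 0.348405 0.037553 1.732822e-20 1.416806 1.316268 1.525022        NaN           NaN             NaN
          RAPS   291 0.376406 0.025058 5.318961e-51 1.457039 1.387207 1.530386        NaN           NaN             NaN
          GSMR   291 0.372271 0.024917 1.794681e-50 1.451026 1.381865 1.523649        NaN           NaN             NaN
MR-Egger SIMEX   291 0.510573 0.141837 3.185807e-04 1.666245 1.261840 2.200256  -0.001955      0.002027        0.334758

I²_GX = 0.666
MR-PRESSO global p = 1.000
R² = 0.0286, F = 68.8 (K = 291)
```

Reading it: 291 of the 303 simulated instruments survive QC (the radial
Cochran's-Q stage trims 12 ratio outliers); the IVW causal odds ratio is
1.451 (95% CI 1.38–1.52) per 1-SD of exposure against a simulated truth
of exp(0.354) = 1.425, and the robust estimators agree. The Egger
intercept is indistinguishable from zero (no directional pleiotropy was
simulated) and I²_GX = 0.67 < 0.9 flags exposure-side measurement error,
which is why the SIMEX-corrected Egger row is added. `results/demo/`
holds the harmonized instruments, QC ledger, result tables, leave-one-out
rows and figure data as TSVs plus a `manifest.json` with every seed.

The same pipeline runs on real summary-statistic files
(`mrpipe run --exposure bmi.tsv --outcome af.tsv ...` with per-file
column maps in a YAML config), and the library surface mirrors each
stage (`harmonize_instruments`, `radial_q_filter`, `ivw`, `egger`, ...)
with scikit-learn-style estimator classes underneath
(`IVWEstimator().fit(instruments).result_`).

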