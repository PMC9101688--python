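# Methods

## Model

For variant *j* the two GWAS report γ̂ⱼ ~ N(γⱼ, σ_γⱼ²) (per-allele
effect on the exposure, SD units) and Γ̂ⱼ ~ N(Γⱼ, σ_Γⱼ²) (per-allele
log-odds on the outcome), with independent errors because the samples
do not overlap. A valid instrument satisfies Γⱼ = β·γⱼ; an invalid one
carries a direct (pleiotropic) path αⱼ, so Γⱼ = β·γⱼ + αⱼ. The causal
parameter β is a log-odds ratio per 1-SD of exposure; results are
reported as OR = exp(β̂) with 95% CI exp(β̂ ± 1.96·SE).

## Harmonization

Both effects must refer to the same effect allele. Reconciliation order:
direct allele match → swapped labels (negate Γ̂, complement EAF) →
strand complement → complement + swap. Palindromic variants (A/T, C/G)
are strand-ambiguous, so they are oriented by allele-frequency
concordance and dropped when either study's EAF is missing or lies in
the intermediate band (default [0.42, 0.58], configurable — the
conventional choice; frequency cannot identify strand near 0.5).
Harmonizing an already-harmonized pair is a no-op, and all downstream
estimates are invariant to the input allele encoding; both properties
are tested.

## Instrument QC

Stage order is fixed: genome-wide significance (p < 5×10⁻⁸, strict) →
greedy LD pruning (accept in ascending-p order, reject r² ≥ 0.001
within 1000 kb; ties broken lexicographically by rsID) → exclusion
lists (a precomputed rsID→reason table; the interface for phenome-scan
screens) → harmonization → radial Cochran's Q → MR-PRESSO → HEIDI. A
ledger records every variant at every stage; counts chain exactly, and
a disabled stage leaves an explicit "skipped" row.

- **Radial Q** (α = 0.05, iterated): against the IVW fit, qⱼ =
  wⱼ(bⱼ − β̂)² with wⱼ = γ̂ⱼ²/σ_Γⱼ² is ~χ²₁ under homogeneity;
  variants above the upper-α quantile are removed and the fit repeated
  until stable. Iteration never goes below 3 instruments.
- **MR-PRESSO** (n_sim = 1000): the observed residual sum of squares
  around leave-one-out IVW slopes is compared with a parametric null
  (Γ̂ⱼ* ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ²), γ̂ⱼ* ~ N(γ̂ⱼ, σ_γⱼ²)); per-variant
  outlier p-values are Bonferroni-screened only when the global p is
  below α. The simulation is fully vectorized; the global p uses the
  (r+1)/(n+1) convention so it is never exactly zero.
- **HEIDI** (p < 0.01, one repeat pass): per-variant deviation dⱼ =
  bⱼ − β̂ with Var(dⱼ) ≈ (σ_Γⱼ² + β̂²σ_γⱼ²)/γ̂ⱼ², two-sided normal test.
- **Strength**: per-variant R²ⱼ = 2fⱼ(1−fⱼ)γ̂ⱼ² for a standardized
  exposure (alternative zⱼ²/(zⱼ²+n) available);
  F = R²(n−1−K)/((1−R²)K). At the published inputs (R² = 0.025,
  n = 681,275, K = 303) this formula gives F ≈ 57.6; it is exposed as a
  plain function so that number is reproducible as printed math.

## Estimators

All five consume the harmonized table; SEs and two-sided normal
p-values as noted. IVW and Egger use multiplicative random-effects
scaling floored at 1 (fixed-effect is a switch), so with
under-dispersed instruments the two coincide.

- **IVW**: β̂ = Σwγ̂Γ̂/Σwγ̂², w = 1/σ_Γ²; SE = (Σwγ̂²)^(−1/2), scaled
  by max(1, √(Q/(L−1))).
- **Egger**: instruments oriented to γ̂ ≥ 0, WLS with intercept;
  slope = causal estimate, intercept = mean directional pleiotropy.
  Scaling floor as above with L−2. I²_GX = (Q_GX−(L−1))/Q_GX measures
  NOME violation; below 0.9 the slope is materially attenuated.
- **SIMEX-Egger**: for λ ∈ {0, 0.5, 1, 1.5, 2}, γ̂ is perturbed with
  extra noise of variance λσ_γ² (1000 replicates per λ), the mean
  slope/intercept per λ is fit by a quadratic in λ and read off at
  λ = −1 (zero-error limit). SEs by jackknife over instruments, with
  leave-one-out sums computed by subtraction so the whole procedure is
  vectorized. With σ_γ = 0 all λ points coincide and SIMEX returns the
  naive Egger fit exactly.
- **Weighted median**: weights γ̂²/σ_Γ² normalized; the estimate
  interpolates the weighted quantile function at 0.5 via cumulative
  midpoints. SE by nonparametric pair bootstrap (resample instruments
  with replacement, 1000 draws). The often-cited parametric bootstrap
  (redraw γ̂, Γ̂ around their observed values) is available as an
  option but is deliberately not the default: redrawing around
  observed values convolves the realized scatter with a second copy of
  the sampling noise, and under a sharp null its SE runs ~20% high
  (measured type-I error 0.012 at nominal 0.05; the pair bootstrap
  gives 0.05–0.06).
- **RAPS** (simple model, no overdispersion): maximizes the profile
  likelihood l(β) = −½Σ(Γ̂−βγ̂)²/(σ_Γ²+β²σ_γ²). Its score includes
  the term βσ_γ²(Γ̂−βγ̂)²/v² which cancels the O(βσ_γ²) bias of the
  naive ratio score; dropping it (a common simplification) reintroduces
  a small attenuation. Root found by bracketed bisection around the
  IVW estimate at near-machine tolerance (the score at the root is
  < 1e-8); SE from the observed information. The empirical sandwich is
  asymptotically equivalent but shrinks on QC-trimmed panels whose
  residual dispersion is deflated by outlier removal (measured 95%
  coverage 0.883 vs 0.920 for the information SE at the default
  paper-scale scenario), so the information form is used.
- **GSMR** (identity LD, as guaranteed by upstream pruning): HEIDI
  screen, then β̂ = Σwb/Σw with w = γ̂²/(σ_Γ² + β̂²σ_γ²) iterated three
  times from the IVW start; SE = (Σw)^(−1/2). Plugging the pooled β̂
  rather than each noisy bⱼ into the variance keeps the weights
  independent of the per-variant ratio noise; with bⱼ in the weights
  the pooled estimate is measurably attenuated (0.338 vs 0.346 at the
  paper-scale scenario) and its CI undercovers.

## Synthetic data

The generator emulates a post-discovery instrument panel, not a whole
genome: per variant it draws fⱼ ~ U(maf_range), γⱼ ~ N(gamma_dist),
αⱼ by pleiotropy mode (none; balanced N(0, sd²); directional
N(mean, sd²); InSIDE-violating αⱼ = 0.3γⱼ + noise), sets
Γⱼ = βγⱼ + αⱼ, and adds noise with σ = 1/√(2f(1−f)·n·v) where v = 1
for the standardized exposure and v = φ(1−φ) for a case-control
outcome with case fraction φ — without the case-fraction factor the
outcome SEs (and every downstream SE) would be ~4× too small relative
to a real case-control GWAS of this size. Allele encoding exercises the
harmonizer: configurable fractions of palindromic variants, strand
flips and label swaps in the outcome file.

When `ascertain_p` is set, (γⱼ, γ̂ⱼ) pairs are resampled until the
observed exposure association passes that threshold. This reproduces
how a real discovery panel is built — every published instrument passed
genome-wide significance in the exposure study itself — and it is what
makes the pipeline's significance stage a no-op on the emulated panel.
Its price is realism's price: winner's curse. Observed γ̂ are slightly
inflated, so the direct IVW estimate is attenuated by ~2% (regression
dilution 1/F̄ plus curse), exactly as in real two-sample MR at this
instrument strength.

### Scenario presets

| preset | emulates | key settings |
|---|---|---|
| `paper_like` | the BMI→AF study scale | L = 303, β = 0.354, n_exp = 681,275, n_out = 1,030,836 (φ = 0.0588), γ ~ N(0.0125, 0.0036²), f ~ U(0.3, 0.5), ascertained at 5×10⁻⁸ |
| `null` | no causal effect | paper_like with β = 0 |
| `balanced_pleiotropy` | InSIDE-respecting noise | α ~ N(0, 0.005²), all variants |
| `directional_pleiotropy` | Egger's target | α ~ N(0.01, 0.002²), all variants; n_exp = 2×10⁶ so I²_GX > 0.9 and the intercept is unattenuated |
| `forty_pct_invalid` | weighted-median regime | L = 100, 40% invalid with α ~ N(0.02, 0.035²) |
| `weak_instruments` | NOME violation | L = 800, n_exp = 80,000, γ ~ N(0.02, 0.008²) → I²_GX ≈ 0.69 |

`paper_like` calibration: gamma_dist was chosen so the observed panel
explains R² ≈ 0.030 (within 20% of the published 2.5%) and the
exposure-side spread is as large as that constraint allows; at the
published (R², n, K) the mean instrument χ² is pinned near 57, so some
ascertainment pressure is unavoidable and the resulting I²_GX ≈ 0.65
(below the published 0.778 — the published panel's effect-size spread
cannot be widened further without leaving the R² band). Outcome SEs
land at ≈ 0.006 per variant, which reproduces the published IVW SE
scale (≈ 0.029 for the pooled log-OR).

What the generator does **not** emulate: LD between instruments (the
panel represents the post-pruning regime), allele-frequency differences
between the two studies, population stratification, sample overlap, and
genome-wide discovery itself (no non-significant variants are
produced). Passing tests therefore demonstrate estimator correctness
and pipeline bookkeeping under the stated sampling model, not
robustness to those data pathologies.

## Verification battery (problem sizes)

- Null calibration: 500 draws of `null`; each estimator's type-I error
  at α = 0.05 must lie in [0.03, 0.07]. Measured ≈ 0.04–0.06.
- Parameter recovery: 300 full pipeline runs of `paper_like`; the mean
  IVW log-OR must land within 0.01 of 0.354, and IVW/WME/RAPS/GSMR 95%
  CI coverage within [0.90, 0.99]. 300 replicates put the Monte-Carlo
  SEM of the mean (≈ 0.0016) well inside the 0.01 band. The measured
  mean is ≈ 0.345–0.347 across seed blocks (the ~2% winner's-curse/
  dilution attenuation noted above, close to the band's edge); IVW
  coverage likewise sits at the low edge of the band (0.90–0.93
  across seed blocks) because the QC-trimmed panel's realized
  dispersion falls below the model SE — a real post-selection
  phenomenon, not an implementation artifact.
- Robustness: 50 draws of `forty_pct_invalid`; the weighted median's
  replicate-mean must recover β within twice its mean SE while IVW is
  biased beyond 2·SE in ≥ 80% of replicates. The per-replicate version
  of the WME clause is unattainable in principle: with one-sided
  invalid instruments the weighted median converges to an upper
  quantile of the valid ratio distribution, so its bias and its SE
  both scale with the ratio noise and their ratio grows as √L.
- SIMEX: 50 draws of `weak_instruments`; the SIMEX slope must beat the
  naive Egger slope in ≥ 45. Measured 49–50.
- Oracle equivalence: closed-form IVW/Egger vs a generic WLS solver on
  100 random instances, agreement to 1e-10.
- Bookkeeping: encoding invariance of all estimates and exact ledger
  chaining on every synthetic run.

## Numerical choices and edge cases

- Strict inequality at the significance threshold; LD ties broken by
  rsID; missing LD pairs treated as r² = 0 with a warning (configurable
  to raise).
- Outlier filters refuse to go below 3 instruments (they keep the
  least-extreme ones).
- All stochastic stages draw their seed as
  `master_seed XOR crc32(stage_name)` (kept below 2³¹), so inserting or
  disabling a stage never changes another stage's stream, and identical
  configs are byte-identical end to end.
- p-values are two-sided normal throughout; exact zeros are clipped to
  the smallest positive float on generation.
- OR and CI columns are exact transforms of (β̂, SE), never rounded
  intermediates.
- Tables are TSV with "NA" for missing (also accepted: empty, ".");
  ≥ 10 significant digits on write, so read∘write is identity to 1e-9.

## Known limitations

- GSMR is the identity-LD special case; correlated instruments are out
  of scope (LD enters only through pruning).
- RAPS implements the simple quadratic-loss model only (no
  overdispersion, no robust loss), matching the published analysis
  note that the simple model was used.
- The Egger orientation step makes the intercept sign convention
  depend on the γ̂ ≥ 0 recoding, as is standard.
- Real-data reproduction requires the two public GWAS files; the test
  suite substitutes the calibrated synthetic panel and checks the
  published numbers only through their printed arithmetic
  relationships.
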