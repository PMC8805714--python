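# Methods

## Study design implemented

The package implements a complex-level, tissue-specific two-sample MR
design. The exposure for one analysis cell is the pooled expression of a
gene complex (e.g. the RNA-polymerase-III-specific subunits) in one
tissue: all significant cis-eQTLs for any gene of the complex are pooled
into a single instrument list. Pooling genes means the causal estimate is
in "per unit NES of any complex member" units and its absolute magnitude
is hard to interpret; the direction and significance of the association
are the scientific outputs, and that caveat is inherited by everything
downstream.

Cells in which a tissue yields no pooled instruments (sparse tissues such
as small intestine in real eQTL catalogues) are recorded as not-testable
and still count toward the designed family size in multiple testing (see
below).

## Instrument assembly

**Pooling and deduplication.** A variant that is an eQTL for two or more
genes of the same complex would enter the regression twice with correlated
effects; the default `min_p` policy keeps exactly one record per variant —
the smallest eQTL p — and `keep_all` is available for sensitivity
analysis. Output order is p-ascending with the variant key as a
deterministic tie-break.

**LD pruning** (`r2_threshold` default 0.1, unitless squared correlation)
is greedy: visit SNPs in ascending eQTL-p order and accept a SNP iff its
r² with every already-accepted SNP is ≤ the threshold. This realises the
"drop the weaker instrument of a violating pair" rule deterministically
and guarantees the admissibility invariant (no retained pair above
threshold). Pruning is applied across the pooled set, not per gene, so
the invariant holds set-wide; pairs absent from the LD source are treated
as independent (r² = 0).

**Harmonization.** Exposure effects follow the GTEx NES convention
(effect of ALT relative to REF), so the exposure effect allele is ALT.
Outcome records are matched by rsid. Non-palindromic allele pairs are
aligned directly, by swapping (flip the sign of β_Y, replace EAF by
1−EAF), or via strand complement. For palindromic SNPs (A/T, C/G) allele
labels cannot identify the physical allele across strands, so orientation
is inferred by comparing effect-allele frequencies; a palindromic SNP is
dropped whenever either frequency lies inside the ambiguity window
(`palindromic_window`, default 0.42–0.58 — the convention of the widely
used harmonization tooling), or when the exposure has no frequency to
compare. Every drop is counted in per-cell provenance so that
pooled = kept + dropped_palindromic + dropped_unmatched + dropped_invalid
(+ pruned) holds exactly.

## Estimators

All estimators weight by the inverse outcome variance 1/se_Y²; exposure
effects are treated as fixed (the NOME convention of summary-data MR).

- **IVW**: θ̂ = Σ w β_X β_Y / Σ w β_X², fixed SE = (Σ w β_X²)^{−1/2}.
  The default multiplicative-random-effects SE multiplies the fixed SE by
  max(1, √(RSS_w/(J−1))). The floor at 1 makes the default deliberately
  conservative under homogeneity (its measured null rejection rate is
  slightly below nominal); the point estimate is identical in both modes,
  and the fixed mode — exact under the model — is used for distributional
  calibration checks. P-values are two-sided normal.
- **MR-Egger**: weighted regression with free intercept after orienting
  every instrument to β_X ≥ 0 (Egger is not invariant to per-SNP sign
  conventions; orienting on the exposure effect is the standard choice).
  Slope and intercept SEs share the residual scale max(1, √(RSS_w/(J−2)));
  p-values from t(J−2). Requires J ≥ 3.
- **Weighted median**: Wald ratios sorted ascending; with normalized
  weights w_j ∝ (|β_X|/se_Y)², the estimate interpolates the cumulative
  mid-weights p_j = Σ_{k≤j} w_k − w_j/2 at 1/2. SE by seeded parametric
  bootstrap (default `n_boot` 1000): resample (β_X, β_Y) from normals at
  the observed values, SE = SD of replicate estimates. Requires J ≥ 3.
- **Cochran's Q** at the IVW slope, χ²(J−1), reported with IVW.

Cells below an estimator's minimum instrument count yield a recorded
`not_estimable` result (NaN estimates), never an exception, so grid runs
always complete.

## MR-PRESSO

The global statistic is the weighted RSS of leave-one-out IVW residuals:
r_j = β_Yj − θ̂_(−j) β_Xj with θ̂_(−j) the IVW slope excluding j. Its null
distribution is simulated by redrawing β_X*_j ~ N(β_Xj, se_Xj) and
β_Y*_j ~ N(θ̂_(−j) β_Xj, se_Yj) (`n_sim` default 1000) and recomputing the
statistic; the per-SNP simulated weighted squared residuals are retained
for the outlier test, whose empirical p_j is Bonferroni-adjusted (×J)
against α = 0.05. Empirical p-values use the add-one estimator
(k+1)/(n_sim+1), so p = 0 is impossible and the resolution floor is
1/(n_sim+1); the package warns when J/(n_sim+1) ≥ α, i.e. when no outlier
flag could pass Bonferroni at the chosen simulation count. The distortion
test compares D = (θ̂_raw − θ̂_corrected)/|θ̂_corrected| against removing
the same number of instruments at random (without replacement). The
corrected estimate is exactly IVW on the non-outlier subset. The exposure
SE required by the parametric simulation is taken from the eQTL table's
slope SE. Requires J ≥ 4 (leave-one-out must retain ≥ 3).

## Multiple testing

The family size m is a design parameter, not inferred from the data: the
longevity grid is 8 tissues × 2 case definitions = 16 tests per gene set
(`m_longevity`), and the disease/trait arm is 10 outcomes per exposure
(`m_outcomes`), per (gene set, tissue). Cells without instruments
contribute no p-value but keep m at its design value. q-values are
computed as BH-adjusted p against the designed m — q_(j) = min_{k≥j}
p_(k)·m/k — which is exactly the λ = 0 (most conservative) q-value;
BH step-up flags at `fdr_level` (default 0.10) coincide with q ≤ level
when m equals the number of p-values. If more p-values are supplied than
the designed m, the family is corrected against the actual count.

## Synthetic data generator

The generator draws from the same model the estimators assume:
β_Yj = θ·β_Xj(true) + α_j + ε_j, with observed exposure effects
β_Xj(obs) = β_Xj(true) + N(0, se_Xj). Defaults define the emulated study
conditions:

- true |β_X| ~ U(0.3, 0.8) NES units with random sign; se_X ~ U(0.05,
  0.10), giving mean instrument F ≈ 50 (> 30), as appropriate for
  FDR-significant cis-eQTLs, which are strong by construction;
- se_Y ~ U(0.02, 0.05) on the log-OR scale, typical of a
  case/control longevity meta-analysis at these sample sizes;
- MAF ~ U(0.05, 0.45); the ALT allele is randomly minor or major;
- pleiotropy α_j: `none` (0), `balanced` (mean-zero normal),
  `directional` (nonzero mean, independent of β_X — InSIDE holds), or
  `inside_violating` (α_j ∝ |β_X| plus noise);
- allele metadata with configurable palindromic and swapped-encoding
  fractions, and a block LD structure (constant within-gene r²,
  independence across genes).

Outcome effects are generated directly on the log-OR scale — the pipeline
operates purely on summary statistics, so no individual-level binary
outcome model is simulated. What the generator does **not** emulate:
winner's-curse selection of eQTLs, realistic LD decay (blocks are
exchangeable), sample overlap between exposure and outcome studies, and
allele-frequency mismatch between panels. Passing tests therefore show
the pipeline's arithmetic and decision rules are correct under the
assumed model, not that real GTEx/GWAS data meet those assumptions.

## Numerical and calibration choices

- Exposure measurement error attenuates IVW by roughly E[se_X²]/E[β_X²]
  (order 1/F ≈ 2–4% at the defaults). Parameter-recovery and coverage
  checks are therefore run under the estimator's identification
  conditions (se_X ≈ 10⁻³, where the model the estimator fits is the
  model that generated the data), and the default-strength regime is
  checked separately for bounded attenuation. Likewise the type-I-error
  calibration uses the fixed-effects flag, since the random-effects floor
  is conservative by design.
- Estimator p-values are floored at the smallest positive double rather
  than reported as 0.
- All stochastic steps (bootstrap, PRESSO simulations) take explicit
  seeds; grid runs spawn per-cell seeds deterministically from the study
  seed via CRC32 of the cell label mixed into a `SeedSequence`, so an
  identical config reproduces the results grid bit for bit.
- Degenerate inputs: β_X = 0 instruments are excluded from ratio-based
  computation with a warning; empty LD files with a declared SNP list mean
  "no LD"; ties in eQTL p are broken by variant key.
- Simulation sizes in tests and the acceptance script (e.g. 2000 null
  replicates for type-I error, 500 for recovery, 60 seeds for outlier
  detection, 8-SNP × 2-gene cells for grid studies) were chosen as the
  smallest sizes at which the binomial/Monte-Carlo bounds being asserted
  are meaningfully tight.

## Known limitations

- Variant matching between exposure and outcome uses rsid; positional
  fallback is not possible with rsid-keyed outcome files that carry no
  coordinates.
- MR-Egger under the generator's default exposure noise is attenuated
  (weak-instrument regression dilution); no SIMEX-style correction is
  implemented.
- The disease/trait arm is exercised only on synthetic outcome files; no
  remote GWAS catalogue access is built in, by design.
- No mode-based estimators, multivariable MR, or Steiger filtering.
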