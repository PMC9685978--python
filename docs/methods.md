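# Methods

`mrscreen` implements a two-sample summary-data Mendelian randomisation
(MR) screen of the kind used to rank circulating biomarkers for causal
relevance to a disease outcome: instrument selection and harmonisation,
a battery of pleiotropy-robust univariable estimators, multivariable
adjustment models, and Bayesian model averaging for exposure ranking.
This note records the statistical model behind each component, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer should know about.

## The two-sample MR model

For variant j, let β̂_Xj (SE σ_Xj) be its association with a standardised
(inverse-rank-normalised) exposure from one GWAS and β̂_Yj (SE σ_Yj) its
association with the outcome on the log-odds scale from a second,
non-overlapping GWAS. If variant j is a valid instrument — relevant to the
exposure, independent of confounders, and affecting the outcome only
through the exposure — then β_Yj = θ β_Xj, where θ is the causal effect in
log-odds per SD of exposure. Results are reported as odds ratios per SD,
OR = exp(θ).

### Instrument selection and harmonisation

Instruments are genome-wide-significant variants (p < 5×10⁻⁸, strict
inequality) pruned to approximate linkage-equilibrium by greedy clumping:
accept the smallest remaining p-value, discard unaccepted variants within
10,000 kb on the same chromosome with r² ≥ 0.001 against it, repeat. The
pairwise r² comes from an abstract lookup (a file-backed implementation is
provided); with no lookup the panel is treated as LD-free — the synthetic
generator's case — and clumping reduces to the significance filter plus a
same-position de-duplication. Ties on p break by (chromosome, position,
id), so output is deterministic. A post-hoc assertion that no retained
in-window pair violates the r² threshold is part of the test suite.

Harmonisation aligns the outcome's effect allele to the exposure's coding:
matching alleles keep β̂_Y, swapped alleles flip its sign (and complement
the frequency), and a complement-strand match (A↔T, C↔G) is attempted
before a variant is dropped as `allele_mismatch`. Palindromic variants
(A/T, C/G) cannot be resolved from alleles alone; the default policy
`infer_by_frequency` aligns them by effect-allele frequency when both
frequencies fall outside [0.42, 0.58] and drops them as
`palindromic_ambiguous` otherwise, mirroring the conservative default of
standard two-sample MR tooling. `drop` and `keep` policies are available;
every exclusion is recorded with its reason, and |drops| + |retained|
always equals the intersection size.

Instrument strength is summarised by the per-variant F statistic
F_j = (β̂_Xj/σ_Xj)², with F ≤ 10 counted as weak by convention.

### Univariable estimators

- **Wald ratio** (single instrument): θ̂ = β̂_Y/β̂_X with the first-order
  delta-method SE σ_Y/|β̂_X|. The first-order SE ignores exposure-side
  noise; this matches the fixed-effect IVW weighting below and is accurate
  for the strong instruments (F ≫ 10) the selection step produces.
- **IVW**: the fixed-effect inverse-variance-weighted meta-analysis of the
  per-SNP Wald ratios, each weighted by σ_Yj⁻²; algebraically the weighted
  least-squares slope of β̂_Y on β̂_X through the origin. Fixed-effect SEs
  are the headline convention; a multiplicative random-effects inflation
  (√(RSS_w/(J−1)), floored at 1) is available behind a flag for
  sensitivity.
- **MR-Egger**: after orienting every SNP so β̂_X ≥ 0 (joint sign flips
  leave ratios unchanged), weighted regression β̂_Y = α + θβ̂_X with
  weights σ_Y⁻². The intercept α absorbs directional pleiotropy under the
  InSIDE assumption (pleiotropic effect sizes independent of instrument
  strength). Both SEs carry the multiplicative inflation
  max(1, √(RSS_w/(J−2))) and p-values use a t reference with J−2 degrees
  of freedom — standard practice where the source analyses are silent.
- **Weighted median**: per-SNP ratios θ_j weighted by w_j = β̂²_Xj/σ²_Yj,
  normalised; with ratios sorted, the cumulative-midpoint breakpoints are
  s_j = Σ_{i<j} w_i + w_j/2 and the estimate interpolates θ against s at
  0.5. Consistent when ≥50% of the weight comes from valid instruments.
  The SE is the SD of the estimate over a seeded parametric bootstrap
  (β̂* ~ N(β̂, SE²), default 1000 draws); the point estimate never depends
  on the seed, only the SE within Monte-Carlo error.
- **MR-PRESSO**: residual r_j = β̂_Yj − θ̂₋j β̂_Xj around the
  leave-one-out IVW slope θ̂₋j; the global statistic is the σ_Y⁻²-weighted
  RSS (the weighted form keeps heteroskedastic panels comparable; an
  unweighted variant would overweight imprecise SNPs). Its null
  distribution is simulated by redrawing β̂*_X ~ N(β̂_X, σ²_X) and
  β̂*_Y ~ N(θ̂₋j β̂_Xj, σ²_Y); empirical p-values use (1+count)/(n_sim+1)
  so they are never zero. Per-SNP outliers compare each observed squared
  residual with its own simulated distribution, Bonferroni-multiplied by J
  and flagged below 0.05; note the attainable minimum J/(n_sim+1) means
  n_sim must exceed roughly 20·J for flagging to be possible at all
  (default n_sim = 1000). The corrected estimate is plain IVW on the
  non-outliers, and the distortion test compares the corrected-minus-raw
  shift against random same-size subsets. Computation is ordered by
  variant id internally, so results are invariant to input row order.

Multiplicity over the screen is controlled per outcome with
Benjamini–Hochberg FDR across exposures, applied to the primary (IVW or
Wald) p-values; nominal and FDR thresholds both default to 0.05. A pair
whose primary estimate is null while a robust estimator is nominally
significant is flagged `discordant` rather than called significant — the
primary estimator carries the screening decision.

### Multivariable IVW

For K exposures, weighted least squares of β̂_Y on the J×K exposure-effect
matrix, no intercept, weights σ_Y⁻²; each coefficient is a direct effect
conditional on the co-modelled exposures, assuming pleiotropic pathways act
through the modelled set. Instruments are pooled across exposures (any
variant genome-wide significant for any modelled exposure), ranked by the
minimum p across exposures, and re-clumped as one set — re-clumping the
pooled list (rather than concatenating per-exposure lists) guarantees the
final design has no in-window LD pairs. Rank-deficient designs raise
`collinear_exposures` naming the most collinear pair rather than returning
a silent estimate. A per-exposure conditional-instrument-strength
diagnostic (the F of regressing each exposure column on the others; large
values flag weakly separated exposures) is reported as good practice.

### Bayesian model averaging (exposure ranking)

Each non-empty subset S of the K exposures is a candidate model. On the
whitened scale x̃_jk = β̂_Xjk/σ_Yj, ỹ_j = β̂_Yj/σ_Yj the model is
ỹ = X̃_S θ_S + ε with ε ~ N(0, I) and prior θ_S ~ N(0, σ²I), giving the
closed-form marginal likelihood ỹ ~ N(0, σ²X̃_S X̃_Sᵀ + I) (evaluated via
the determinant lemma and Woodbury identity, so cost scales with |S|, not
J). Priors are independent-inclusion, p^|S|(1−p)^(K−|S|); the empty model
is excluded. Posterior model probabilities (PP) normalise prior × evidence
over all 2^K − 1 models; the marginal inclusion probability (MIP) of an
exposure sums the PP of models containing it, and the model-averaged
causal effect (MACE) is the PP-weighted posterior-mean effect, zero where
absent. The MACE systematically understates the causal effect and is read
for direction and relative size only.

Defaults: inclusion prior p = 0.5 (0.25 and 0.75 as sensitivity runs, with
Kendall-τ rank concordance reported), effect-prior scale σ = 0.25 on the
whitened scale. σ is a genuine free parameter here — published analyses of
this design rarely state it — so rank orders are robust to it in the
regimes we test, but absolute MIPs shift with σ, and any comparison to
published MIP values carries that tolerance. Empirical per-exposure
p-values permute the whitened outcome vector against the rows of X̃ (one
permutation per replicate, shared across exposures; SEs held fixed) and
use the (1+count)/(n_perm+1) estimator, followed by BH FDR. Exhaustive
enumeration is bounded at K = 20; a stochastic model search is out of
scope.

## The synthetic generator

`TruthManifest`/`simulate` produce summary-statistics panels emulating the
screen's real inputs: standardised exposures from a large quantitative
GWAS (default n_x = 194,174, the female biobank sample the screen is
designed for) and a case-control outcome on the log-odds scale (default
n_y = 228,951). Per SNP j with assigned exposure a_j: a scalar
g_j ~ N(0,1) (oriented positive under `orient_bx`, emulating
effect-allele-increasing coding) gives true exposure effects
β_X[j,·] = τ·g_j·R[·,a_j] with τ = 0.02 and R the exposure correlation
matrix — with R = I a SNP instruments only its assigned exposure; with
correlated exposures (lipid-like blocks) the assigned effect propagates in
proportion to the correlation. τ = 0.02 with σ_X = 1/√n_x puts typical
instrument F statistics in the tens-to-hundreds, the range seen in
biobank-scale screens of this kind. True outcome effects are
β_Y = β_X θ* + α with pleiotropy α per mode: `none`; `balanced`
(N(0, ψ²)); `directional` (N(μ, ψ²)); `inside_violating`
(c·β_Xj1 + N(0, ψ²), coupling pleiotropy to instrument strength).
`pleio_fraction` restricts pleiotropy to the trailing fraction of SNPs
(the invalid-minority scenarios). SNPs named in `outlier_ids` have β_Y
multiplied by `outlier_scale` (default 10) and are guaranteed at least
reference instrument strength (|g| ≥ 1), because a multiplicative
distortion of a near-zero fitted value would be no outlier at all.
Observed effects add N(0, se²) noise with se_x = 1/√n_x, se_y = 1/√n_y;
p-values are recomputed from z-scores. Draws come from a single seeded
generator in a fixed, documented order (exposure effects, pleiotropy,
exposure noise, outcome noise), so identical manifests replay
byte-identically and tests can reconstruct the latent truth.

Simplifications to keep in mind: se = 1/√n treats the outcome as a
balanced continuous-scale GWAS (real case-control log-odds SEs also depend
on case fraction and allele frequency); panels are LD-free with a constant
allele frequency of 0.3 and non-palindromic A/G coding (a palindromic A/T
fraction is available on request); no winner's-curse or sample-overlap
structure. Passing calibration on these panels therefore demonstrates the
estimators' internal correctness under their own assumptions — not
robustness to LD misspecification, allele-frequency artefacts, or
selection effects in real data.

## Built-in calibration studies

`mrscreen.validation` packages the standing simulation studies that
`scripts/acceptance.py` re-runs from scratch (problem sizes chosen so the
whole battery completes in well under a minute on one CPU):

- IVW 95% CI coverage under the null: J = 50, 1000 replicates.
- Egger intercept test size under balanced pleiotropy (ψ = 0.004 ≈ 2σ_Y,
  so the inflation factor is active): J = 50, 1000 replicates.
- IVW vs weighted-median bias with 30% directional-pleiotropy instruments
  (μ = 0.004, oriented effects): 200 replicates.
- Outlier-detection power for one 10×-inflated SNP: J = 30,
  n_sim = 1000, 200 replicates.
- Ranking recovery: one true cause (θ* = 0.15) among K = 4 exposures with
  pairwise correlation 0.3, J = 100, 200 replicates.
- End-to-end screen: 10 exposures, 1 causal, exactly-one-FDR-hit rate over
  100 replicates (primary-estimator-only screen for speed).

## Numerical choices and degenerate inputs

- p-values are floored at the smallest positive double, never zero, so
  −log₁₀ p stays finite.
- All WLS fits solve the weighted normal equations directly (solve, not
  inversion by cofactors); the BMA evidence uses slogdet and reports the
  condition number on failure.
- Strict inequality at the significance threshold; clump discards at
  r² exactly equal to the threshold; clump ties break deterministically.
- β̂_X = 0 is a hard error for the Wald ratio (`null_instrument`);
  estimator preconditions (≥3 SNPs for Egger/median, ≥4 for the outlier
  battery, n_snp > K for MVMR/BMA) raise `insufficient_instruments`.
- Every stochastic step (bootstrap, outlier simulation, permutations,
  generator) requires an explicit seed; results objects record it.
- An all-SNPs-flagged outlier set raises `degenerate_outlier_set` rather
  than returning an estimate from nothing.

## Known limitations

No proxy-variant search for instruments missing from the outcome GWAS; no
LD estimation from genotypes (r² is consumed, not computed); no
MVMR-Egger/median variants; no stochastic model search beyond K = 20; the
bidirectional runner requires the outcome GWAS to have its own
genome-wide-significant instruments, and reports a structured skip when it
does not. Secondary-trait (pleiotropy-annotation) lookups are accepted as
user-supplied trait lists rather than queried from external services.
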