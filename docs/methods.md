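# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic world used for testing, and the
numerical and design choices that were genuinely open.

## 1. Confound removal and standardization (`hcdn.deconfound`)

Each regional grey-matter volume is replaced by its ordinary-least-squares
residual on a confound design containing body mass index, head size, two
head-motion summaries, head position (x, y, z), scanner-table position,
acquisition site (one-hot, first level dropped, global intercept kept), and
the derived terms age, age², sex, sex·age, sex·age². Residuals are exactly
orthogonal to every confound column and the operation is idempotent.
Missing rows are dropped listwise with a logged count; a rank-deficient
design falls back to minimum-norm least squares with a warning.

Standardization z-scores each column using the **population (n-denominator)
standard deviation**. This convention is fixed throughout the package
(deconfounding, CCA, Spearman ranks, the latent-axes matrix); sample-SD
would rescale every downstream quantity by √(n/(n−1)) without changing any
test decision.

## 2. Canonical correlation analysis (`hcdn.cca`)

Classical CCA via SVD of the whitened cross-covariance
`Σxx^{-1/2} Σxy Σyy^{-1/2}`. Whitening uses an eigendecomposition-based
inverse square root; when a within-set covariance is near-singular
(minimum eigenvalue below 1e-10 of the maximum) a ridge
`ε = 1e-8 · trace/p` is added and logged. In the intended regime
(n ≫ p + q) the ridge is inert.

Canonical vectors are normalized so each training variate has unit
variance, and a deterministic sign convention is applied: per mode, the
pair `(v_l, u_l)` is flipped jointly so the largest-|entry| of the DN
vector `v_l` is positive. The convention has no statistical content; it
makes refits byte-reproducible. Default retained mode count is k = 25
(configurable); the synthetic demos use k = 3.

Estimation note: in-sample canonical correlations carry an upward
overfitting bias of order (p+q)/n. At n = 2,000 with p + q = 129 this is
≈ +0.06; at n = 20,000 it is within the suite's ±0.03 recovery tolerance.

## 3. Bootstrap group-divergence test (`hcdn.divergence`)

Per bootstrap iteration (default B = 100), each family-history group is
resampled with replacement **at its own size** and a separate CCA is fit
per group (2B fits total). Each refit is matched to a full-sample reference
model by mode rank order (descending canonical correlation) and joint sign
flips against the reference vectors; optional greedy matching by maximal
|correlation| is available (`match_by_correlation=True`) for worlds where
canonical correlations nearly tie and rank matching can pair
non-corresponding modes. Differences of canonical-vector entries
(with-history − without) are pooled over iterations, and a region is a
**hit** for a mode when the [10th, 90th] percentile interval (linear
interpolation) excludes zero. This is an 80% interval: the nominal
null exclusion rate is 20%, which must be kept in mind when reading hit
counts.

**Calibration domain.** The percentile logic is calibrated when each
group's CCA refit is in its asymptotic regime (group size ≫ p + q).
Monte Carlo on the generator: with an 8+6-region atlas and group sizes of
~1,275/3,725 (ratio ≈ 90 subjects per region) the null exclusion rate
averages 0.200 across worlds. With the full 91+38 atlas at n = 5,000
(ratio ≈ 10) the per-group bootstrap refits are attenuated — the bootstrap
difference distribution centers at ≈ 0.7× the observed difference — and
the observed exclusion rate drops to ≈ 0.09: the test becomes conservative.
Cohorts of the reference scale (n ≈ 37,000) are comfortably inside the
calibrated regime. The acceptance suite deliberately runs the
miscalibrated desk-scale configuration as specified and the corresponding
check is expected to fail; the small-atlas calibration test is the
supporting evidence that the implementation, rather than the regime, is
sound.

**Detectability of planted hits.** A loading perturbation δ on a region
translates into a canonical-vector-entry shift of roughly 0.3·δ (dampened
by renormalization of the group's canonical vector, and saturating for
large δ because the perturbed direction dominates the mode). With
per-entry bootstrap SDs of ≈ 0.09 at n = 5,000, perturbations δ ≳ 0.8
(about five times a typical orthonormal loading entry, 1/√38 ≈ 0.16) are
reliably detected (sensitivity ≈ 1); the generator's default
`hit_delta = 0.3` is a moderate, partially detectable effect.

## 4. APOE dosage phenome scan (`hcdn.phewas`)

The bivariate dosage scale scores a genotype as (#ε2 − #ε4):
ε2/2 → +2, ε2/3 → +1, ε3/3 and ε2/4 → 0, ε3/4 → −1, ε4/4 → −2. Per sex and
mode, dosage is regressed on the mode's (DN, HC) variate pair with
intercept ("stacking"); subjects at or beyond the 5th/95th percentiles of
the fitted dosage (linear-interpolation quantiles, ≈10% of subjects) are
selected, and each phenotype is Pearson-correlated with the predicted
dosage among them. The scan correlates phenotypes with the *predicted*
dosage — the quantity the stacking step produces — rather than the raw
dosage. Missing phenotype values are handled pairwise-complete; columns
with fewer than 3 complete pairs or zero variance are skipped and logged.
Multiple testing: Bonferroni at α/m per signature and Benjamini–Hochberg
FDR at q = 0.05 per signature; the Bonferroni-significant set is forced to
be a subset of the FDR set. The male-vs-female comparison table
(`sex_difference_table`) is a display utility with no new statistics.

## 5. Genotype-masked risk clustering (`hcdn.clustering`)

The z-scored canonical variates are multiplied by a one-hot genotype
indicator (non-carriers zeroed **and retained**), then Spearman-correlated
with the z-scored risk factors. Spearman is computed as Pearson on
mid-rank-transformed columns; the zeroed non-carriers form one massive tie
handled by mid-ranks — statistically odd, but a faithful reproduction of
the masking design (a carriers-only subset is available behind
`carriers_only=True`). Risk-factor rows are clustered with Ward's
minimum-variance linkage (scipy; merge heights follow scipy's
√(2·ΔESS) convention, verified against a direct within-cluster
sum-of-squares oracle in the tests). "Three levels of branching" cuts the
last three merges from the root, giving at most four clusters. Cluster
models from different genotypes are compared by Pearson-correlating their
merge-height sequences by step; because both sequences are monotone
non-decreasing, even unrelated trees correlate highly — the comparison is
informative only near the top of its scale and is reported as such.

## 6. Brain × genotype interaction models (`hcdn.interactions`)

Per sex, an outcome (risk factor: linear; family-history label: logistic)
is regressed on one canonical variate, the six genotype indicators (no
global intercept, so each genotype coefficient is that group's adjusted
baseline), six genotype×variate interactions, and age — 14 coefficients.

**Identifiability.** The genotype indicators partition the subjects, so the
six interaction columns sum exactly to the variate column: the 14-column
design is structurally rank 13. Linear fits use minimum-norm least squares
and logistic fits IRLS with pseudo-inverse steps, both deterministic.
Genotype main effects, the age effect and every per-genotype **total
slope** (variate + interaction coefficient) are uniquely identified; only
the split between the variate main effect and the interaction set is
convention-dependent. Recovery tests therefore assert identifiable
contrasts (e.g. exp(b[ε4/4] − b[ε3/3]) for an odds ratio). Rank
deficiency beyond the structural one — a genotype absent from a sex
subset — is an error naming the offending columns.

**Permutation masking.** The outcome is shuffled across subjects B times
(default 1,000; design fixed; sex-stratified models shuffle within the
subset), the model refit, and each coefficient assigned the add-one
two-tailed empirical p-value `(1 + #{|b*| ≥ |b|}) / (1 + B)`; coefficients
with p ≤ 0.05 are retained, the rest are masked. For the linear family the
B refits are computed as one matrix product with the design pseudo-inverse
— algebraically identical to B separate OLS fits and ~1000× faster.

## 7. Latent brain–behaviour axes (`hcdn.latent`)

`M` (risk factors × stacked DN/HC variates; 63 × 50 at reference
dimensions) holds Pearson correlations. Its **columns** are z-scored (the
pooled-z alternative is behind `zscore="pooled"`), then `M = U S Vᵀ`; the
top three components give projections `U·S`, weights `V`, and
explained-variance fractions `s²/Σs²` (summing to 1 over all components).
Per component, the sign is fixed so the largest-|entry| of the weight
vector is positive. Reliability: per bootstrap iteration, either resample
all n subjects and split into two halves of ⌊n/2⌋ (split-half), or
resample each sex at its own size (by-sex); agreement per component is the
|Pearson r| between the two solutions' weight vectors (sign-aligned).
A sex-stratified run should exclude the grouping variable from the
risk-factor list (62 instead of 63 columns); the module takes the list as
given.

## 8. External projection (`hcdn.projection`)

External volumes — deconfounded with the external cohort's own confound
model — are standardized with the **external** cohort's means/SDs (the
reference cohort's statistics behind `use_reference_stats=True`) and
multiplied by the reference canonical vectors. Repeated visits are treated
as independent rows. Phenotype correlations with the projected variates
are screened by permuting phenotype rows B times (default 1,000) and
retaining coefficients with add-one permutation p ≤ 0.05, the same rule as
the interaction masking. Under a null phenotype panel the retained
fraction is ≤ 5% plus Monte-Carlo error.

## 9. The synthetic world (`hcdn.synth`)

The generator emulates the statistical structure the analyses assume, not
the imaging data behind it:

- latent scores `Z` i.i.d. standard normal (n × k); loadings `A` (p × k)
  and `B` (q × k) QR-orthonormalized Gaussian matrices;
- `X = Z·diag(s)·Aᵀ + E`, isotropic Gaussian noise, with per-mode signal
  scales solved analytically from the planted canonical correlations:
  `ρ = s²/(s² + σ²)` ⇒ `s² = σ²·ρ/(1−ρ)`;
- family-history subjects use perturbed loadings `A + δ`, `B + δ` on
  configured hit regions;
- genotypes drawn from the reference population frequencies
  (ε3/3 59.3%, ε3/4 23.1%, ε2/3 12.4%, ε2/4 2.4%, ε4/4 2.2%, ε2/2 0.6%);
  family history drawn **after** genotype and sex with per-genotype/sex
  odds ratios on a 25.5% baseline prevalence (defaults encode the
  reported approximate effects, e.g. ε4/4 OR 1.56 in males and 1.86 in
  females, ε2/2 OR 0.5 in females), so the odds ratios hold exactly in the
  design;
- linear confound contamination with known coefficients, so that
  residualization can be verified against ground truth;
- phenotype tables (977 columns at full width) that are pure noise except
  for configured `slope·latent + noise` links, optionally in one sex only;
  a 63-column risk-factor table in three correlated blocks (social,
  cardiovascular, personality) sharing block factors tied to the leading
  latent modes.

`oracle_canonical_correlations` computes the population canonical
correlations from the analytic joint covariance via an independent
whiten-and-SVD route (pseudo-inverse square roots cover the noiseless
singular case) and never calls the sample solver.

**What a green test does not establish.** The generator has no spatial
structure, no segmentation noise, no heteroscedastic regions, no missing
data beyond what tests inject, no population stratification and no
genotype–confound correlation. Green recovery tests show the estimators
find the structure they assume; they do not validate the biological claims
on real cohorts.

## 10. Numerical conventions and degenerate inputs

- Quantiles/percentiles everywhere: linear interpolation (numpy default).
- Permutation p-values: add-one (Phipson–Smyth) correction; p = 0 cannot
  occur.
- Zero-variance volume columns: error naming the region (deconfound, CCA);
  zero-variance phenotypes: skipped with a logged reason (scans).
- Bootstrap resamples with a zero-variance region are redrawn and logged.
- Seeds: a single global seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence`; identical (config, seed) reproduces every
  artifact byte for byte.
- Ward ties: scipy's deterministic behavior; real-valued random inputs
  make exact ties measure-zero.

## 11. Known limitations

- The divergence test is conservative below roughly 30–50 subjects per
  region in the smaller group (see §3); hit counts from small cohorts
  understate divergence.
- Mode matching by rank order can pair non-corresponding modes when
  canonical correlations tie within sampling error; correlation-based
  matching is provided but changes the estimand slightly.
- The 14-parameter interaction model's variate/interaction split is
  identified only by the minimum-norm convention (§6); compare total
  slopes, not raw interaction coefficients, across software.
- The phenome scan's tail selection conditions on the fitted stacking
  model; its p-values are descriptive, as in the original design, and the
  permutation masks elsewhere carry the same descriptive caveat.
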