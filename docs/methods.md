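# Methods

## The analysis model

The package treats longitudinal response assessment as three linked
problems: (i) turning each daily CT's tumor ROI into a small panel of
texture statistics, (ii) expressing every biomarker — imaging or serum — as
a *relative net change from its own baseline* so that patients with very
different absolute scales can be pooled, and (iii) asking, with models that
respect the repeated-measures structure, whether those changes track
pathological response and survival.

### Texture features

All matrix features operate on a fixed-bin-count quantization: in-mask
intensities are binned into L = 32 equal-width levels over the in-mask
[min, max] (the maximum maps to level L; a constant ROI maps to level 1).
Fixed bin *count* (rather than fixed bin width) makes every quantized
feature exactly invariant to affine intensity rescaling, which the test
suite asserts. L = 32 is the common radiomics default; it is configurable
and recorded in the extraction sidecar, because no single value is
canonical.

* **GLCM**: voxel pairs at distance 1 along the 13 unique 3D directions,
  counted symmetrically, summed over directions, normalized. Features:
  entropy (−Σ p log₂ p), contrast (Σ (i−j)² p), cluster tendency
  (Σ (i+j−μᵢ−μⱼ)² p), inverse variance (Σ_{i≠j} p/(i−j)²), information
  measure of correlation 1 ((HXY − HXY1)/max(HX, HY)), and inverse
  difference normalized (Σ p/(1+|i−j|/L)). "Information measure" is
  ambiguous in the radiomics literature (IMC1 vs IMC2); IMC1 was chosen and
  the choice is logged in the output metadata.
* **NGTDM**: 26-neighborhood with the neighborhood mean computed over
  in-mask neighbors only (voxels with no in-mask neighbor are excluded from
  the valid count). Coarseness = 1/(ε + Σ pᵢ sᵢ) with ε = 1e-6 capping the
  constant-ROI reciprocal at 10⁶; complexity uses the standard
  occupied-level double sum.
* **GLRLM**: maximal same-level runs along the same 13 directions;
  direction-specific matrices are averaged into one matrix before the
  gray-level non-uniformity statistic is computed (matching how the GLCM is
  direction-averaged).
* **First order**: mean, skewness and kurtosis on the *raw* (unquantized)
  in-mask intensities. Kurtosis is the Pearson (non-excess) form — a normal
  sample gives ≈ 3 — because excess/non-excess confusion is the most common
  source of irreproducible radiomics values; the convention is written into
  the extraction sidecar. Zero-variance ROIs yield NaN (propagated as
  missing, never zero).
* **NESTD** ("normalized entropy to standard deviation difference"): for
  each in-mask voxel, the entropy of the quantized levels in its 3×3×3
  in-mask neighborhood normalized by log₂ L, minus the population SD of the
  raw neighborhood intensities normalized by the full ROI range; the
  feature is the ROI mean, and the per-voxel map can be exported. Only the
  one-phrase definition of this feature is public; the neighborhood radius
  (1) and range normalization are this package's documented choices.

Every matrix feature is verified against an independently coded naive-loop
implementation to 1e-12 relative tolerance on randomized volumes. No
resampling to isotropic voxels is performed by default (typical daily-CT
voxels are 0.98×0.98×3 mm and the analysis compares a patient against
themselves), but spacing travels with every volume.

### The delta transform

For feature value F at fraction n, change is (F₁ − Fₙ)/F₁ (n = 2..28);
CA19-9 uses the same formula against the pre-treatment blood draw
("fraction 0"). Decline from baseline is therefore *positive* for both
families, so later stages never need per-biomarker orientation. Records
with a zero or missing baseline are skipped with a logged reason, never
imputed. Weeks are ceil(fraction/5): a 28-fraction course gives weeks 1–6,
week 6 = fractions 26–28 plus any sample within two days after the course.
Weekly summaries pool all fraction-level values from all patients in the
week (boxplot convention: median and linearly interpolated quartiles).

### Feature selection

Redundancy is removed greedily on |Spearman r_s| > 0.9, visiting features
in descending variance (the tie-break rule is deterministic and logged;
which member of a redundant pair a given study kept is unknowable, so the
package picks the higher-variance representative). The association screen
requires *both*:

* a two-sided Welch t-test on pooled fraction-level changes, and
* a likelihood-ratio χ²(1) test of the Response fixed effect in
  `DRF ~ Response + (1|Patient) + (1|Fraction)` with crossed random
  intercepts, fitted by ML (REML likelihoods are not comparable across
  fixed-effect structures).

The two tests are deliberately complementary: the pooled t-test is
anticonservative when observations are clustered within patients (measured
type-I ≈ 0.13 at ICC ≈ 0.08 with 10 fractions/patient), while the LME
accounts for both patient and fraction intercepts. Requiring both is the
guard against the pooled test's optimism. Calibration is verified by
simulation: each test holds 0.05 ± 0.02 under its own null (the LME
measures ≈ 0.06 with 24 patients — ML likelihood-ratio tests are mildly
liberal with few clusters).

The LME is fitted in-package: with θ = (σ²ₚ/σ²ₑ, σ²_f/σ²ₑ), β and σ²ₑ have
closed-form GLS/profile solutions, leaving a smooth 2-D likelihood surface
optimized by a coarse log-grid plus Nelder–Mead polish. For balanced
designs the covariance is diagonal in the {grand mean, patient-mean space,
fraction-mean space, remainder} split, making each evaluation O(1); the
general path uses the Woodbury identity on the low-rank random-effect
structure. The optimum matches statsmodels' MixedLM log-likelihood to
~1e-5 where the latter converges (asserted in the tests); the in-package
fitter exists because the general-purpose optimizer fails to converge on
near-null variance components and is ~30× slower, which matters for
simulation-based calibration. No multiple-testing correction is applied
across features by default (an optional Benjamini–Hochberg switch exists);
with 13–73 features and the both-tests rule the expected false-selection
count is small, and the default mirrors common practice in small-cohort
radiomics screens — users running wide screens should enable BH.

### Response model and detection weeks

The headline model is logistic regression of response on z-standardized
predictors (each selected texture change summarized as its mean over the
last observed week; CA19-9 as the latest available change), always with a
tiny L2 penalty (λ = 1e-4 per observation on the standardized scale) so
the fit stays defined under perfect separation; separation is detected
(all cases scoring above all controls) and flagged. The concordance index
uses 0.5 credit for ties and is reported *in-sample*, as is conventional
for pilot-size cohorts: adding even a pure-noise predictor cannot lower
it, so it measures association, not generalization. A clearly labelled
leave-one-out variant is available.

Weekly detection uses a *label-free* combined biomarker: within each week,
each biomarker's per-patient change is z-scored across patients and the
z-scores averaged. (A refit model score per week was rejected: with ~24
patients an in-sample logistic score separates even random labels, making
the weekly between-group test wildly anticonservative.) Detection week is
the start of *sustained* significance — the earliest week from which every
subsequent tested week has Welch-t p < α — matching the notion that
significance "begins" at a week; a literal first-p<α mode is available but
is vulnerable to isolated type-I hits in early weeks.

### Survival

Kaplan–Meier curves compare patients whose final normalized CA19-9 change
is ≥ 0 ("decreasing or normalized") vs < 0 ("increasing"); the median is
the first time the curve reaches 0.5 and 5-year survival is the step
function read at 60 months. Cox models use Efron tie handling (lifelines),
Wald CIs on the log-HR, and a Newton precision of 1e-11 (the 1e-7 default
leaves the estimate ~1e-5 short of the partial-likelihood optimum, visible
against a brute-force oracle). Covariates are z-standardized and
benefit-oriented, so protective effects give HR < 1. For multi-covariate
rows of the prognostic ladder, the reported HR is per 1 SD of the model's
combined benefit score — exp(−SD(linear predictor)) — which makes rows
with different covariate counts comparable and makes "the combined model
is more protective" a monotone, testable statement. A monotone likelihood
triggers a ridge-stabilized refit, flagged in the output.

## The synthetic cohort: what it emulates, what it does not

Defaults state one plausible world and are not estimates of any clinical
population:

| parameter | default | rationale |
|---|---|---|
| patients / fractions | 24 / 28 | two equal response groups, daily imaging |
| texture drift | −2.5%/fraction (good), +1.5% (bad), patient SD 0.025 | disorder roughly halves over a responding course; groups overlap |
| CA19-9 baseline | lognormal, median 100 U/mL, log-SD 1 | serum CA19-9 spans orders of magnitude |
| CA19-9 trend | ×0.90/week (good), ×1.10/week (bad), log-trend SD 0.2/week | decline ↔ response; heterogeneity keeps single-marker AUC ≈ 0.75 |
| CA19-9 noise | 30% CV, unit-mean lognormal | combined assay + biological variability |
| sampling | fractions {0, 9, 18, 28} | baseline, sparse mid-course, final week |
| survival | exponential, median 40 mo, HR 0.7 per unit change, 30% censoring | protective decline; realistic follow-up loss |

Texture is a correlated Gaussian random field posterized to L_f
equiprobable gray values; drift acts multiplicatively on L_f, so the
direction of the GLCM-entropy trend is analytically known — that is the
handle the generator-oracle tests use. Each patient consumes an RNG stream
derived from (master seed, patient index, purpose), so cohorts extend
without reshuffling and identical configs are byte-identical.

Not emulated: CT physics and reconstruction noise, anatomy and deformable
motion, stent artifacts, registration error, contouring variability,
non-tumor CA19-9 elevation (biliary obstruction), non-exponential hazards.
A green test therefore establishes that the *pipeline recovers what the
generator put in* — correctness and calibration — not that the clinical
effect sizes are as stated.

Separate trajectory-level generators (`simulate_lme_dataset`,
`simulate_weekly_biomarkers`) draw directly from the statistical models the
selection and detection stages assume; they exist because calibration
studies need thousands of replicates and image synthesis would add runtime
without adding information.

## Numerical choices

* Quantization assigns the in-mask maximum to level L; constant ROI → level 1.
* GLCM entropy uses log₂ and 0·log 0 = 0; degenerate single-level matrices
  return 0 for contrast, inverse variance and IMC1 rather than raising.
* NESTD box sums are accumulated per offset with integer level counts and a
  two-pass variance, keeping the vectorized path within 1e-12 of a literal
  sliding-window loop (a one-pass E[x²]−E[x]² formulation does not survive
  that comparison).
* JSON reports round floats to 12 significant digits: BLAS threading inside
  scikit-learn produces last-bit jitter that would otherwise break
  byte-identical same-seed re-runs.
* Volumes are written as uncompressed `.nii` — gzip embeds timestamps,
  which breaks byte-level reproducibility. NIfTI is the only supported
  image format (nibabel); NRRD is not available in the target environment.
* KM median of an all-censored group is undefined (inf/NaN), reported as
  such; censoring-free KM medians follow the product-limit convention
  (smallest observed time with Ŝ ≤ 0.5), which for even n is the upper of
  the two middle order statistics.

## Known limitations

* The exact numeric feature values of any given clinical study are not
  reproducible by construction: discretization level, GLCM distance and
  NESTD neighborhood are unreported in the literature this panel follows;
  all are configurable and logged.
* In-sample concordance overstates predictive value at n = 24; the
  leave-one-out option gives an honest but high-variance alternative.
* The pooled weekly t-tests treat within-patient values as exchangeable
  within a week; with one value per patient per week (the CA19-9 case) this
  is exact, with daily values it is an approximation the detection
  simulations quantify.
* The Cox ladder refits overlapping covariate sets without correction for
  model multiplicity, mirroring exploratory prognostic tables.
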