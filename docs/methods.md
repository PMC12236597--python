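# Methods

This note documents the models, the numerical choices, and the design
decisions behind `stemgrowth`, and states what the synthetic-data experiments
do and do not demonstrate.

## Growth phenotype

**QC cascade.** The order is fixed — informative-well filter, shape-outlier
removal, replicate-concordance filter, logistic fit, residual filter — and
each stage only removes wells, never edits values.

- *Informative wells*: ≥ 3 coverage measurements in [30, 70]% (inclusive
  boundaries; the permissive reading of "between 30–70%", configurable).
  This guarantees the exponential-to-saturation transition is observed.
- *Shape outliers*: pointwise directional outlyingness of each well is its
  deviation from its own donor's median curve standardized by a per-timepoint
  robust scale (normalized MAD) pooled across donors. A handful of replicates
  cannot estimate a stable per-donor MAD, which is why the scale is pooled;
  the centering stays donor-specific so that between-donor growth-rate
  differences are not mistaken for outlyingness. Each well's mean (MO) and
  variance (VO) of outlyingness — the magnitude and shape channels — are
  screened by robust Mahalanobis distance (minimum covariance determinant)
  against an F cutoff at tail level α = 0.007 (the conventional MS-plot
  level). MCD distances are stochastically larger than the classical law, so
  the distance distribution is anchored at the χ²₂ median before applying
  the F tail quantile. Comparison groups with fewer than 5 wells are skipped.
- *Concordance*: times are rounded to the nearest day, pairs aligned on
  shared days (≥ 3 required, else the pair is uninformative and ignored), and
  Pearson r computed on complete aligned observations. The default removal
  rule is greedy: while any same-donor pair has r < 0.75, drop the well in
  the most violating pairs (ties: lower mean r, then well id). This makes a
  single rogue well among concordant replicates the sole casualty. A
  `strict` mode drops, in one simultaneous pass, every well with any
  violating pair — the literal reading of "exclude any well with r < 0.75
  against any replicate"; both behaviors are tested.
- *Logistic fit*: per-well min–max normalization to [0, 1], then bounded
  nonlinear least squares for `N(t) = K/(1 + ((K−n0)/n0)e^{−rt})` from three
  starts (data-driven K = max, n0 = first positive value, r from the
  steepest growth segment, plus two perturbations); bounds K ∈ (0, 2],
  n0 ∈ (1e−6, K), r ∈ (1e−4, 20], tolerances 1e−10, ≤ 500 evaluations.
  Times are shifted so each well's clock starts at 0; alignment rounding is
  used only for QC, fits use raw times.
- *Residual filter*: fits with RSS above mean + 3·SD of the batch (global
  statistics over all converged fits, not per donor) are dropped, as are
  non-converged fits.
- *gAUC*: closed form `[K t + (K/r) ln(1 + c e^{−rt})]` over the well's own
  observation window (a common horizon is configurable; a log warning fires
  when windows differ by more than 20%, since unequal windows bias
  cross-well comparison). Evaluated with `logaddexp` for stability at large
  `rt`.
- *Donor summary*: mean gAUC across retained wells, then a rank-based
  inverse normal transform with Blom offset (c = 3/8), average ranks for
  ties.

**ICC(1,1).** One-way random-effects ANOVA for single measurements with the
unbalanced-design effective group size `k0 = (N − Σn_i²/N)/(g − 1)`;
`ICC = (MSB − MSW)/(MSB + (k0 − 1) MSW)`, F = MSB/MSW on (g−1, N−g) df.

## Genotype QC, relatedness, ancestry

- HWE exact p by enumeration over heterozygote counts conditional on the
  allele counts, in log space; two-sided by summing configurations no more
  probable than the observed one. Monomorphic sites return p = 1.
- Variant filters: MAF (> 0.05 common panel, < 0.1 rare-panel mode), HWE
  p > 1e−10, missingness ≤ 5%; an imputation-quality filter applies only
  when an r² vector is supplied. Hard calls for counting estimators come
  from nearest-integer rounding of dosages (no uncertainty model).
- LD pruning: 1 kb windows sliding by 0.8·window (the printed step size is
  dimensionless and < 1, so it is read as a window fraction); within a
  window the higher-r² pair loses its lower-MAF member (tie: larger
  position) until all retained pairs have r² < 0.1. An optional BED of
  excluded high-LD regions is honored when provided.
- KING-robust kinship `φ̂ = (N_het,het − 2 N_opp-hom)/(N_het(i) + N_het(j))`
  over jointly-called variants; pairs with φ̂ > 0.354 (the duplicate /
  monozygotic-twin threshold) are collapsed keeping the sample with less
  missingness, ties by sample id. Pairs with no heterozygotes are logged and
  treated as unrelated.
- GRM over variants with MAF > 0.1 (in-sample frequencies; mean imputation
  of missing dosages). In-sample centering forces each GRM row to sum to
  zero, so the off-diagonal mean is exactly −diag/(n−1); tests account for
  this finite-sample identity.
- Ancestry: plain projection of target samples onto reference PCA loadings
  (same standardization as the reference) and nearest group centroid over
  the first 30 PCs. No shrinkage adjustment of the projections is applied;
  with strongly separated groups the plain projection assigns correctly,
  which is all the synthetic experiments claim.

## Variance components and association

- **REML.** With `K = UΛUᵀ`, the restricted likelihood is profiled over
  h² ∈ [1e−6, 1−1e−6] using `d_i = h²λ_i + (1−h²)`; the total variance and
  GLS fixed effects are closed-form at each h², leaving a 1-D bounded Brent
  search (tol 1e−8). The h² standard error comes from the numerical
  curvature of the profile. Boundary hits and a non-identifiable K (numerically
  constant eigenvalues, e.g. K = I) are flagged; an exactly-deterministic y
  (zero residual) collapses to the degenerate flag with h² = 0. Negative
  variance estimates are precluded by the boundary parameterization.
- **Null-model cache.** The fitted object stores the whitening transform
  `W = U diag(v)^{−1/2}` and the QR of the whitened design, so any score
  quantity `xᵀPy`, `xᵀPx` is two matrix products — no per-variant refit
  (two-step score testing).
- **Covariate scan.** Line attributes are tested against per-well gAUC with
  a donor random intercept (the same engine with K = ZZᵀ), by
  likelihood-ratio tests of ML fits (χ², df = levels − 1) and BH control at
  FDR 5%. LRTs replace the Satterthwaite t-tests of the usual mixed-model
  software: fully specified here, asymptotically equivalent; in the
  zero-donor-variance limit the LRT p agrees with one-way ANOVA (tested).
  Quantitative covariates (e.g. pluripotency marker TPMs) enter as ordinary
  design columns.
- **Common variants.** `T = (xᵀPy)²/(xᵀPx) ~ χ²₁` with mean-imputed
  dosages used as-is; variants fully projected out by covariates
  (`xᵀPx ≤ 1e−12`) get p = 1 and a flag. Tier labels use the conventional
  5×10⁻⁸ (genome-wide) and 10⁻⁶ (nominal) thresholds.
- **Rare variants.** Qualifying = pLoF (any score) or missense with
  phred-scaled deleteriousness ≥ 20 (25 in sensitivity mode), MAF < 0.01;
  genes need ≥ 2 qualifying variants and a non-zero burden in ≥ 1% of
  samples. Weights are the Beta(1, 25) density in MAF (the standard
  rare-variant upweighting; a flat-weight mode reduces burdens to minor
  allele counts). The hybrid test computes the burden score test, then
  orthogonalizes the per-variant scores and kernel against the burden
  direction; the adjusted SKAT p comes from the eigenvalues of the residual
  kernel via the modified 4-moment match by default (deterministic and
  dependency-light), with Imhof characteristic-function inversion behind
  `method="davies"`; a single-eigenvalue kernel is evaluated exactly. The
  two p-values are Fisher-combined (χ², 4 df). Degenerate kernels (single
  variant or one shared carrier pattern) return the burden p directly, which
  makes the single-variant contract exact. Bonferroni thresholds are
  α / n_genes.

## Differential expression

Median-of-ratios size factors; per-gene NB GLM (log link, size-factor
offset) by IRLS with a fixed dispersion; Wald test on the phenotype
coefficient; BH q-values. Dispersion is a per-gene moment estimate
(floored at 1e−8) gated on Dean's score test for overdispersion at the 1%
level: with no evidence of extra-Poisson variation the moment estimate is
pure noise and the Poisson limit is used, which makes the scan match a
Poisson GLM in the dispersion→0 limit. There is no trend or shrinkage across
genes — a deliberate, documented fidelity gap relative to shrinkage-based DE
machinery.

Three stages: (1) scan with the inverse-normalized gAUC plus covariates;
(2) control genes = stage-1 raw p > 0.25 (≥ 20 required), factor = leading
right singular vector(s) of the centered log(size-factor-normalized
counts + 1) control submatrix, k = 1 by default ("a factor"), configurable;
(3) refit with the factor appended.

**Known limitation.** When the unwanted factor is correlated with the
phenotype, empirical-control factor estimation is structurally unable to
recover the correlated component: controls are selected precisely for small
realized association with the phenotype, so the estimated factor is
approximately orthogonalized against it. In simulations with a factor at
ρ = 0.3 to the phenotype, stage 3 consistently reduces the false-discovery
proportion relative to stage 1 (by roughly a third) but does not restore the
nominal level. Passing the orthogonal-confounding and global-null
experiments therefore shows calibration and benefit, not full immunity to
signal-correlated batch structure.

## Power

HWE group frequencies (p², 2pq, q²), group means (0, δ₁, δ₁+δ₂),
noncentrality `λ = n Σ f_g (μ_g − μ̄)²/σ²`, exact noncentral-F power with
df = (2, n−3) (no χ² approximation), central-F fallback at λ = 0 (scipy's
noncentral F is unreliable there). Sample size by doubling + bisection on
the analytic power. A scalar effect size expands to the symmetric additive
case (δ, δ). The defaults σ = 0.4584 and α = 5×10⁻⁸ mirror a
genome-wide-threshold design; published sample-size figures that depend on
effect sizes estimated from restricted data are not reproduced.

## Synthetic cohort generator

The generator inverts the analysis models and is the package's test bed:

- *Cohort*: 0/1-coded attributes at fixed frequencies (male 46.2%,
  mTeSR 57.6% — the cohort scale it emulates; starting cell type and
  reprogramming method balanced, as no frequencies are published). Twin
  pairs share a `twin_group` and identical genotype rows.
- *Genotypes*: HWE binomial dosages; common MAF ~ U(0.05, 0.5), rare
  generating MAF < 0.01 (realized in-sample MAFs scatter around these).
  Rare variants are assigned round-robin to genes; consequences from a
  0.15/0.65/0.20 pLoF/missense/other mixture, deleteriousness scores
  U(0, 40).
- *Phenotype*: y = covariate shifts + polygenic + rare-burden + noise. The
  polygenic part (standardized dosages × N(0,1) effects) is empirically
  rescaled to sample variance exactly h², the noise to 1 − h², so the
  realized polygenic fraction matches the target by construction — simpler
  and exact in-sample compared with per-variant variance formulas.
- *Wells*: donor rate `r_d = r0 exp(s·z(y_d))` (r0 = 0.45/day, s = 0.12 —
  keeps rates positive, monotone in the latent value, and leaves ≥ 3 daily
  points inside [30, 70]% over the default 16-day window), logistic curves
  with K = 95%, n0 = 4%, Gaussian coverage noise (SD 2 percentage points,
  chosen to put replicate ICC in the high-concordance regime), clipped to
  [0, 100]. Artifacts: magnitude outliers (+20 points), time-warp outliers
  (1.8× compressed time axis) — the two MS-plot channels — and discordant
  wells (reversed trajectories).
- *Counts*: NB with log-mean = baseline + b_g·z(y) + w_g·u; u is the
  unwanted factor, optionally correlated with z at a configurable ρ; a
  truth table (DE flags, loadings) is returned for calibration experiments.
- Each sub-simulator draws from its own RNG stream spawned from the master
  seed, so resizing one component does not shift another's draws; all
  outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: plate-layout spatial effects,
imputation dosage uncertainty, population structure beyond optional
group-shifted allele frequencies, LD between variants, and realistic
RNA-seq library composition. Passing tests on this cohort demonstrates the
estimators' correctness under their stated models, not robustness to those
real-data features.

## Experiment problem sizes

The validation battery (`stemgrowth.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) uses: 25 replicate
cohorts of 400 donors × 1,000 SNPs for h² recovery; 500 donors with 2,000
null variants for score-test calibration; three replicates of 500 simulated
genes (≈ 1,300 tested) for hybrid-test calibration; 60 donors × 8 wells
with 8% outlier and 4% discordant wells for artifact detection; 400
groups for the ICC regime; 20,000 Monte-Carlo replicates per grid point for
ANOVA power; and 150–200 donors with 400–1,000 genes for the DE
experiments. These sizes give each empirical rate a standard error well
inside its assertion band while keeping the whole battery to a few minutes.
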