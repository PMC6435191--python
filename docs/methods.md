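# Methods

`ewaskit` implements a desk-scale differential DNA-methylation analysis for a
two-group cohort design — an exposed group (institutional care, "IC") and a
comparison group (biological family care, "BFC") — together with a synthetic
cohort generator that provides ground truth for every stage. This note
records the models, the defaults and why, and what the synthetic experiments
do and do not demonstrate.

## The analysis model

**Probe QC.** A probe is removed if (i) its detection p-value exceeds .05 in
any sample or any beta is missing, then (ii) it lies on chrX/chrY, then
(iii) it overlaps a polymorphism with minor allele frequency ≥ .05. Removals
are counted once, in the first class hit, so the cascade counts conserve the
input (`n_retained = n_input − Σ removals`). The any-sample detection rule is
the strictest reading of the usual practice; a maximum failing-sample
fraction is configurable.

**Normalization.** Between-sample quantile normalization within probe
strata: each sample's sorted values inside a stratum are replaced by the
stratum-wide mean quantile vector; tied input values receive the mean of the
target quantiles they span. The default stratification is two strata by
genic-region class (promoter-like = TSS200/TSS1500/5'UTR/1stExon vs. other),
a desk-scale mirror of region-stratified array normalization; a single
stratum is available.

**Cell-type deconvolution.** Whole-blood betas are modeled as
`m ≈ R w` with `R` a six-leukocyte reference (CD4T, CD8T, Bcell, NK, Mono,
Gran) restricted to cell-type discriminating probes (per type, the k probes
maximizing |value − mean of others|). Per sample, `w` solves nonnegative
least squares with a penalty row (weight 1000) pulling `Σw` to 1, then is
renormalized exactly. CD4/CD8 ratios are per-sample ratios; samples with a
CD8 fraction below 0.005 get a flagged, undefined ratio.

**Moderated t and the empirical-Bayes prior.** Per-probe pooled variances
`s²` are modeled as `s² ~ s0² F(df, d0)`. The prior `(d0, s0²)` is a
method-of-moments fit matching the mean and variance of `log s²` via
digamma/trigamma inversion; when the spread of log variances does not exceed
chi-square sampling noise, `d0 = ∞`. The posterior variance is
`s̃² = (d0 s0² + df s²)/(d0 + df)` and the statistic
`t = Δmean / (s̃ √(1/n₁ + 1/n₂))` is referred to a t distribution with
`d0 + df` degrees of freedom (normal limit for infinite `d0`). The
implementation reproduces the reference R implementation (limma
`lmFit`/`eBayes`) to machine precision on finite-`d0` fixtures; this is
asserted in the test suite via `Rscript`.

**The DMES cascade.** Probes are called differentially methylated when they
pass, in order: Benjamini–Hochberg adjusted p < .05; signed beta fold change
|FC| ≥ 1.2, where `FC = m₁/m₂` if `m₁ ≥ m₂` else `−m₂/m₁` (hyper/hypo in the
exposed group by the sign of the mean difference); and a cell-composition
elimination filter — OLS of the candidate's beta on five fraction predictors
(granulocyte dropped to break the simplex collinearity) plus intercept, with
removal when the overall regression F-test has p < .05. The test operates on
beta values because the effect-size gate is defined on the beta scale. The
per-coefficient variant of the cell filter and an M-value test mode are
deliberately out of scope of the default path.

**Residualization.** Behavior raw domain scores are regressed on age at
assessment, (centered) age², and gender; candidate-probe betas on age at
blood draw and gender. Outputs are standardized residuals (mean 0, SD 1,
ddof = 1), exactly orthogonal to each covariate. The quadratic-for-behavior
vs. linear-for-methylation asymmetry is intentional and preserved. Age is
centered before squaring only to reduce collinearity; residuals are
unchanged by centering.

**Deviation analysis.** For each exposed-group child, `D_VABS` is the
Euclidean distance of the four-domain behavior Z-profile from the comparison
group's mean ("normative") profile; `D_EPI` the same for the DMES
methylation z-profile. Distances are rescaled into [0, 1] by the cohort
maximum (default) or a theoretical maximum (`√p`, suited to unit-bounded
data). Because Pearson correlations are invariant to positive rescaling,
every reported r and R² is independent of the scaling rule; the rule is
presentation only, and this invariance is asserted exactly in the tests.
The "institutionalized at birth" subcohort is age-at-placement ≤ 1 month
(configurable).

## The synthetic cohort generator

The generator emulates the structure of a 29 + 29 blood-methylation study of
infants/toddlers:

- **Mixtures.** Per-sample fractions are Dirichlet draws with group-specific
  means (IC: .241/.127/.142/.037/.058/.395; BFC: .282/.126/.186/.039/.050/.317)
  and concentration 30, back-solved once from the published per-type SDs
  (`m(1−m)/(c+1) ≈ SD²` gives c ≈ 18–65 across types). Clean betas are
  `R w`; the reference has six 0.9-vs-0.1 discriminating blocks plus a
  bimodal baseline with 0.02 cross-type jitter.
- **Planted differential CpGs.** 60 probes with a mean beta shift of 0.08,
  half hyper- and half hypomethylated in the exposed group, planted at
  low-methylated probes (reference mean in [0.12, 0.32]) so the ±1.2
  fold-change gate is attainable — matching the observation that group
  differences concentrate at lowly methylated sites. The per-sample effect
  pattern is **orthogonalized against the realized fraction matrix**: the
  ground truth represents condition-driven, cell-composition-independent
  signal — precisely the class of effect the composition filter is designed
  to leave untouched. Without this choice a constant group shift partially
  projects onto the (group-different) fractions and the conservative filter
  removes roughly a third of true effects, which is a property of the
  filter, not of the caller. `composition_orthogonal=False` restores the
  confounded variant for studying exactly that behaviour.
- **Duration coupling.** Exposed-sample effect magnitudes scale with
  standardized institutionalization duration (`1 + 0.5 z(duration)`,
  clipped, re-centered to mean 1), so longer exposure yields larger
  epigenetic deviation.
- **Demographics.** A random 5% of probes get a linear age slope
  (~0.004/month) and/or a gender offset (~0.03); ages are ~N(20.4, 6.9)
  months clipped to [8, 35]; female fractions 9/29 (IC) and 11/29 (BFC);
  ~52% of exposed children are placed at birth, the rest later, with
  duration = age − age at placement.
- **Noise.** Gaussian on logit(beta), then inverse-logit and clipping to
  [1e-6, 1−1e-6], giving bounded betas with heteroscedastic beta-scale
  spread. The default SD of 0.35 reproduces a realistic total
  between-subject spread (beta-scale SD ≈ 0.05 at mid-low methylation). The
  DMES recovery experiment uses 0.05, the near-noiseless measurement-error
  regime under which the recovery calibration is defined.
- **Behavior scores.** Four domain raw scores = intercept + age slope +
  coupling × (sign-aligned mean z of the planted CpGs) + N(0, 6), floored at
  0; the sign alignment makes the exposed group's planted methylation states
  the "disadvantageous" ones. Four comparison-group children lack behavior
  scores by default, mirroring interview refusals. Detection failures hit a
  2e-4 fraction of (probe, sample) cells (≈1% of probes under the any-sample
  rule at n = 58); ~3% of probes are placed on sex chromosomes and ~1.5%
  get a common SNP. Planted and discriminating probes are kept autosomal,
  SNP-free and detection-clean so the ground truth survives QC.

All randomness flows from one integer seed through a single generator;
identical designs produce byte-identical fixture files.

**What the generator does not emulate:** probe-type chemistry (Infinium
I/II), spatial/batch effects, realistic per-probe variance heterogeneity
beyond the logit-noise heteroscedasticity, linkage between neighboring CpGs,
and any genome-scale probe count (desk scale is 2k–20k probes). Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated mixture-plus-noise model, not performance on real
arrays.

## Numerical choices

- Trigamma inversion by Newton iteration (relative tolerance 1e-10);
  nonpositive sample variances floored at 1e-12 with a warning.
- NNLS sum-penalty weight 1000 (√penalty row); reference rank checked on the
  selected probes with an error advising a larger k.
- Fold change floors zero means at 1e-6 with a warning; |FC| ≥ 1 always.
- Quantile-normalization ties get the mean of the spanned target quantiles;
  strata with fewer than two probes pass through with a warning.
- Constant responses: the cell filter skips them; residualization returns
  flagged all-zero output; correlations return NaN with a flag.
- Two-sided p-values throughout; BH is the only multiple-testing procedure.

## Problem sizes in the recovery experiments

DMES recovery runs at 5,000 probes, 60 planted effects, n = 29 + 29 (the
study's dimensions at desk-scale probe count); null calibration at 2,000
probes over 50 seeded replicates; deconvolution recovery at 900 probes / 58
samples with logit noise 0.02; the empirical-Bayes prior recovery at 5,000
variances with 56 residual df; deviation-analysis calibration at n = 29 with
1,000 (null R²) and 100 (duration-coupling sign) replicates. These sizes
make the whole acceptance computation run in seconds while keeping every
binomial acceptance band meaningful.

## Known limitations and open choices

- Published tables print the label "Welch's t-test" while their footnote
  (df = 52 = 29 + 25 − 2) implies the pooled form; the pooled form
  reproduces the printed values and both forms are exposed. One published
  demographic chi-square ("0.999") is not reproducible from the printed
  counts under either reading; the direct Pearson value (0.305) is the one
  computed here.
- Which age (blood draw vs. assessment, mean gap 1.3 months) enters each
  adjustment is a convention: assessment age for behavior, draw age for
  methylation.
- The MANOVA design for cell-composition group tests is exposed as a
  generic Pillai's-trace test for one term; published F values for it are
  not reproduction targets.
- Expected beta-z fidelity after demographic adjustment is r ≈ 0.98, not
  higher: with two covariates and n = 58, chance fit alone removes
  E[R²] ≈ 2/57 of variance.
- `D_VABS` weights all four domains equally; no weighting option is offered.
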