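# Methods

`magicgxe` implements a complete analysis chain for genotype-by-environment
(G×E) interaction in a multiparent (MAGIC) doubled-haploid population grown
in replicated multi-environment trials, together with a synthetic-data
generator that provides ground truth for every estimator. This note
describes the models, the estimation choices, and what the simulations do
and do not establish.

## Synthetic populations and trials

**Founder panel and mosaics.** Founder haplotypes are biallelic indicator
vectors at mapped markers (defaults: 16 founders, chromosomes of 150 Mb at
an assumed 1 cM/Mb, polymorphism enforced at every marker). Doubled-haploid
(DH) genomes are Markov mosaics of founder blocks: block lengths are
exponential with a user-set mean (default 30 cM), successive founders
differ, and founder choice is uniform. This is deliberately *not* an
explicit multi-generation funnel pedigree: downstream methods consume only
genotypes and founder probabilities, and the block-length scale is the one
property that matters for LD structure. The realized block-length
distribution of a real MAGIC population is not claimed to be exponential;
the scale is a user parameter. Founder probabilities are one-hot for the
true mosaic and can be blurred with a Dirichlet draw concentrated on the
true founder (expected mass (c+1)/(c+16) at concentration c) to emulate
imputation uncertainty.

**Trials.** A trial places each line's plots (default 2 per environment)
on a rectangular grid in serpentine order. Plot values sum an environment
mean, environment-specific QTL founder effects, a polygenic main effect, a
polygenic line-by-environment effect, a smooth field surface, and i.i.d.
residuals. The field surface is a sum of random Gaussian bumps, centered to
mean zero over the grid (so it cannot alias the environment mean) and
scaled to the requested variance. Polygenic effects come in two modes:
`markers` (weighted sums of centered genotypes, covarying with the genomic
relationship matrix — realistic, and restrictable to chosen chromosomes)
and `iid` (exchangeable line effects — exactly the assumption of the
variance-component model). Marker-backed draws on a finite genome are
weakly correlated between terms because they live in the genotype matrix's
column space; recovery tests that audit an exact variance decomposition
therefore use `iid` mode, while GWAS fixtures use `markers`. Random draws whose variance *is* the quantity under
study — iid polygenic effects and the environment deviations — are
standardized to the exact requested sample variance (ddof = 1): with only
five environment levels, the realized variance of unstandardized draws
fluctuates several-fold, and recovery checks would measure that draw
noise rather than estimator behaviour. With
`multitrait` effects, line-level trait vectors are drawn per environment
with covariance G and plot residuals with covariance R, giving known
ground truth for the G-matrix machinery. Default study dimensions follow a
maize MAGIC design: 16 founders, ~300 lines, 5 environments, 2 plots per
line, with optional per-environment withheld-line sets emulating realistic
missingness. Traits are unitless.

## Kinship

VanRaden genomic relationships: K = M M′ / (2 Σ p_j(1−p_j)), with the
allele-count matrix (DH lines coded {0, 2}) column-centered at 2p_j and
p_j the sample allele frequency. Markers can first be thinned by a greedy
windowed LD prune (window in kb, step in markers, r² threshold; the later
marker of an offending pair is dropped; monomorphic markers are removed
up front). Leave-one-chromosome-out (LOCO) kinship recomputes K without
the tested chromosome, re-filtering markers monomorphic within the subset.
A ridge of 1e-8 is added to the diagonal before any factorization. The
exact tie-breaking of other pruning tools is not reproduced bit-for-bit;
the greedy rule is specified and tested against an independent all-pairs
re-implementation.

## Variance components (univariate, plot level)

The model is y = 1μ + Z_G u_G + Z_E u_E + Z_{E:G} u_{E:G} + f_E(x,y) + e
with independent effects within each factor (identity covariance — kinship
is intentionally not used here), a tensor-product cubic B-spline surface
nested within environment sharing a single variance (default 6×6 marginal
knots), and i.i.d. residuals. The line-by-environment incidence contains
only observed combinations; missing trait values are dropped listwise with
logged counts. The environment factor can instead be fit as fixed
(`env_fixed=True`).

Estimation is average-information (AI) REML with an EM fallback and step
halving, so the restricted likelihood is non-decreasing across accepted
steps (relative tolerance 1e-8). All quantities are computed in the
mixed-model-equations parameterization; the largest random block whose
incidence has a diagonal Gram matrix (normally line-by-environment) is
absorbed analytically, which reduces a fit with 300 lines × 5 environments
× 2 plots to sub-second factorizations of a few-hundred-dimensional
system. Standard errors come from the inverse AI matrix. Components
converging to a negligible share of the total (< 1e-3) are reported as
exactly 0 (boundary). Variance proportions divide each component by the
included total; the default excludes the spline from the denominator and
includes everything else, and the output records which components were
included. The spline coefficient variance is a penalty-scale parameter and
is not comparable to the generative surface variance, which is why
recovery checks assert on the four named components only.

## G×E genome scans

Markers are founder-probability blocks: X_m is the n × 16 matrix of
probabilities that each observation's line inherited each founder at
marker m. Three models are scanned:

1. **deviation** — two contrasting environments, w = ±1; fixed effects
   (μ, wα, X_m β_m, w∘X_m β_{E:m}); H0: β_{E:m} = 0.
2. **plasticity** — all environments; w is each environment's mean
   phenotype (computed once from unpermuted data and held fixed) and the
   per-environment means enter as fixed dummies; the tested block is
   w∘X_m. Equal environment means make this design collinear and raise an
   explicit error.
3. **Finlay–Wilkinson** — two-stage: each line's environment means are
   regressed on the all-line environment means of an index trait
   (environment quality; slopes defined for lines seen in ≥ 2
   environments), then the slope vector is scanned line-level with
   s = X_m β_s + u_s + e, u_s ∼ K. The single-stage slope-in-model variant
   is not implemented.

Random terms for models 1–2: u_G1 ∼ K (LOCO per tested chromosome),
u_{E:G1} ∼ K through the w-scaled incidence, u_G2 ∼ I (nonadditive,
switchable), and i.i.d. error. Because founder probabilities sum to one
(collinear with the intercept), fixed effects are estimated by
minimum-norm least squares after Cholesky whitening — no arbitrary
reference founder — and the Wald chi-square uses the rank of the tested
block after projection on the preceding columns (typically 15), with the
error variance estimated with a degrees-of-freedom-corrected denominator.
Variance ratios are selected by maximum likelihood on a grid over variance
proportions (default step 0.1): per marker (`mode="grid"`), or once at the
no-marker null fit (`mode="null"`, the fast EMMAX-like choice used
throughout the test suite), or fixed explicitly (`mode={"ratios": ...}`,
the hook for oracle comparisons).

**Permutation thresholds.** Family-wise significance is the level-q
quantile (inverted CDF) of genome-wide minimum p-values over phenotype
permutations — lines within environment for models 1–2, the slope vector
for model 3. Each permutation re-runs the scan *including* the ratio
refit; freezing the observed whitening makes permuted p-values grossly
inflated, because permutation changes the dependence structure. Whitened
per-marker bases are cached per grid cell, so 100 permutations cost little
more than the original scan.

**Calibration caveat (replicated plots).** When lines have replicate plots
and a polygenic background, permuting line groups within environments
produces per-environment line-block covariance that the model family
(K-structured and whole-line i.i.d. terms) cannot represent; thresholds
are then conservative. Calibration is therefore assessed in designs with
one plot per line per environment, where plot-level exchangeability is
exact; null-uniformity checks draw the polygenic background from
N(0, σ²K) so that held-out tested markers are true nulls. Power fixtures
use genome-backed effects. This distinction matters for interpreting the
tests: they establish calibration under the model's own assumptions, not
under arbitrary misspecification.

**Founder representation.** Expected carriers (probability sums) and hard
carriers (probability > 0.8) are reported per marker × founder; founders
below a configurable support level flag the marker
(`low_founder_support`), the diagnostic for artifactual peaks driven by a
founder carried by essentially one line.

## Per-environment G-matrices (multivariate, Bayesian)

Within one environment, Y = Z U + f(x,y) + E with vec(U) ∼ N(0, G ⊗ I_r)
and vec(E) ∼ N(0, R ⊗ I_n). Traits are first mean-scaled (divided by the
grand mean across all environments, then centered — globally by default,
per environment by flag) so genetic variances are unitless mean-scaled
evolvabilities; a `--no-scale` path reproduces analyses on raw traits. The
scaling record allows exact inversion. A condition-number check on the
phenotypic correlation matrix (warn above 1e3) catches derived traits that
would destabilize the fit; rows missing any trait are dropped
complete-case.

The sampler is conditionally conjugate Gibbs. G and R carry the
hierarchical inverse-Wishart prior of Huang & Wand (2013): conditional on
per-trait inverse-gamma scales, the covariance is inverse-Wishart, and the
implied marginal on each standard deviation is exactly half-t(ν, A_k)
(ν = 3, A_k = the trait's observed phenotypic SD; verified against the
analytic half-t CDF by sampling the prior with no data). This is a fully
specified stand-in for a separation-strategy prior with half-t standard
deviations and an LKJ correlation prior; the correlation margins differ
(near-uniform but not exactly LKJ(1)), which is accepted and noted.
The spline variance has the same half-t construction. Updates: line
effects in closed form (vectorized over lines grouped by replicate count),
spline coefficients jointly across traits, covariances by inverse-Wishart,
auxiliary scales by inverse-gamma. Chains are seeded independently from
the user seed and pooled post burn-in with labels (defaults 4 × 1500+3500,
matching the intended analysis scale; recovery tests run reduced budgets
of 2 × (200–300 burn-in, 400–700 draws), which the tests show suffice for
posterior medians and 95% intervals at r = 150–300 lines). Draws failing a
Cholesky check are resampled and counted (none observed in practice —
inverse-Wishart draws are PSD by construction).

Diagnostics are rank-normalized split-chain R̂ and bulk effective sample
size per SD/correlation parameter (ArviZ), with a warning above R̂ = 1.01
and for single-chain runs. Correlation differences between environments
are computed draw-wise on matched (seeded subsampled) posteriors, with the
2.5–97.5% interval, an exclusion-of-zero significance flag, and the
fraction of draws with positive covariance in each environment (the
covariance sign-switch diagnostic).

## Covariance-tensor eigenanalysis

The m per-environment G-matrices are vectorized with the
Frobenius-isometric weighting (off-diagonals × √2, row-major upper
triangle), and their v × v sample covariance S (divisor m − 1; the divisor
cancels in variance fractions) is eigen-decomposed. Eigenvectors map back
to orthonormal eigentensors (sign: largest-magnitude element positive;
ties broken by sort order; eigenvalues below 1e-10 × λ₁ are zero). At most
m − 1 eigenvalues are nonzero — an algebraic property of a centered
m-point covariance, which is why five environments yield exactly four
eigentensors regardless of estimation noise. Environment coordinates are
Frobenius inner products with the eigentensors; element contributions are
the absolute eigentensor entries normalized to a maximum of one.

**Uncertainty** projects matched posterior draws of the m G-matrices onto
the *fixed* observed eigentensors (variance along each axis over the trace
of the draw-set covariance), keeping coordinates attached to stable axes;
re-deriving axes per draw is available behind `refit_axes=True`.

**Significance** comes from shuffling environment labels over
line-by-environment records (lines keep identities, per-environment counts
preserved; shuffles leaving an environment with too few distinct lines are
redrawn), refitting the G-matrix posteriors per pseudo-environment, and
building per-draw tensors on both the real and the shuffled side. The
statistic is the variance explained per ranked eigentensor (the
eigenvalue): shuffling homogenizes the matrices, so genuine environmental
structure collapses the null eigenvalues, while normalized fractions alone
are scale-free and nearly powerless. Using posterior *draws* on both sides
matches the MCMC noise of the two distributions; comparing observed draws
against null point estimates is anticonservative. An eigentensor is
flagged when the 5% quantile of its observed variance-explained exceeds
the 95% quantile of the null (conservative overlap rule). Power to flag a
doubled genetic variance grows with line number (posterior noise in each
G scales as 1/√r while the between-environment signal does not); the power
demonstration uses 600 lines, the false-positive check 60.

## Numerical and design notes

- One integer seed per public operation; internal streams derive from
  (seed, label) pairs via `SeedSequence`, so every fixture is
  bit-reproducible and independent across labels.
- Whitened-space rank decisions use a cutoff relative to the
  *pre-projection* scale of a block, so blocks annihilated by projection
  (fully collinear markers) cleanly report zero degrees of freedom instead
  of round-off directions.
- Degenerate inputs: monomorphic-only genotype panels, single-chromosome
  LOCO requests, zero grand means in mean-scaling, equal environment means
  in the plasticity design, and single-matrix tensors all raise explicit
  errors; markers with rank-zero tested blocks record a missing p-value
  with a reason flag.
- Problem sizes in the test suite (150–600 lines, 30–120 markers, reduced
  MCMC budgets, 10-shuffle nulls) were chosen as the smallest scales at
  which each scientific property is clearly resolved by the corresponding
  statistics; the library defaults remain at the full analysis scale.

## Limitations

- The mosaic generator approximates MAGIC ancestry with a Markov process;
  funnel-specific features (unequal founder contributions along the
  pedigree, interference) are not emulated.
- Passing calibration under model-consistent backgrounds does not certify
  behaviour under real-data misspecification (spatial trends interacting
  with genotype placement, heteroscedastic environments).
- The permutation-threshold machinery holds environment means (model 2)
  and variance-ratio *grids* fixed; only the ratio selection is refit per
  permutation.
- The G-matrix sampler mixes slowly for strongly collinear traits; the
  collinearity check warns but does not reparameterize.
- Weather-derived covariates, growing-degree-day computation, and
  haplotype-level follow-up of association peaks are out of scope.
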