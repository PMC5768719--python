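# Methods

## The model

gsmrkit estimates the causal effect `b_xy` of an exposure `x` on an outcome
`y` from two sets of GWAS summary statistics, using genome-wide-significant
SNPs as instrumental variables.  For instrument `i` with effects `b_zx(i)`
(on `x`, SD units) and `b_zy(i)` (on `y`, logOR for diseases), the ratio

    b_xy(i) = b_zy(i) / b_zx(i)

estimates the same causal effect for every valid instrument.  The vector of
ratios is treated as multivariate normal around `1·b_xy` with covariance `V`:

* diagonal (delta method):
  `var(b_xy(i)) = b_xy(i)^2 [var(b_zx)/b_zx^2 + var(b_zy)/b_zy^2 − var(b_zx)^2/b_zx^4]`,
  computed internally in the algebraically identical form
  `var = se_zy^2/b_zx^2 + b_xy^2 (se_zx^2/b_zx^2 − se_zx^4/b_zx^4)` so that
  `b_zy = 0` is handled (the equality of the two forms is unit-tested);
* off-diagonal: the same delta-method expansion with the LD correlation `r`
  between the two SNPs, estimated from a reference genotype panel;
  at `i = j`, `r = 1` it reduces to the diagonal exactly (property-tested).

Generalized least squares then gives

    b_xy_hat = (1'V⁻¹1)⁻¹ 1'V⁻¹ b_xy ,   var(b_xy_hat) = (1'V⁻¹1)⁻¹ ,

tested against zero with `T = b_xy_hat²/var ~ χ²(1)`.  The solve is a
Cholesky linear solve; a condition number of `V` above 1e8 aborts with the
most correlated instrument pairs named (the cutoff is our operationalization
of "non-invertible"; no published threshold exists).  True `b_xy(i)` values
inside `V` are replaced by their per-SNP estimates — the only quantities
computable from summary data; this plug-in is an acknowledged approximation.

Because a logOR is unaffected by case over-sampling, the estimator applies
unchanged to case-control outcome GWAS, and `exp(b_xy_hat)` reads as an odds
ratio per SD of the exposure.

## Instrument selection

Instruments are chosen from the exposure side only: SNPs at `p < 5e-8`
thinned by greedy P-value-ranked clumping (`r² ≥ 0.05` within ±1 Mb removed;
PLINK window convention, ties in p broken by position then ID).  A minimum
of 10 near-independent instruments is enforced as an overridable guard —
it is a rule of thumb, not a hard requirement.  The outcome never informs
selection.

## HEIDI-outlier

Under the causal model all ratios share one expectation, so a pleiotropic
instrument shows up as an outlier.  The test statistic for instrument `i`
against a target SNP is

    d_i = b_xy(i) − b_xy(target),
    var(d_i) = var(b_xy(i)) + var(b_xy(target)) − 2 cov(·,·),
    T = d_i²/var(d_i) ~ χ²(1),

with the covariance from the same structural formula as `V`'s off-diagonal.
The target is the SNP with the strongest exposure association within the
third quintile of the ratio distribution — strong for power, central to
avoid picking an extreme pleiotropic outlier as the reference.  The quintile
band is operationalized as 1-based ranks in `(0.4m, 0.6m]`; when no integer
rank falls there (small `m`) the median rank is used; ties in exposure
p-value break by distance from the median ratio, then ID.  SNPs with
`p < 0.01` are removed in a single pass (iteration available behind a flag);
filtering is pure subset selection and never alters stored effects.
Instruments with numerically non-positive `var(d)` are conservatively
retained and reported as indeterminate.

Calibration note: with the target's own sampling variance included in
`var(d)` and the target conditioned into the central quintile, the test is
mildly conservative.  In our simulations the null removal rate at the 0.01
threshold is ~0.4–0.7% rather than the nominal ~1%; with a fixed,
noise-free target the rate is nominal (verified by Monte Carlo), so the
conservatism is attributable to the published target-selection rule, not to
the variance formula.

Power note: the filter reliably removes large pleiotropic effects (≥ ~10
outcome SEs; >95% detection in our tests).  Moderate direct effects — big
enough to bias, too small to flag — pass through and inflate the causal
test; this intermediate regime is a real limitation of single-pass
per-SNP outlier removal.  Likewise, when a majority of instruments is
contaminated (e.g. pleiotropic loci spreading through LD blocks covering
most of the instrument set) the central-quintile target itself can be
pleiotropic and the method breaks down; the validation scenarios keep
contamination a minority, which is also the regime the method claims.

## mtCOJO

The conditional analysis replaces each target-trait SNP effect by

    b_adj = b_zy − b_zx' b_xy ,

where `b_xy` are the joint effects of the covariate traits' genetic values
on the target, converted from GSMR's marginal estimates by
`b_xy = D^{−1/2} R_x^{−1} D^{1/2} β_xy` with `D = diag(h²_SNP)` and `R_x`
the genetic-correlation matrix.  The sampling variance is

    var(b_adj) = var(b_zy) + b_xy' V_zx b_xy − 2 b_xy' cov(b_zy, b_zx),

with between-trait sampling covariances `c·se_a·se_b`, `c` the bivariate
LD-score-regression intercept (the product of sample-overlap fraction and
phenotypic correlation).  No overlap gives the `+` special case; full
same-sample overlap the `−` case.  `h²`, `r_g` and the intercepts are
configuration inputs (YAML) — estimating them is out of scope.  SNPs absent
from any covariate dataset are skipped, not zero-imputed.  The derivation
assumes covariates in SD units; a heuristic warns when covariate betas look
unstandardized, and another warns at `|r_g| > 0.9` (over-correction risk —
excluding near-duplicate covariates is the caller's job).

## Synthetic data

The generator emulates the statistical structure of two-sample MR:

* **Genotypes** — Hardy-Weinberg allele counts; LD blocks are compound-
  symmetric, built from two latent-Gaussian gametes whose correlation is
  tetrachorically calibrated so the *realized allele-count* correlation hits
  the target; one MAF per block (drawn from Uniform(0.05, 0.5)), blocks
  independent.
* **Effect sizes** — per-instrument explained variance
  `per_snp_h2 × LogNormal(−0.5, 1)` (unit mean), the heavy-tailed shape of
  real GWAS hits; default `per_snp_h2 = 0.001`, so the reference scenario
  (m = 50) has instruments explaining 5% of the exposure in total.
* **Phenotypes** — `x = Z b_zx + e` at unit variance; quantitative
  `y = b_xy·x + Z d + e`; binary `y` from a logistic model on the same
  linear predictor with the intercept solved to hit the target prevalence
  (default 10%), so the `b_xy ≈ logOR` interpretation is exact in design;
  a liability-threshold variant is available for sensitivity analysis.
  Reverse causation is supported by solving the simultaneous system.
  Exposure and outcome samples are disjoint individual sets (default
  50,000 each).
* **Summary statistics** — either per-SNP regression scans on the simulated
  individuals, or a fast path drawing effect estimates from their asymptotic
  distribution `N(b_marginal, S R S)` with `S = diag(1/sqrt(2p(1−p)n))`,
  exposure and outcome independent.  Marginal effects are `R`-weighted
  combinations of the joint effects, so per-SNP ratios remain `b_xy` under
  LD.
* **Instrument definition in experiments** — `selection="estimated"`
  thresholds the sampled exposure p-values (the applied workflow; subject to
  winner's curse near the threshold), `selection="true"` thresholds the
  noise-free effects (the validation design that isolates estimator bias).

What the generator does **not** model: realistic recombination maps or
allele-frequency spectra, population stratification, assortative mating,
imputation noise, and cryptic sample overlap between the two GWAS.  Passing
tests therefore demonstrate the estimators' statistical behaviour under the
stated sampling model, not robustness to those real-data pathologies.

## Numerical and validation choices

* z-standardization: `b = z/sqrt(2p(1−p)(n+z²))`, `se = 1/sqrt(·)`, so
  `b/se` reproduces `z` to 1e−10 (property-tested).
* Harmonization: outcome effects are re-signed onto the exposure's effect
  allele, trying direct and complementary-strand matches; palindromic
  (A/T, C/G) SNPs are aligned by allele frequency when informative
  (MAF ≤ 0.4) and dropped otherwise (retainable by flag); a post-alignment
  frequency gap > 0.2 warns of strand errors.  These conventions are ours —
  conservative community practice, no published prescription exists.
* Type-I error of the GLS test at α = 0.05 is verified over 2,000
  direct-sampling replicates (binomial 3σ band).
* Parameter recovery is asserted as `|mean − truth| ≤ 3·MCSE + 5%·|truth|`:
  the ratio-GLS estimator carries a second-order downward bias of order
  `1/z²` (weights ∝ b̂_zx² act like regression dilution; ~3% at the default
  instrument strength, shrinking as instruments strengthen), so exact
  mean-equality is not attainable at finite instrument strength and the 5%
  term is that documented error scale.
* The binary-outcome check compares the GSMR estimate with a correctly
  specified logistic regression of disease on exposure in the outcome
  sample (m = 30 instruments, n = 15,000 per sample) within two combined
  standard errors.
* Simulation scales: validation suites run at m = 40–60 instruments and
  n = 50,000 per sample with replicate counts of 80–2,000 chosen so each
  check's Monte-Carlo error is small against its tolerance.

## Known limitations

* The weak-instrument deflation above is not corrected; the genome-wide
  significance threshold is the only guard, as in the method's standard formulation.
* Single-pass HEIDI misses moderate pleiotropic effects and cannot rescue
  majority-contaminated instrument sets (see above).
* mtCOJO accuracy depends entirely on externally supplied `h²`, `r_g` and
  overlap intercepts; errors there propagate undetected.
* The LD reference is assumed to match the GWAS populations; mismatched
  panels bias `V` and the HEIDI covariances.
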