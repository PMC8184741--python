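# Methods

This note documents the models, numerical choices, and defaults behind
`emscore`, and what the synthetic experiments do and do not demonstrate.

## The classification task and the score

Candidate *cis* variant–gene pairs (±1 Mb around the TSS) are labeled from
two fine-mapping posteriors: **positive** when both PIPs exceed 0.9,
**negative** when both fall below 10⁻⁴, otherwise unlabeled and excluded
from training. The classifier is a scikit-learn random forest. Training
uses all positives plus an equal-size seeded random sample of negatives;
the labeled sets this method produces are overwhelmingly negative, and
balancing stabilizes the forest without affecting the calibrated output
(prevalence is restored at calibration time). Feature selection keeps the
top-k columns (default k = 152, capped at the number of columns) by
mean-decrease-of-impurity from a preliminary forest, ties broken
lexicographically by name. Hyperparameter search, when a budget above 1 is
given, is a random search over tree count, depth, leaf size and feature
subsampling followed by a small grid around the winner, scored by AUROC on
a stratified validation split; budget 1 fits a fixed default
(100 trees, unlimited depth, √p features).

**Calibration.** Raw scores on a held-out labeled split are cut into 20
quantile bins; adjacent bins with fewer than 50 labeled pairs are merged.
Per bin, the positive fraction f is rescaled from the held-out prevalence
π_t to the genome-wide base rate π by prior odds:

    EMS = (f·π/π_t) / (f·π/π_t + (1−f)·(1−π)/(1−π_t)),

then made monotone non-decreasing in raw score by pooling adjacent
violators (weighted by bin count). π defaults to
#positives / #all pairs in the input and is overridable. The simpler
reading EMS = f is available via `rescale=False`. When π = π_t the two
coincide exactly.

**Leave-one-chromosome-out.** A model with a held-out chromosome is
trained *and calibrated* entirely on the other chromosomes (the
calibration split is an inner stratified 25% of the training labels), so a
held-out chromosome's scores never depend on its own pairs. The holdout is
recorded in the model metadata.

**Episomal-assay mode.** `score_pairs(..., fixed_tss_bp=200)` overrides
the distance feature with a constant before scoring, for comparisons
against reporter-assay data where constructs place every variant at a
typical short promoter distance.

**Prior-ratio adjustment.** `adjust_prior_ratio` floors weights at
max/100 (ratio configurable). A floor rather than a ceiling preserves the
top of the prior, which is where the information lives; the operation is
idempotent and order-preserving on untouched weights.

## The sum-of-single-effects fitter

The bundled fitter implements iterative Bayesian stepwise selection for
the model y = Zb + ε, b = Σₗ bₗ, ‖bₗ‖₀ = 1, with genotype columns
standardized and the phenotype centered internally. Per sweep and per
effect, the effect's contribution is removed from the fit, the
single-effect Bayesian regression is computed against the residual
(Gaussian Bayes factors per variant; α ∝ prior weight × BF), and the
fitted value is restored. Numerical choices:

- **Prior effect variance**: estimated per effect each sweep by maximizing
  the single-effect marginal likelihood over a fixed grid of
  {0, 10⁻⁴, 10⁻³, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1} × var(y). A zero
  estimate marks a *null effect*: its α reverts to the prior weights and it
  is excluded from PIP computation. Without this, unused effects
  contribute a flat α of 1/m to every variant and floor all PIPs at
  roughly L/m, destroying the confident-negative stratum.
- **Residual variance**: re-estimated each sweep from the expected
  residual sum of squares under the mean-field posterior.
- **Convergence**: change in the evidence lower bound below 10⁻⁶, up to
  200 sweeps; non-convergence flags the result rather than raising.
- **Credible sets**: per effect, the shortest prefix of variants sorted by
  descending α (ties by ascending variant id) reaching 95% cumulative
  mass. Purity is the minimum pairwise |r| over members, computed on the
  sample genotype correlation of the analyzed cohort (no external LD
  panel); a set is pure at min |r| ≥ 0.5, singletons are pure with
  min |r| = 1.
- **Reweighting**: pure effects only, α̂ₗ ∝ w·αₗ renormalized; an
  all-zero weighted mass leaves the row unchanged and flags it. Variants
  without a score receive the 5th percentile of the supplied weights by
  default, so unscored variants are down- but not zero-weighted. Purity is
  decided on the uniform-prior sets; reweighted credible sets are then
  recomputed, but the original purity decision governs eligibility (the
  reweighting step is defined on the uniform-prior fit).

The L = 1 fitter with fixed hyperparameters reduces exactly to the
exhaustive single-causal Bayes computation, which the test suite exploits
as an independent oracle.

## Enrichment, colocalization, tissue specificity

Enrichment of a set in a score bin is P(set | bin) / P(set); its standard
error is the binomial SE of the numerator proportion divided by the
denominator, treating the denominator as fixed (its error is negligible
when the candidate catalog is large). Percentile bins default to deciles
with a finer top bin at the 99th percentile; right-closed, ties share a
bin. Downsampling keeps every set row and samples non-set rows without
replacement to an exact total (default 100,000), deterministically per
seed.

CLPP for a gene is the maximum of eQTL PIP × trait PIP over tissues and
the variants of the unresolved trait credible set; a gene is prioritized
at CLPP > 0.1 when it holds the *strict* maximum in its region (a tie
prioritizes nothing — the conservative choice where the rule is silent).
Region construction mirrors the evaluation design: 1 Mb windows centered
on credible sets with no coding variant above trait PIP 0.1, kept only
when they contain an evaluation gene (coding variant with trait PIP >
0.5); coding flags are input columns.

A TF is tissue-specific when its TPM in one tissue is the unique maximum
and exceeds the across-tissue mean by more than two standard deviations
(sample sd, ddof = 1; the candidate tissue is included in the mean and sd,
the more conservative reading). Controls are tissues below a tenth of the
maximum; calls without controls are dropped. The feature-enrichment test
is a two-sided Welch t test (unequal variances are the norm across tissue
groups), Bonferroni-corrected over the number of features tested.

## The synthetic-data generator

Genotypes are drawn per LD block from a Gaussian copula with constant
within-block latent correlation ρ, thresholded at the allele-frequency
quantile twice per individual to give Hardy–Weinberg dosages in {0, 1, 2}.
Variants within a block share a base MAF with ±20–25% jitter — tightly
linked variants arise from shared ancestry, and without shared MAFs the
dosage correlation is attenuated far below ρ. Blocks are independent.
Expression is standardized-genotype effects plus Gaussian noise; every
variant is independently causal with a configurable probability. Feature
structure: causal pairs' TSS distances follow a two-sided exponential
(default scale 20 kb) against a uniform ±1 Mb background; binary
annotations fire 10× more often in causal pairs (base rate 5%); continuous
scores are a standardized causal indicator scaled by an informativeness
parameter plus unit Gaussian noise, with one pure-noise column. A
complex-trait phenotype can share the causal variants of a subset of genes
for colocalization tests. All randomness descends from a single integer
seed through `numpy.random.Generator.spawn`.

What the generator does *not* emulate: realistic allele-frequency spectra,
recombination maps, population structure, correlated features across
columns, allele-aware regulatory scores, or the ascertainment biases of
real fine-mapped training sets. Tests passing on this generator therefore
demonstrate the correctness and internal consistency of the machinery —
calibration, reweighting arithmetic, ranking behaviour — not performance
on real cohort data.

## The recovery benchmark

The end-to-end benchmark simulates 300 genes × 200 variants (ρ = 0.9
blocks of 10, n = 400, causal probability 0.1 per variant, effect sd 0.5
against unit noise), fine-maps each gene with L = 10 under the uniform
prior, labels pairs from the resulting PIPs (the bundled fitter supplies
both PIP columns; a second independent fine-mapper is out of scope),
trains and calibrates EMS leave-one-chromosome-out across 10 synthetic
chromosomes, reweights the pure effects, and compares the two posteriors.
Across seeds, the functionally informed posterior calls at least as many
true causal variants at PIP > 0.9, keeps the empirical FDR of those calls
at or below 0.1, and does not widen the median pure credible set. The
problem size was chosen to exercise the full pipeline at meaningful power
while completing in about a minute per seed on one CPU; the demo pipeline
uses a smaller default (40 genes × 100 variants) for interactive use.

## Known limitations

- The fitter targets the standardized-genotype, scalar-phenotype case; no
  summary-statistic mode and no covariate adjustment (residualize first).
- Calibration quality depends on the held-out labeled split being
  representative; with very few labeled pairs the bin-merge rule can leave
  a single bin, collapsing EMS to a near-constant.
- The prevalence rescaling assumes labels are missing at random given the
  bin, which ascertainment in real fine-mapping data violates to an
  unknown degree.
- `nearby_pairs` is a quadratic helper intended for the small sets of
  tissue-specific eQTLs, not genome-scale interval joins.
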