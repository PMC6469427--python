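# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `polygs`, in the order data flows through the package.

## Synthetic populations (`polygs.simulate`)

**What is emulated.** A recurrent-selection cycle of an autotetraploid
perennial crop: `n_founders` parents (default 146) crossed in
`n_crosses` distinct biparental families (default 124) of
`progeny_per_cross` offspring (default 15, ≈1,860 progeny), genotyped by
per-entry sequencing reads and phenotyped over `n_years` field seasons
(default 2). Defaults mirror those study conditions; tests and
benchmarks scale the counts down and say so where they do.

**Inheritance.** Founder dosages at each marker are Binomial(4, q) with
marker frequencies drawn Uniform(0.1, 0.9) (so post-filter MAF ≥ 0.05 is
typically satisfied). Meiosis is bivalent: each parent transmits 2 of
its 4 allele copies sampled without replacement, i.e. the transmitted
alternative-allele count given parent dosage d is Hypergeometric(4, d, 2).
Double reduction is fixed at zero and isolated in a single sampling
rule (`_gamete_indices`), so a nonzero rate can be added later without
touching anything else. An unknown parent contributes a base-population
gamete at the founder frequencies.

**Reads.** Per-entry total depth is negative-binomial with mean
`mean_depth` (default 73) and dispersion φ (variance μ + φμ², default
φ = 0.2; φ = 0 gives Poisson). Each read reports the alternative allele
with probability `π = (d/4)(1−e) + (1−d/4)e`, with a symmetric per-read
error `e` (default 0.005). Zero total depth yields a *missing* genotype
(0/0 is undefined); missingness is handled downstream by imputation, not
here.

**Dosage calling.** Two emulation methods: `naive_round` (round
`ratio × ploidy`) and `binomial_map` (argmax of the binomial read
likelihood over dosage classes). Both are deliberately simple: they
reproduce the *mechanism* of misclassification — overlapping read-ratio
distributions — not any specific caller's priors or filters.

**Phenotypes.** `y = μ + year + column + row + a + year×genotype + e`,
all random terms i.i.d. normal at the configured variances; row and
column effects are drawn per index and nested within year when more
than one year is simulated; each genotype receives one random field
cell per year. The additive value is the gene-dropped true breeding
value (random marker effects on centered dosages) rescaled to the
configured σa². Default variance components (1.0, 0.15, 0.15, 0.3, 2.0
for additive/row/column/g×e/residual) put h² at ≈0.28, inside the
0.15–0.57 band typical of yield and fruit-quality traits.

**What the generator does not model** — and hence what passing tests do
not establish about real data: linkage (markers are unlinked, so LD
reflects family structure only), selection during the pedigree,
dominance/epistasis, caller-specific artifacts, shared lab batch
effects, and spatial autocorrelation beyond i.i.d. row/column effects.

## Gene-dropping oracle

`gene_dropping_relationship` estimates the additive relationship by
Monte Carlo: distinct labels on every founder allele copy are dropped
through the pedigree under the same bivalent rule; with `M_xy` the
label matches among the 16 ordered copy pairs of two individuals,
kinship is `θ_xy = E[M_xy]/16` and `A = 4θ` (diploid mode: 4 ordered
pairs, `A = 2θ`). Because the per-replicate match count is computed
exactly (not subsampled), the estimator is the Rao-Blackwellized
version of pair sampling; entrywise standard errors are returned.
Founder–founder entries are deterministic, so the oracle is exact
there. This estimator — not any transcription of published recursion
formulas — is the correctness authority for the pedigree matrices.

## Relationship matrices (`polygs.kinship`)

`A2` is the standard numerator-relationship recursion. `A4` works on
the kinship scale with tetrasomic transmission and no double reduction:

```
θ_xi = (θ_xs + θ_xd)/2
F_i  = (F_s + F_d)/6 + (2/3) θ_sd
θ_ii = (1 + 3 F_i)/4,        A = 4θ  (diagonal 1 + 3F)
```

The `F_i` recursion comes from decomposing the pairs of a progeny's
four copies: both copies from the same gamete with probability 1/6 each
(IBD with probability equal to the parent's F, since the gamete holds
two distinct parental copies), one from each with probability 2/3 (IBD
with probability θ_sd). The test suite asserts entrywise agreement with
the gene-dropping oracle on random multigeneration pedigrees.

G-matrices are VanRaden cross-products `G = WW'/k` with `W` the
column-centered codes (observed column means; no base-population
frequencies are available). The scale `k` is the expected centered
cross-product under the parameterization's sampling model:
`Σ 2p(1−p)` for G2 and `Σ 4p(1−p)` for G4 with `p = column mean/ploidy`.
For `Gr` no ploidy model applies, so `k = Σ s²_j`, the observed column
variances (ddof 0), which makes the mean diagonal exactly 1 with no
assumption at all — consistent with the parameterization's
"assumption-free" framing. The choice of `k` only rescales σa²;
predictions and predictive ability are invariant to it (tested).
Monomorphic columns are dropped with a warning before computing `k`.
`bend_psd` shifts the diagonal by `ε·mean(diag)` plus any eigenvalue
deficit when the smallest eigenvalue is negative, leaving off-diagonals
untouched, so rank-deficient G matrices (n > m) factorize.

## The mixed model (`polygs.model`)

**Structure.** Single-year traits drop the year and year×genotype
terms; row/column factors are nested within year only for multi-year
traits. Breeding values are predicted for every label of the
relationship matrix, including genotypes without records (this is what
makes genotype-masking cross-validation meaningful).

**Sampler.** Gibbs sampling with every block drawn jointly from its
exact full conditional. The additive effect is reparameterized once:
with `K = UDU'`, set `S = U√D` (dropping null eigenvalues), then
eigendecompose `(ZS)'(ZS) = QΛQ'` and sample `a = SQβ`, where the full
conditional of β has *diagonal* precision `Λ/σe² + I/σa²`. The i.i.d.
blocks (row, column, year×genotype) have orthogonal incidence columns,
so their joint conditionals are also diagonal; the fixed block uses a
one-time Cholesky of `F'F`. Per-sweep cost is O(records × genotypes)
with no per-iteration factorizations. Variances update from
scaled-inverse-χ² conditionals. Chains are deterministic given the
seed; chain length is `ceil((n_iter − burn_in)/thin)`.

**Priors.** Each variance has a scaled-inverse-χ² prior with
`prior_df = 5` whose mode splits `prior_R2 = 0.5` of var(y) equally
among the random terms, the residual receiving the remainder — the
default-hyperparameter convention of the reference Bayesian regression
implementation this model follows. Note this prior is *informative*
about scale: alone it keeps each variance above roughly a quarter of
its prior mode, which floors no-signal h² estimates near 0.3 and damps
extreme variance ratios at small n. `ModelSpec.prior_scales` overrides
the per-component scales for users who need scale-equivariant or
weaker priors. The sampler was verified against exact 2-D grid
integration of the posterior on small data (agreement to three
decimals) and against pathwise scale equivariance (scaling K by c with
a 1/c prior scale reproduces the σa² chain exactly divided by c).

**Heritability** is computed per retained draw as σa² over the sum of
all variance components, then averaged. **DIC** uses the conditional
(plug-in random effects) deviance: `DIC = D̄ + pD`,
`pD = D̄ − D(posterior means)`, with D the Gaussian deviance given the
linear predictor and σe². Effective sample sizes per variance use the
initial-positive-sequence autocorrelation estimator; chains are never
auto-extended (iteration counts are fixed by configuration, as in the
analysis this package reproduces).

**eBLUEs.** The all-fixed companion model treats year, row, column and
genotype as fixed and *drops* the year×genotype interaction — keeping
it fixed alongside genotype and year makes genotype means
non-estimable. Genotype least-squares means average predictions over a
uniform reference grid of the other factors via a pseudo-inverse solve;
the LSMeans are estimable functions, hence invariant to the choice of
generalized inverse.

## Evaluation (`polygs.evaluate`)

Cross-validation partitions *genotypes* (not records) into k = 10 folds
of near-equal size, without stratification; all records of a validation
genotype are masked, the model refits, and the predicted breeding
values of the masked genotypes are compared with their full-data
eBLUEs. Predictive ability is the Pearson correlation computed per
fold and averaged (a pooled-across-folds correlation is emitted as a
secondary statistic). MSE is computed after centering both vectors
within the fold, because predictions and eBLUEs live on different
location scales. One fold assignment is shared across all models for a
given seed, so model contrasts are paired.

Expected genetic gain is `ΔG = PA·σa·i/L`, with selection intensity
i = 1 and default cycle lengths of 12 years for phenotypic and
pedigree selection and 9 for genomic selection (a three-year reduction
from earlier selection); both are configurable, since printed gains
depend on the L assigned to each method. Tukey letter groups come from
one-way ANOVA + Tukey HSD over independent runs, with letters assigned
to maximal cliques of the non-significance graph ordered by model mean
(relabel-invariant); when every run is identical the degenerate
zero-variance case falls back to grouping equal means.

## Population-genetics diagnostics (`polygs.popgen`)

LD is the squared Pearson correlation of genotype columns within a
scaffold, after pruning to one randomly chosen SNP per capture probe.
The decay distance at a threshold (default r² = 0.2) is where a fitted
exponential `r² = r₀·exp(−d/λ)` crosses it, `d* = λ·ln(r₀/θ)`, with a
percentile bootstrap over marker pairs for the CI; "below threshold
everywhere" and "crossing beyond the observed range" are explicit
statuses, not numbers. The estimator behind published decay figures is
generally unstated, so this fitted-curve operationalization is a
package choice and its output is compared structurally, not
numerically. PCA diagnostics double-center the relationship matrix
(classical PCoA) and report percent variance per component over the
positive eigenvalues only (small negative eigenvalues can occur for
unbent G).

## Pipeline and validation scale

`run_pipeline` drives simulate → encode/filter → kinship → fit → CV →
report for any subset of {I, A2, A4, G2, G4, Gr}, with one global seed
fanned out to per-stage seeds through `SeedSequence.spawn`, making
reruns byte-identical. Tukey letters for predictive ability use
fold-level values (paired folds); letters for h² require `n_runs ≥ 2`
refits. The pipeline is simulation-backed; file-backed analyses
compose the CLI subcommands (`encode`, `filter`, `kinship`, `fit`,
`cv`, `ld`, `pca`, `het`) instead.

The validation benchmarks (`polygs.benchmarks`, used by both the test
suite and `scripts/acceptance.py`) run at desk scale: a 60-individual,
4-generation pedigree with 10⁵ gene drops for oracle agreement; n=500,
m=5,000 Hardy–Weinberg dosages for G4 scaling; twenty 500-individual
populations (45 founders, 35 crosses × 13, m = 2,000, variance
components 0.3/0.1/0.1/0.5, chains 6,000/1,000/5) for h² recovery; and
five 210-individual populations at 5× depth (m = 400, chains
1,500/500/3, 10 paired folds) for the miscalling comparison, where
MAP-called dosages are ~43% wrong and the continuous-ratio matrix `Gr`
sidesteps calling entirely. These sizes keep the full suite to a couple
of minutes while leaving every comparison well above its noise floor.

## Known limitations

- No double-reduction rates > 0, no dominance/digenic or H
  (pedigree–genomic blended) matrices, no REML path, no multi-trait
  models, no spatial-kernel field models.
- The eBLUE interaction-dropping rule is a modeling decision forced by
  estimability; other resolutions (e.g. weighted two-stage analyses)
  would give different LSMeans in unbalanced data.
- Heritability and variance-component point estimates inherit the
  informative default prior's pull at small n (see Priors above);
  comparisons *between* relationship matrices, which share the prior,
  are unaffected.
- The diploid/tetraploid heterozygosity contrast on synthetic data is
  much smaller than on real caller output: a MAP caller at high depth
  assigns every intermediate read ratio to a heterozygous class,
  whereas production variant callers shift many of those calls to
  homozygote classes via priors and quality filters the simulator does
  not model.
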