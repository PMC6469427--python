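# polygs — genomic prediction for autotetraploid breeding populations

Genotype calling is hard in autopolyploids: a tetraploid locus has five
dosage classes (*AAAA*, *AAAB*, *AABB*, *ABBB*, *BBBB*) whose
sequencing-read signals overlap, so assigned dosages are frequently
wrong even at high coverage. `polygs` implements, as a tested Python
library and CLI, the model-comparison analysis this problem motivates in
genomic selection for species such as highbush blueberry: build additive
relationship matrices from different information sources and ploidy
assumptions, fit the same Bayesian mixed model with each, and compare
them by cross-validated predictive ability, goodness of fit and expected
genetic gain — including the *ploidy-assumption-free* route that skips
dosage calling entirely and uses the raw alternative-read ratio
`#A / (#A + #a)` as a continuous genotype.

## The model

For a trait record the single-step mixed model is

```
y = μ + Xb + Z₁c + Z₂r + Z₃a + Z₄(b×a) + e
```

with `b` the fixed year effect, `c ~ N(0, Iσc²)` and `r ~ N(0, Iσr²)`
random field column and row effects (nested within year for two-year
traits), `a ~ N(0, Ga σa²)` the additive genetic effect, `b×a ~ N(0,
Iσb×a²)` the year-by-genotype interaction, and `e ~ N(0, Iσe²)`.
Narrow-sense heritability is `h² = σa² / (σa² + σc² + σr² + σb×a² + σe²)`.

`Ga` is swapped among six constructions:

| matrix | source   | ploidy assumption |
|--------|----------|-------------------|
| `I`    | none     | — (phenotypic BLUP) |
| `A2`   | pedigree | 2 (numerator-relationship recursion) |
| `A4`   | pedigree | 4, bivalent pairing, no double reduction |
| `G2`   | markers  | 2 (heterozygotes collapsed, codes 0–2) |
| `G4`   | markers  | 4 (allele dosage, codes 0–4) |
| `Gr`   | markers  | none (continuous read ratios in [0, 1]) |

Marker matrices are VanRaden cross-products `WW'/k` of column-centered
codes; pedigree matrices come from exact kinship recursions, which are
validated against a Monte-Carlo gene-dropping oracle. Fitting is by a
Gibbs sampler (30,000 iterations, 5,000 burn-in, thinning 5 by default)
with scaled-inverse-χ² variance updates; model comparison uses 10-fold
genotype-masking cross-validation (predictive ability = Pearson
correlation between genotype least-squares means and predicted breeding
values), DIC, Tukey letter groups over repeated runs, and expected
genetic gain `ΔG = PA·σa·i/L`.

A synthetic-population module simulates the whole data stack — ~124
biparental crosses of ~146 tetraploid parents, tetrasomic inheritance
without double reduction, per-entry read counts at a mean depth of 73×,
field layouts over two years — so every stage is testable without any
real dataset.

## Worked example

```python
import numpy as np
from polygs import (SimulationConfig, simulate_population, gmatrix,
                    ModelSpec, build_design, fit_gibbs, cross_validate)

cfg = SimulationConfig(n_founders=30, n_crosses=20, progeny_per_cross=9,
                       n_markers=400, n_years=1, field_dims=(15, 15),
                       seed=5000)
population, reads, phenotypes = simulate_population(cfg)
G4 = gmatrix(population.true_dosage.astype(float), "G4",
             labels=population.pedigree.ids)

spec = ModelSpec(trait="sim_trait", relationship=G4,
                 n_iter=6000, burn_in=1000, thin=5, seed=1)
result = fit_gibbs(build_design(phenotypes, spec))
print(f"h2 = {result.h2_mean:.3f}, DIC = {result.dic:.1f}")

cv = cross_validate(phenotypes, G4, spec, k=10, seed=1)
print(f"predictive ability = {cv.pa_mean:.3f} +- {cv.pa_sd:.3f}")
```

prints (exactly, for these seeds):

```
h2 = 0.239, DIC = 811.9
predictive ability = 0.327 +- 0.211
```

i.e. the sampler estimates a heritability near the simulated value
(~0.28 under the default variance components, single-year model) and a
G4-based model transfers a substantial part of the eBLUE signal to
genotypes whose phenotypes were held out — in the range the method
reports for yield-type traits at moderate h². The same
analysis runs from the shell: `polygs simulate`, `polygs kinship
--method G4`, `polygs fit`, `polygs cv`, or end-to-end over any model
subset with `polygs run --config config.yaml`.

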