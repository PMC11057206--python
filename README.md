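# adaptarch

Inferring the **adaptive architecture** of quantitative traits — oligogenic
(few contributing loci) versus polygenic (many) — from the temporal
dynamics of their **phenotypic variance** in experimental evolution.

When a population adapts to a shifted trait optimum under Gaussian
stabilizing selection, a trait controlled by few loci loses phenotypic
variance drastically as large-effect alleles sweep, while a highly
polygenic trait stays close to the neutral drift expectation. The variance
change

&nbsp;&nbsp;&nbsp;&nbsp;*F* = σ²ₓ / σ²₁

(phenotypic variance at generation *x* over the ancestral, generation-1
variance) therefore carries information about the number of contributing
loci. This package provides, for a typical *Drosophila*-style
evolve-and-resequence design (hundreds of founder haplotypes, N ≈ 300,
~100 generations):

- a forward Wright–Fisher simulator of quantitative (expression) traits —
  recombination on a genetic map, gamma effect sizes standardized to mean
  1/M with a negative frequency–effect correlation (r = −0.7), sampled
  heritabilities, single-trait or 20-trait-module Gaussian fitness with an
  optimum shift of *a* ancestral SDs and width *b* ancestral SDs
  (`adaptarch.forward_sim`, `adaptarch.trait_architecture`);
- synthetic inputs so everything runs without downloads: founder haplotype
  panels, genetic maps, neutral burn-ins, and negative-binomial RNA-seq
  count matrices emulating the 2-ancestral + 2-evolved, ~20-individual,
  lot-confounded study design (`adaptarch.synthetic_data`);
- variance-change statistics and ensemble summaries
  (`adaptarch.variance_dynamics`);
- the inference layer: a single-trait variance F-test against the neutral
  expectation, the group-level Welch t-test between selected and neutral
  trait sets, simulation-based power grids over sample size / duration /
  population size, the lower bound on contributing loci, and the
  between-replicate correlation permutation test
  (`adaptarch.inference_power`);
- the expression-data stage: TMM normalization, natural-log CPM, per-gene
  variance change within library lots, jackknife confidence intervals,
  the CV² partition (total CV² = technical CV² + biological CV²), and the
  DE-vs-non-DE comparison of variance changes
  (`adaptarch.expression_analysis`).

## Worked example

Simulate five-locus (oligogenic) and thousand-locus (polygenic) selected
traits plus a neutral reference, and ask whether 20 phenotyped individuals
per time point distinguish them:

```python
import numpy as np
from adaptarch import FitnessRegime, simulate_trait_ensemble
from adaptarch.inference_power import group_power
from adaptarch.study import default_panel

panel = default_panel(seed=0)                      # 189 founder haplotypes
mild = FitnessRegime.single_trait(a=1.0, b=3.6)    # mild optimum shift
kw = dict(N=300, generations=100, record=(1, 100),
          store_phenotypes=(1, 100))

oligo   = simulate_trait_ensemble(panel, 200, M=5,    shape=2.5, regime=mild, seed=1, **kw)
poly    = simulate_trait_ensemble(panel, 200, M=1000, shape=2.5, regime=mild, seed=2, **kw)
neutral = simulate_trait_ensemble(panel, 200, M=50,   shape=2.5,
                                  regime=FitnessRegime.neutral(), seed=3, **kw)

for name, ens in [("M=5", oligo), ("M=1000", poly), ("neutral", neutral)]:
    print(name, round(float(np.mean([t.F(100) for t in ens])), 3))
print("power M=5    vs neutral:",
      group_power(oligo, neutral, n=20, iterations=100, seed=4))
print("power M=1000 vs neutral:",
      group_power(poly, neutral, n=20, iterations=100, seed=5))
```

```
M=5 0.613
M=1000 0.856
neutral 0.922
power M=5    vs neutral: 1.0
power M=1000 vs neutral: 0.3
```

The oligogenic traits lose ~40% of their variance by generation 100 and
are separated from neutrality in every resampling iteration; the
thousand-locus traits sit close to the neutral decay and are detected in
only a minority of iterations at these desk-scale ensemble sizes — the
signature used to argue that an observed *absence* of excess variance loss
(as in the fly gene-expression data this design mirrors) reflects a
polygenic adaptive architecture.

The numbered drivers under `analysis/` run the full story at desk scale
and write tables under `results/`:

1. `01_variance_trajectories.py` — mean-F trajectories with 95% envelopes
   across architectures, shapes and selection strengths;
2. `02_power_grids.py` — group-test power over the locus ladder and the
   design axes (n, generations, N), census single-trait power, lower bound;
3. `03_modular_traits.py` — burn-in + coregulated 20-trait modules under
   multivariate Gaussian fitness;
4. `04_expression_variance.py` — the expression pipeline on a synthetic
   count matrix (TMM, ln CPM, per-gene F, CV² partition, DE vs non-DE,
   jackknife, replicate-correlation test).

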