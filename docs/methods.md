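# Methods

## The question and the model

When a population adapts to a new environment, the loci that actually
respond — the *adaptive architecture* — are hard to enumerate, especially
when many loci of small effect contribute. This package implements an
indirect route: track the **phenotypic variance** of traits through time.
Under stabilizing selection toward a shifted optimum, a trait controlled by
few loci (oligogenic, < 10) loses variance rapidly as the large-effect
alleles sweep; a highly polygenic trait barely departs from the neutral
drift expectation. The contrast between the two regimes, quantified as the
variance change

    F = sigma_x^2 / sigma_1^2

(phenotypic variance at generation *x* over the ancestral, generation-1
variance; F is always evolved/ancestral, so a drop "to 84%" is F = 0.84),
is the basis of all inference here.

## Forward simulation

The simulator is a diploid, monoecious Wright–Fisher model with constant
census size N (treated as the effective size): each of the N offspring
draws two parents independently with probability proportional to fitness
(selfing allowed), and receives one recombinant gamete from each.
Recombination follows the Markov chain equivalent to a Poisson crossover
process through Haldane's map function (no interference); adjacent loci on
different chromosomes assort freely. No de novo mutation occurs during the
experimental phase — the response draws exclusively on the variation
carried by the founder haplotypes. Only a trait's causal loci are tracked;
their pairwise linkage is taken from the genetic map, which is sufficient
for the trait's dynamics and keeps thousand-replicate ensembles at
desk scale.

A trait architecture consists of M loci drawn uniformly from the panel's
segregating sites, with gamma-distributed effect magnitudes (shape 0.5, 2.5
or 100; the sample mean standardized to exactly 1/M) rank-correlated with
the founder allele frequency at r = −0.7 by a Gaussian-copula reordering
(sorting effects against a latent variable correlated with the frequency
ranks — the semantics of the `correlate()` reordering approach, with the
latent correlation adjusted so the *Spearman* correlation hits the target).
Effects then receive a random sign with probability 0.5 each way:
sign-symmetric effects
avoid a degenerate, strictly directional ancestral mean while leaving
|effect| marginals and the frequency–effect coupling untouched. Dominance
is additive (d = 0.5) by default; a per-locus dominance vector is accepted
(genotypes 0/1/2 contribute 0 / 2dα / 2α).

Phenotype = genotypic value + Gaussian environmental noise. Each trait's
heritability is drawn from Beta(3.2, 1.7) (mean ≈ 0.65) — a stand-in for
the unpublished empirical distribution of expression-trait heritabilities,
calibrated so that the neutral variance ratio after 100 generations at
N = 300 is ≈ 0.9 under the drift closed form
1 − h̄²(1 − (1 − 1/2N)^t). A user-supplied table of empirical
heritabilities can be resampled instead. The environmental variance is
assigned per trait as sigmaE² = V_anc (1 − h²)/h², with V_anc the *realized
genetic* variance of the founded population at generation 1 (a config
switch anchors on the phenotypic SD instead).

Selection is Gaussian stabilizing selection anchored at generation 1 (no
pre-shift equilibration): optimum z0 = X̄_anc + a·√V_anc and width
b·√V_anc, with a ∈ {1, 3} and b ∈ {1.8, 3.6, 5.4}. For coregulated modules
of 20 traits the fitness is multivariate,
ω = exp(−½ Σᵢ (zᵢ − z0ᵢ)²/(2 Vsᵢ)) with Vsᵢ = b·√V_ancᵢ — an effective
exponent denominator of 4 Vs, carrying an extra ½ relative to a standard
Gaussian. Both readings of this fitness form are in circulation, so the
default keeps the formula as written above and a switch
`fitness_exponent_convention = "standard_gaussian"` gives the conventional
exp(−(z−z0)²/(2Vs²)).

## Synthetic data

**Founder panel.** 189 haplotypes over (default) 2,000 loci; per-locus
frequencies from a Beta(1, 3) spectrum (skewed toward rare alleles;
uniform and 1/f spectra available), realized by Bernoulli sampling, with
monomorphic columns redrawn. The genetic map is a synthetic stand-in —
5 Morgans uniform over 5 chromosome arms — since the real linkage map is
not reproduced here; map files are loadable for users who have one.

**Burn-in for the modular scenario.** A neutral Wright–Fisher burn-in with
symmetric biallelic mutation on weakly linked loci (r = 0.001 per
interval). Defaults are desk-scaled (N = 1,000, 10N generations); the
study-scale configuration (N = 10,000, 20,000 generations) is accepted via
parameters. Stationary heterozygosity follows the diffusion value
a/(2a + 1) with a = 4Nμ for this mutation model.

**Counts.** RNA-seq counts are gamma-Poisson: per gene, a log-normal
baseline mean, a unit-mean gamma multiplier per individual carrying the
biological CV² (= the NB dispersion), per-lot log-scale batch offsets
(sd 0.15), and log-normal library sizes around 5 × 10⁶. The default design
mirrors the study: two reconstituted ancestral and two evolved populations
of 19–22 individuals, each lot holding one ancestral and one evolved
library. DE genes (default 20% of genes, the experiment's order of
magnitude) have their evolved mean shifted by ±1 ancestral biological SD
on the natural-log scale (σ = √trigamma(1/φ)); evolved dispersions are
multiplied by a variance factor, default 0.84, emulating the drift-driven
loss of expression variance for *all* genes — so DE and non-DE variance
changes are indistinguishable by construction, the polygenic expectation.
What the generator does **not** emulate: count outliers, gene–gene
correlation, GC/length biases, or selection actually acting through an
oligogenic architecture; passing tests therefore validate the estimators
and the statistical machinery, not any claim about real fly data.

## Inference

**Single-trait test.** The observed ratio s_x²/s_1², divided by the neutral
expectation F_neutral (0.9 at generation 100 under the defaults), referred
to the lower tail of F(n−1, n−1). Power is the fraction of simulated
selected traits rejected at α = 0.05; the power to "rule out ≤ M loci
across all parameter combinations" is the **minimum** per-combination power
over the mild-shift grid — the across-all-combinations reading used for the
lower-bound logic (the least favourable nuisance parameters limit what can
be excluded).

**Group test.** Welch's two-sample t-test (the unequal-variance form is
the safe default for F distributions of different spread) between the F
distributions of a selected and a neutral trait set, each trait's F
re-estimated per iteration from n = 20 individuals sampled without
replacement, independently at generations 1 and x (distinct flies are
phenotyped at the two time points). Power = fraction of 100 iterations
significant.

**Lower bound on loci.** The largest M such that M and all smaller
simulated M remain detectable under the chosen criterion (default: power
≥ 0.8) in *every* parameter combination; `None` when even the smallest M
fails.

**Replicate-correlation test.** Pearson correlation of per-gene F between
the two evolved replicates for DE genes, compared with a permutation null
built from equally sized random draws of non-DE genes (add-one p-value).

## Expression pipeline

TMM normalization is re-implemented (reference = library whose 75th
count quantile is closest to the mean; 30%/5% double trimming on
log-ratios/abundance; precision-weighted mean; factors scaled to geometric
mean 1 — the conventional defaults of the published scheme). Expression is
natural-log CPM with pseudocount 0.5 (configurable). Per-gene variance
changes are computed only within lot-matched ancestral/evolved pairs.
The CV² partition is total CV² = technical CV² + biological CV² with the
technical term modeled as Poisson read-sampling noise 1/mean(normalized
count) and the biological term max(0, total − technical), optionally shrunk
(default weight 0.3) toward a rolling-median mean–dispersion trend; the
identity holds exactly for every partitioned gene by construction.
Jackknife intervals for per-gene variances use log-scale pseudovalues (the
variance-stabilizing choice; coverage ≈ 94–95% at n = 20 versus ≈ 91% for
the linear construction), falling back to the linear form for degenerate
input. The DE-call stand-in (per-gene Welch t + Benjamini–Hochberg at
FDR 0.05) exists only so the pipeline runs without external labels;
user-supplied labels override it exactly.

## Numerical and design notes

- F uses unbiased (n−1) sample variances throughout. The finite-sample
  estimator F̂ from n individuals is biased upward by (n−1)/(n−3) for
  Gaussian data (≈ 12% at n = 20); the group test compares two sets of F̂
  with identical bias, so this cancels where it matters.
- The mean of the *population* variance ratio across traits exceeds the
  drift closed form by ≈ +0.015 under the canonical conditions: founding
  300 diploids from 189 haplotypes leaves linkage-disequilibrium/relatedness
  noise in the generation-1 variance, and averaging the ratio over traits
  is a Jensen-biased operation. Per-locus heterozygosity decay is exactly
  (1 − 1/2N) per generation. The closed form is therefore used as a
  calibration anchor, not an exact expectation.
- Under the default heritability distribution, the fraction of neutral
  traits whose mean drifts ≥ 1 ancestral phenotypic SD in ~100 generations
  is ≈ 2.5–3.5%, consistent with the drift variance of the mean,
  2 V_A (1 − (1 − 1/2N)^t): a threshold of one phenotypic SD sits at
  ≈ 2.2 drift SDs when h̄² ≈ 0.65. A sub-1% fraction would require
  h̄² ≲ 0.45, which is incompatible with a neutral F of ≈ 0.9 at
  generation 100; the two headline calibrations cannot hold simultaneously
  under this model, and this package reports what the model gives.
- Ensembles redraw a trait's architecture (bounded retries) if the founded
  population has zero genetic variance — possible for small M with rare
  alleles.
- Desk-scale problem sizes (chosen as the package's defaults): 1,000-trait
  ensembles for headline numbers, 150–500 for exploratory grids and tests;
  burn-ins of a few thousand generations. All sizes are parameters.
- Seeds: every public operation takes a seed or Generator; ensembles spawn
  child seeds via `SeedSequence`, so runs are reproducible and
  parallelizable by trait.

## Known limitations

- No epistasis, no pleiotropy between modules, no sex chromosomes, no
  overlapping generations, no de novo mutation during the experiment.
- The genetic map, founder SFS and heritability distribution are explicit
  stand-ins for unpublished empirical inputs.
- The CV² partition uses a Poisson technical model and a simple trend
  shrinkage, not a full NB dispersion estimator.
- Power numbers are Monte-Carlo estimates; with 100-iteration resampling
  their resolution is one percentage point at best.
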