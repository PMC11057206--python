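"""Diploid Wright--Fisher forward simulation of quantitative traits.

A monoecious population of constant size N reproduces by
fitness-proportional parent sampling (two parents drawn independently per
offspring, selfing allowed) with Poisson-crossover recombination along a
genetic map and no de novo mutation — the variation available to selection
is exactly what segregates among the founder haplotypes. Selection is
Gaussian stabilizing selection around an optimum shifted by ``a`` ancestral
genetic SDs, of width ``b`` ancestral SDs; the neutral regime assigns equal
fitness to everyone. The simulator tracks only the causal loci of the trait
under study (plus their pairwise linkage), which is sufficient for the
trait's dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._recomb import meiosis
from .synthetic_data import GeneticMap, HaplotypePanel
from .trait_architecture import (
    ModuleArchitecture,
    TraitArchitecture,
    assign_environmental_variance,
    build_trait_architecture,
    sample_heritability,
)
from .variance_dynamics import TraitTrajectory

__all__ = [
    "Population",
    "FitnessRegime",
    "genotypic_value",
    "phenotype",
    "gaussian_fitness",
    "module_fitness",
    "next_generation",
    "evolve",
    "evolve_module",
    "simulate_trait_ensemble",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Population:
    """N diploids: two haplotype matrices over the tracked loci."""

    haplotypes: np.ndarray  # (2, N, L) uint8
    generation: int = 1

    def __post_init__(self):
        h = np.asarray(self.haplotypes)
        if h.ndim != 3 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, N, L)")
        self.haplotypes = h.astype(np.uint8)

    @property
    def size(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def genotype_counts(self) -> np.ndarray:
        """(N, L) matrix of derived-allele counts in {0, 1, 2}."""
        return self.haplotypes[0].astype(np.int8) + self.haplotypes[1]

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass(frozen=True)
class FitnessRegime:
    """Stabilizing-selection regime anchored to the ancestral trait distribution.

    ``a`` is the optimum shift and ``b`` the fitness-function width, both in
    units of the ancestral genetic standard deviation sqrt(V_anc) (a config
    switch ``scale`` = "phenotypic" uses the phenotypic SD instead). The
    anchors (ancestral mean and variance) are captured from the founded
    population at generation 1 — no pre-shift equilibration is assumed.

    For ``kind`` = "module" the fitness of an individual over the module's
    n traits is

        omega = exp( -1/2 * sum_i (z_i - z0_i)^2 / (2 Vs_i) )

    with Vs_i = b * sqrt(V_anc_i): an effective exponent denominator of
    4 Vs, i.e. an extra 1/2 relative to a standard Gaussian. Both readings
    are in circulation; ``fitness_exponent_convention`` =
    "standard_gaussian" switches to exp(-(z - z0)^2 / (2 Vs^2)).
    """

    kind: str = "neutral"  # neutral | single_trait | module
    a: float = 1.0
    b: float = 3.6
    scale: str = "genetic"  # genetic | phenotypic
    fitness_exponent_convention: str = "as_printed"
    # anchors, filled in by .anchor(); arrays for module regimes
    z_opt: float | np.ndarray | None = None
    width: float | np.ndarray | None = None
    Vs: float | np.ndarray | None = None
    X_anc: float | np.ndarray | None = None
    V_anc: float | np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("neutral", "single_trait", "module"):
            raise ValueError("kind must be neutral, single_trait or module")
        if self.kind != "neutral" and self.b <= 0:
            raise ValueError("fitness width multiplier b must be positive")
        if self.scale not in ("genetic", "phenotypic"):
            raise ValueError("scale must be 'genetic' or 'phenotypic'")
        if self.fitness_exponent_convention not in ("as_printed", "standard_gaussian"):
            raise ValueError("unknown fitness exponent convention")

    @classmethod
    def neutral(cls) -> "FitnessRegime":
        return cls(kind="neutral")

    @classmethod
    def single_trait(cls, a: float = 1.0, b: float = 3.6, **kw) -> "FitnessRegime":
        return cls(kind="single_trait", a=a, b=b, **kw)

    @classmethod
    def module(cls, a: float = 1.0, b: float = 3.6, **kw) -> "FitnessRegime":
        return cls(kind="module", a=a, b=b, **kw)

    def anchor(self, mean, var) -> "FitnessRegime":
        """Fix the optimum and width from the ancestral mean/variance."""
        mean = np.asarray(mean, dtype=float)
        var = np.asarray(var, dtype=float)
        sd = np.sqrt(var)
        anchored = replace(
            self,
            X_anc=mean if mean.ndim else float(mean),
            V_anc=var if var.ndim else float(var),
            z_opt=mean + self.a * sd,
            width=self.b * sd,
            Vs=self.b * sd,
        )
        return anchored


def genotypic_value(
    pop: Population | np.ndarray,
    arch: TraitArchitecture,
    loci_are_columns: bool = True,
) -> np.ndarray:
    """Per-individual genetic value: sum over loci of the dominance-scaled effect.

    Genotypes 0/1/2 derived-allele copies contribute 0, 2 d alpha and
    2 alpha respectively; d = 0.5 recovers the additive 0 / alpha / 2 alpha.
    ``pop`` may be a Population whose columns already are the architecture's
    loci, or a raw genotype-count matrix.
    """
    if isinstance(pop, Population):
        g = pop.genotype_counts()
    else:
        g = np.asarray(pop)
    if g.shape[1] != arch.M:
        raise IndexError("genotype matrix columns do not match architecture loci")
    if arch.is_additive:
        return g @ arch.effect
    het = (g == 1) @ (2.0 * arch.dominance * arch.effect)
    hom = (g == 2) @ (2.0 * arch.effect)
    return het + hom


def phenotype(values: np.ndarray, sigmaE2: float, seed=None) -> np.ndarray:
    """Add independent Gaussian environmental noise of variance sigmaE2."""
    if sigmaE2 < 0:
        raise ValueError("sigmaE2 must be >= 0")
    values = np.asarray(values, dtype=float)
    if sigmaE2 == 0:
        return values.copy()
    rng = _as_rng(seed)
    return values + rng.normal(0.0, np.sqrt(sigmaE2), size=values.shape)


def gaussian_fitness(z: np.ndarray, regime: FitnessRegime) -> np.ndarray:
    """Single-trait Gaussian fitness w(z) = exp(-(z - z0)^2 / (2 width^2))."""
    if regime.kind != "single_trait":
        raise ValueError("gaussian_fitness requires a single_trait regime")
    if regime.z_opt is None:
        raise ValueError("regime is not anchored; call regime.anchor(mean, var)")
    if regime.width <= 0:
        raise ValueError("fitness width must be positive")
    z = np.asarray(z, dtype=float)
    return np.exp(-((z - regime.z_opt) ** 2) / (2.0 * regime.width**2))


def module_fitness(z: np.ndarray, regime: FitnessRegime) -> np.ndarray:
    """Multivariate Gaussian fitness over a module's traits.

    ``z`` has shape (..., n_traits). With the default "as_printed"
    convention the exponent is -sum_i (z_i - z0_i)^2 / (4 Vs_i); with
    "standard_gaussian" it is -sum_i (z_i - z0_i)^2 / (2 Vs_i^2).
    """
    if regime.kind != "module":
        raise ValueError("module_fitness requires a module regime")
    if regime.z_opt is None:
        raise ValueError("regime is not anchored; call regime.anchor(mean, var)")
    Vs = np.asarray(regime.Vs, dtype=float)
    if np.any(Vs <= 0):
        raise ValueError("Vs must be positive")
    z = np.asarray(z, dtype=float)
    dev2 = (z - regime.z_opt) ** 2
    if regime.fitness_exponent_convention == "as_printed":
        expo = dev2 / (4.0 * Vs)
    else:
        expo = dev2 / (2.0 * Vs**2)
    return np.exp(-expo.sum(axis=-1))


def next_generation(
    pop: Population,
    fitness: np.ndarray | None,
    rfrac: np.ndarray,
    seed=None,
) -> Population:
    """One Wright--Fisher reproduction step.

    Each of the N offspring draws two parents independently with probability
    proportional to fitness (uniform when ``fitness`` is None) and receives
    one recombinant gamete from each. Population size is preserved and no
    mutations are introduced.
    """
    rng = _as_rng(seed)
    n = pop.size
    if fitness is None:
        parents = rng.integers(0, n, size=(2, n))
    else:
        w = np.asarray(fitness, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("fitness must be a non-negative length-N vector")
        total = w.sum()
        if total == 0:
            raise ValueError("all-zero fitness: population extinct under this regime")
        parents = rng.choice(n, size=(2, n), p=w / total)
    child = np.empty_like(pop.haplotypes)
    child[0] = meiosis(pop.haplotypes, parents[0], rfrac, rng)
    child[1] = meiosis(pop.haplotypes, parents[1], rfrac, rng)
    return Population(child, generation=pop.generation + 1)


def found_population(
    panel: HaplotypePanel,
    N: int,
    loci: np.ndarray | None = None,
    rng=None,
) -> tuple[Population, np.ndarray]:
    """Found N diploids by sampling haplotype pairs from the panel.

    Returns the population (restricted to ``loci`` when given, in map order)
    and the recombination fractions between the retained adjacent loci.
    """
    rng = _as_rng(rng)
    if loci is None:
        loci = np.arange(panel.n_loci)
    sub = panel.alleles[:, loci]
    rfrac = panel.gmap.subset(loci).recombination_fractions()
    idx = rng.integers(0, panel.n_haplotypes, size=(2, N))
    return Population(sub[idx], generation=1), rfrac


def _record_schedule(record, generations: int) -> np.ndarray:
    if record is None:
        sched = np.array([1, generations])
    elif isinstance(record, int):
        sched = np.unique(np.r_[1, np.arange(record, generations + 1, record), generations])
    else:
        sched = np.unique(np.asarray(list(record), dtype=int))
    if sched.min() < 1 or sched.max() > generations:
        raise ValueError("recording schedule outside the simulated range")
    if 1 not in sched:
        sched = np.r_[1, sched]
    return sched


def evolve(
    panel: HaplotypePanel,
    arch: TraitArchitecture,
    regime: FitnessRegime,
    N: int = 300,
    generations: int = 100,
    record=None,
    seed=None,
    store_phenotypes=(),
    return_population: bool = False,
):
    """Simulate one trait for ``generations`` generations.

    The population is founded from the panel at generation 1, where the
    ancestral phenotypic/genetic mean and variance are captured: the fitness
    regime is anchored there and, if ``arch.sigmaE2`` is None, the
    environmental variance is assigned as V_anc (1 - h2) / h2 from the
    realized ancestral genetic variance. ``record`` is None (generations 1
    and last), an integer stride, or an explicit iterable of generations;
    ``store_phenotypes`` lists generations whose full phenotype vectors are
    kept on the trajectory.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = _as_rng(seed)
    pop, rfrac = found_population(panel, N, arch.loci, rng)
    sched = _record_schedule(record, generations)
    store = set(int(g) for g in store_phenotypes)

    values = genotypic_value(pop, arch)
    V_anc = float(np.var(values, ddof=1))
    if V_anc == 0.0:
        raise ValueError("ancestral genetic variance is zero; redraw the architecture")
    sigmaE2 = (
        arch.sigmaE2
        if arch.sigmaE2 is not None
        else assign_environmental_variance(V_anc, arch.h2)
    )

    anchored = None
    if regime.kind == "single_trait":
        anchor_var = V_anc if regime.scale == "genetic" else V_anc + sigmaE2
        anchored = regime.anchor(float(np.mean(values)), anchor_var)
    elif regime.kind == "module":
        raise ValueError("use evolve_module for module architectures")

    rec = {"generation": [], "pheno_mean": [], "pheno_var": [], "geno_var": []}
    stored = {}

    def observe(gen, values):
        needed = gen in sched or gen in store
        selecting = anchored is not None
        if not (needed or selecting):
            return None
        z = phenotype(values, sigmaE2, rng)
        if gen in sched:
            rec["generation"].append(gen)
            rec["pheno_mean"].append(float(np.mean(z)))
            rec["pheno_var"].append(float(np.var(z, ddof=1)))
            rec["geno_var"].append(float(np.var(values, ddof=1)))
        if gen in store:
            stored[gen] = z
        return z

    z = observe(1, values)
    for gen in range(2, generations + 1):
        fitness = gaussian_fitness(z, anchored) if anchored is not None else None
        pop = next_generation(pop, fitness, rfrac, rng)
        values = genotypic_value(pop, arch)
        z = observe(gen, values)

    traj = TraitTrajectory(
        generations=np.array(rec["generation"]),
        pheno_mean=np.array(rec["pheno_mean"]),
        pheno_var=np.array(rec["pheno_var"]),
        geno_var=np.array(rec["geno_var"]),
        phenotypes=stored,
        meta={
            "M": arch.M,
            "h2": arch.h2,
            "sigmaE2": sigmaE2,
            "V_anc": V_anc,
            "N": N,
            "kind": regime.kind,
            "a": regime.a if regime.kind != "neutral" else 0.0,
            "b": regime.b if regime.kind != "neutral" else np.nan,
        },
    )
    if return_population:
        return traj, pop
    return traj


def evolve_module(
    panel: HaplotypePanel,
    module: ModuleArchitecture,
    regime: FitnessRegime,
    N: int = 300,
    generations: int = 100,
    record=None,
    h2=None,
    seed=None,
) -> list[TraitTrajectory]:
    """Simulate one coregulated module of n traits under multivariate fitness.

    Every trait of the module shares the same causal loci; per-trait
    heritabilities are drawn from the default distribution unless ``h2``
    (scalar or length-n vector) is given. Returns one trajectory per trait.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = _as_rng(seed)
    pop, rfrac = found_population(panel, N, module.loci, rng)
    sched = _record_schedule(record, generations)
    n_traits = module.n_traits

    if h2 is None:
        h2 = sample_heritability(size=n_traits, seed=rng)
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_traits,)).copy()

    def values_of(pop):
        return pop.genotype_counts() @ module.effect_matrix  # (N, n_traits)

    vals = values_of(pop)
    V_anc = np.var(vals, axis=0, ddof=1)
    if np.any(V_anc == 0.0):
        raise ValueError("a module trait has zero ancestral genetic variance")
    sigmaE2 = V_anc * (1.0 - h2) / h2
    anchored = regime.anchor(vals.mean(axis=0), V_anc) if regime.kind == "module" else None

    rec = {g: None for g in sched}

    def observe(gen, vals):
        if gen not in rec and anchored is None:
            return None
        z = vals + rng.normal(0.0, np.sqrt(sigmaE2), size=vals.shape)
        if gen in rec:
            rec[gen] = (
                z.mean(axis=0),
                z.var(axis=0, ddof=1),
                vals.var(axis=0, ddof=1),
            )
        return z

    z = observe(1, vals)
    for gen in range(2, generations + 1):
        fitness = module_fitness(z, anchored) if anchored is not None else None
        pop = next_generation(pop, fitness, rfrac, rng)
        vals = values_of(pop)
        z = observe(gen, vals)

    gens = np.array(sorted(rec))
    means = np.stack([rec[g][0] for g in gens])
    pvars = np.stack([rec[g][1] for g in gens])
    gvars = np.stack([rec[g][2] for g in gens])
    return [
        TraitTrajectory(
            generations=gens,
            pheno_mean=means[:, i],
            pheno_var=pvars[:, i],
            geno_var=gvars[:, i],
            meta={
                "M": module.M,
                "h2": float(h2[i]),
                "rho": module.rho,
                "fraction_causal": module.fraction_causal,
                "N": N,
                "kind": regime.kind,
                "trait": i,
            },
        )
        for i in range(n_traits)
    ]


def simulate_trait_ensemble(
    panel: HaplotypePanel,
    n_traits: int,
    M: int,
    shape: float,
    regime: FitnessRegime,
    N: int = 300,
    generations: int = 100,
    record=None,
    store_phenotypes=(),
    rho_freq_effect: float = -0.7,
    h2=None,
    seed=None,
    max_redraws: int = 5,
) -> list[TraitTrajectory]:
    """Simulate an ensemble of independently architected traits.

    Each trait draws a fresh set of M loci, effect sizes and heritability
    and evolves independently. Architectures whose founded population has
    zero ancestral genetic variance (possible for small M with rare alleles)
    are redrawn a bounded number of times.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_traits)
    out = []
    for s in seeds:
        rng = np.random.default_rng(s)
        for _ in range(max_redraws):
            arch = build_trait_architecture(
                panel, M, shape, rho_freq_effect=rho_freq_effect, h2=h2, seed=rng
            )
            try:
                traj = evolve(
                    panel,
                    arch,
                    regime,
                    N=N,
                    generations=generations,
                    record=record,
                    seed=rng,
                    store_phenotypes=store_phenotypes,
                )
                traj.meta["shape"] = shape
                out.append(traj)
                break
            except ValueError:
                continue
        else:  # pragma: no cover - vanishingly rare with default panels
            raise RuntimeError("could not found a trait with nonzero genetic variance")
    return out
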