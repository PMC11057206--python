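"""Synthetic inputs for the variance-dynamics pipeline.

This module generates every input the downstream stages need so that the
whole analysis runs without external data:

* founder haplotype panels (a fixed set of chromosomes seeding an
  experimental population, 189 by default) with a configurable site
  frequency spectrum,
* genetic maps (uniform per chromosome, or a constant per-interval
  recombination rate) with Haldane conversion to recombination fractions,
* a neutral Wright--Fisher burn-in with recurrent biallelic mutation, used
  to produce mutation--drift equilibrium panels for the modular scenario,
* negative-binomial RNA-seq count matrices emulating a two-replicate
  evolve-and-resequence design (2 reconstituted ancestral + 2 evolved
  populations, ~20 individuals each, batch-confounded library preparation,
  mean shifts of a configurable number of ancestral SDs in a DE subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma

from ._recomb import haldane, meiosis

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "CountMatrix",
    "generate_genetic_map",
    "generate_founder_haplotypes",
    "neutral_burnin",
    "simulate_expression_counts",
    "read_haplotype_panel",
    "write_haplotype_panel",
    "read_count_matrix",
    "write_count_matrix",
]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Per-locus genetic positions (Morgans) with chromosome labels.

    Positions are cumulative within each chromosome and non-decreasing.
    Adjacent loci on different chromosomes recombine freely (r = 0.5).
    """

    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chromosome)
        pos = np.asarray(self.position, dtype=float)
        if chrom.shape != pos.shape:
            raise ValueError("chromosome and position must have equal length")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"map positions decrease within chromosome {c!r}")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    @property
    def n_loci(self) -> int:
        return self.position.size

    @property
    def total_morgans(self) -> float:
        total = 0.0
        for c in np.unique(self.chromosome):
            p = self.position[self.chromosome == c]
            total += float(p.max() - p.min())
        return total

    def recombination_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between each pair of adjacent loci."""
        d = np.diff(self.position)
        r = haldane(np.maximum(d, 0.0))
        same_chrom = self.chromosome[1:] == self.chromosome[:-1]
        return np.where(same_chrom, r, 0.5)

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        """Map restricted to a sorted subset of loci (for causal-loci simulation)."""
        idx = np.asarray(indices)
        return GeneticMap(self.chromosome[idx], self.position[idx])


def generate_genetic_map(
    n_loci: int,
    n_chromosomes: int = 5,
    model: tuple = ("uniform", 5.0),
) -> GeneticMap:
    """Build a synthetic genetic map.

    ``model`` is either ``("uniform", total_morgans)`` — loci spread evenly
    over ``n_chromosomes`` equally sized chromosome arms — or
    ``("per_interval", r)`` — a constant recombination fraction r between
    every pair of adjacent loci on a single chromosome (the weak-linkage
    layout used for the modular scenario, r = 0.001 by default there).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    kind = model[0]
    if kind == "uniform":
        total = float(model[1])
        if total < 0:
            raise ValueError("total map length must be non-negative")
        per_chrom = np.array_split(np.arange(n_loci), n_chromosomes)
        chroms, pos = [], []
        length = total / n_chromosomes
        for i, idx in enumerate(per_chrom):
            m = len(idx)
            if m == 0:
                continue
            chroms.append(np.full(m, f"chr{i + 1}"))
            pos.append(np.linspace(0.0, length, m))
        return GeneticMap(np.concatenate(chroms), np.concatenate(pos))
    if kind == "per_interval":
        r = float(model[1])
        if r < 0 or r >= 0.5:
            raise ValueError("per-interval recombination fraction must be in [0, 0.5)")
        # constant r between neighbours; invert Haldane to get Morgan spacing
        d = -0.5 * np.log(1.0 - 2.0 * r) if r > 0 else 0.0
        pos = np.arange(n_loci, dtype=float) * d
        return GeneticMap(np.full(n_loci, "chr1"), pos)
    raise ValueError(f"unknown map model {kind!r}")


# ---------------------------------------------------------------------------
# founder haplotype panels
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """A panel of founder haplotypes over a shared set of biallelic loci."""

    alleles: np.ndarray  # (n_haplotypes, n_loci), 0/1
    gmap: GeneticMap

    def __post_init__(self):
        a = np.asarray(self.alleles)
        if a.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if a.shape[0] < 2:
            raise ValueError("a panel needs at least 2 haplotypes")
        if a.shape[1] != self.gmap.n_loci:
            raise ValueError("allele matrix and map disagree on locus count")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        self.alleles = a.astype(np.uint8)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Derived-allele frequency per locus (column mean of the alleles)."""
        return self.alleles.mean(axis=0)

    @property
    def monomorphic(self) -> np.ndarray:
        f = self.freq
        return (f == 0.0) | (f == 1.0)

    def segregating_loci(self) -> np.ndarray:
        return np.flatnonzero(~self.monomorphic)


def _sample_frequencies(sfs: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = sfs[0]
    if kind == "uniform":
        lo, hi = float(sfs[1]), float(sfs[2])
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("uniform SFS bounds must satisfy 0 <= lo <= hi <= 1")
        return rng.uniform(lo, hi, size=n)
    if kind == "beta":
        a, b = float(sfs[1]), float(sfs[2])
        if a <= 0 or b <= 0:
            raise ValueError("beta SFS parameters must be positive")
        return rng.beta(a, b, size=n)
    if kind == "neutral":
        # density proportional to 1/f on [f_min, 1 - f_min]
        f_min = float(sfs[1]) if len(sfs) > 1 else 0.01
        if not 0.0 < f_min < 0.5:
            raise ValueError("neutral SFS needs 0 < f_min < 0.5")
        f_max = 1.0 - f_min
        u = rng.random(n)
        return f_min * (f_max / f_min) ** u
    raise ValueError(f"unknown SFS spec {kind!r}")


def generate_founder_haplotypes(
    n_haplotypes: int = 189,
    n_loci: int = 2000,
    sfs: tuple = ("beta", 1.0, 3.0),
    seed: int | np.random.Generator | None = None,
    gmap: GeneticMap | None = None,
    max_retries: int = 100,
    allow_monomorphic: bool = False,
) -> HaplotypePanel:
    """Generate a founder haplotype panel.

    Per-locus derived-allele frequencies are drawn from the requested site
    frequency spectrum and then realized by independent Bernoulli sampling of
    each haplotype's allele. Columns that come out monomorphic are redrawn
    (frequency and alleles) up to ``max_retries`` times; any that remain
    monomorphic are kept only when ``allow_monomorphic`` is set, otherwise an
    error is raised.
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = _as_rng(seed)
    f = _sample_frequencies(sfs, n_loci, rng)
    alleles = (rng.random((n_haplotypes, n_loci)) < f[None, :]).astype(np.uint8)
    col_freq = alleles.mean(axis=0)
    bad = np.flatnonzero((col_freq == 0) | (col_freq == 1))
    for _ in range(max_retries):
        if bad.size == 0:
            break
        f_new = _sample_frequencies(sfs, bad.size, rng)
        alleles[:, bad] = rng.random((n_haplotypes, bad.size)) < f_new[None, :]
        col_freq = alleles[:, bad].mean(axis=0)
        bad = bad[(col_freq == 0) | (col_freq == 1)]
    if bad.size and not allow_monomorphic:
        raise RuntimeError(
            f"{bad.size} loci stayed monomorphic after {max_retries} retries; "
            "pass allow_monomorphic=True to keep them flagged"
        )
    if gmap is None:
        gmap = generate_genetic_map(n_loci)
    return HaplotypePanel(alleles, gmap)


def neutral_burnin(
    pop_size: int = 1000,
    n_loci: int = 5000,
    mutation_rate: float = 2.5e-5,
    gmap: GeneticMap | None = None,
    generations: int | None = None,
    seed: int | np.random.Generator | None = None,
    init: str = "balanced",
) -> HaplotypePanel:
    """Neutral Wright--Fisher burn-in with recurrent biallelic mutation.

    A monoecious diploid population of ``pop_size`` individuals evolves
    neutrally for ``generations`` generations (default 10N) with symmetric
    per-copy allele flips at ``mutation_rate`` per locus per generation and
    recombination along ``gmap`` (default: constant per-interval r = 0.001,
    the weakly linked layout of the modular scenario). Returns the final
    2N haplotypes as a panel, from which experimental founders can be
    sampled. ``init`` is ``"balanced"`` (all loci start at frequency 0.5) or
    ``"monomorphic"``.

    Defaults are desk-scale; the study-scale configuration (N = 10,000,
    20,000 generations) is accepted but slow.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be >= 0")
    rng = _as_rng(seed)
    if gmap is None:
        gmap = generate_genetic_map(n_loci, model=("per_interval", 0.001))
    if gmap.n_loci != n_loci:
        raise ValueError("map and n_loci disagree")
    if generations is None:
        generations = 10 * pop_size
    if generations < 0:
        raise ValueError("generations must be >= 0")

    if init == "balanced":
        haps = (rng.random((2, pop_size, n_loci)) < 0.5).astype(np.uint8)
    elif init == "monomorphic":
        haps = np.zeros((2, pop_size, n_loci), dtype=np.uint8)
    else:
        raise ValueError("init must be 'balanced' or 'monomorphic'")

    rfrac = gmap.recombination_fractions()
    for _ in range(generations):
        parents = rng.integers(0, pop_size, size=(2, pop_size))
        child = np.empty_like(haps)
        child[0] = meiosis(haps, parents[0], rfrac, rng)
        child[1] = meiosis(haps, parents[1], rfrac, rng)
        if mutation_rate > 0:
            flips = rng.random((2, pop_size, n_loci)) < mutation_rate
            child ^= flips.astype(np.uint8)
        haps = child
    return HaplotypePanel(haps.reshape(2 * pop_size, n_loci), gmap)


# ---------------------------------------------------------------------------
# panel / map I/O (plain text)
# ---------------------------------------------------------------------------


def write_haplotype_panel(panel: HaplotypePanel, prefix: str | Path) -> None:
    """Write ``<prefix>.haps.tsv`` (0/1 matrix) and ``<prefix>.map.tsv``."""
    prefix = Path(prefix)
    pd.DataFrame(panel.alleles).to_csv(prefix.with_suffix(".haps.tsv"), sep="\t", index=False)
    map_df = pd.DataFrame(
        {
            "chromosome": panel.gmap.chromosome,
            "locus_id": [f"L{i}" for i in range(panel.n_loci)],
            "genetic_position_morgans": panel.gmap.position,
            "physical_position": np.arange(panel.n_loci),
        }
    )
    map_df.to_csv(prefix.with_suffix(".map.tsv"), sep="\t", index=False)


def read_haplotype_panel(prefix: str | Path) -> HaplotypePanel:
    prefix = Path(prefix)
    alleles = pd.read_csv(prefix.with_suffix(".haps.tsv"), sep="\t").to_numpy()
    map_df = pd.read_csv(prefix.with_suffix(".map.tsv"), sep="\t")
    gmap = GeneticMap(
        map_df["chromosome"].to_numpy(),
        map_df["genetic_position_morgans"].to_numpy(float),
    )
    return HaplotypePanel(alleles, gmap)


# ---------------------------------------------------------------------------
# synthetic RNA-seq counts
# ---------------------------------------------------------------------------

DEFAULT_DESIGN: Mapping[str, int] = {"anc1": 20, "evo1": 19, "anc2": 22, "evo2": 21}
DEFAULT_BATCHES: Mapping[str, str] = {
    "anc1": "lot1",
    "evo1": "lot1",
    "anc2": "lot2",
    "evo2": "lot2",
}


@dataclass
class CountMatrix:
    """Genes x individuals expression counts with sample annotations.

    ``samples`` has one row per individual with columns ``individual_id``,
    ``population`` and ``batch``; ``de_label`` marks genes simulated with a
    shifted evolved mean; ``true_params`` records the generating parameters
    per gene (baseline mean count, dispersion, mean shift in ancestral-SD
    units, evolved variance factor).
    """

    counts: np.ndarray
    samples: pd.DataFrame
    genes: np.ndarray = None
    de_label: np.ndarray | None = None
    true_params: pd.DataFrame | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (genes x individuals)")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if len(self.samples) != c.shape[1]:
            raise ValueError("sample sheet does not match column count")
        if self.genes is None:
            self.genes = np.array([f"G{i}" for i in range(c.shape[0])])
        self.counts = c

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def populations(self) -> np.ndarray:
        return self.samples["population"].to_numpy()

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def columns(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.populations == population)


def _dispersions(model: tuple, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    kind = model[0]
    if kind == "constant":
        phi = float(model[1])
        if phi <= 0:
            raise ValueError("dispersion must be positive")
        return np.full(n_genes, phi)
    if kind == "lognormal":
        median, sdlog = float(model[1]), float(model[2])
        if median <= 0 or sdlog < 0:
            raise ValueError("invalid lognormal dispersion parameters")
        return median * np.exp(rng.normal(0.0, sdlog, size=n_genes))
    raise ValueError(f"unknown dispersion model {kind!r}")


def simulate_expression_counts(
    n_genes: int = 5000,
    design: Mapping[str, int] | None = None,
    de_fraction: float = 0.2,
    mean_shift_sd: float = 1.0,
    variance_factor: float | np.ndarray = 0.84,
    dispersion_model: tuple = ("lognormal", 0.05, 0.5),
    batch_effect: tuple = ("normal", 0.15),
    library_sizes: tuple = ("lognormal", 5e6, 0.2),
    batches: Mapping[str, str] | None = None,
    baseline_log_mean: tuple = (np.log(200.0), 1.5),
    seed: int | np.random.Generator | None = None,
) -> CountMatrix:
    """Simulate a gamma-Poisson (negative binomial) count matrix.

    The default design mirrors a two-replicate evolve-and-resequence study:
    two reconstituted ancestral and two evolved populations of 19--22
    individuals, with library preparation confounded by lot (each lot holds
    one ancestral and one evolved population). Per gene g and individual i
    the count is Poisson with rate

        lib_i / 1e6 * mu_g * exp(batch_gb) * shift_g * Gamma(1/phi, phi)

    where the unit-mean gamma multiplier carries the biological
    across-individual variation (CV^2 = phi). DE genes in evolved
    populations have their mean multiplied by exp(±mean_shift_sd * sigma_g)
    where sigma_g = sqrt(trigamma(1/phi_g)) is the generating ancestral
    biological SD on the natural-log scale. Evolved-population dispersions
    are multiplied by ``variance_factor`` (scalar for all genes, or a
    per-gene vector), emulating the drift-driven loss of expression variance.
    """
    rng = _as_rng(seed)
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    design = dict(DEFAULT_DESIGN if design is None else design)
    batches = dict(DEFAULT_BATCHES if batches is None else batches)
    for pop in design:
        batches.setdefault(pop, "lot1")

    phi = _dispersions(dispersion_model, n_genes, rng)
    vfac = np.broadcast_to(np.asarray(variance_factor, dtype=float), (n_genes,)).copy()
    if np.any(vfac <= 0):
        raise ValueError("variance_factor must be positive")

    mu = np.exp(rng.normal(baseline_log_mean[0], baseline_log_mean[1], size=n_genes))

    n_de = int(round(de_fraction * n_genes))
    de_label = np.zeros(n_genes, dtype=bool)
    de_label[rng.choice(n_genes, size=n_de, replace=False)] = True
    sigma_log = np.sqrt(polygamma(1, 1.0 / phi))
    shift_sign = rng.choice([-1.0, 1.0], size=n_genes)
    log_shift = np.where(de_label, mean_shift_sd * sigma_log * shift_sign, 0.0)

    batch_names = sorted(set(batches.values()))
    if batch_effect[0] != "normal":
        raise ValueError("batch_effect must be ('normal', sd)")
    batch_offsets = {
        b: rng.normal(0.0, float(batch_effect[1]), size=n_genes) for b in batch_names
    }

    if library_sizes[0] != "lognormal":
        raise ValueError("library_sizes must be ('lognormal', median, sdlog)")
    lib_median, lib_sdlog = float(library_sizes[1]), float(library_sizes[2])
    if lib_median <= 0:
        raise ValueError("library size must be positive")

    cols, rows_samples = [], []
    for pop, n_ind in design.items():
        if n_ind < 1:
            raise ValueError(f"population {pop!r} needs at least one individual")
        evolved = pop.startswith("evo")
        batch = batches[pop]
        pop_phi = phi * vfac if evolved else phi
        base = mu * np.exp(batch_offsets[batch])
        if evolved:
            base = base * np.exp(log_shift)
        libs = lib_median * np.exp(rng.normal(0.0, lib_sdlog, size=n_ind))
        for j in range(n_ind):
            bio = rng.gamma(1.0 / pop_phi, pop_phi)
            lam = libs[j] / 1e6 * base * bio
            cols.append(rng.poisson(lam))
            rows_samples.append(
                {"individual_id": f"{pop}_{j}", "population": pop, "batch": batch}
            )
    counts = np.column_stack(cols).astype(np.int64)
    samples = pd.DataFrame(rows_samples)
    true_params = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n_genes)],
            "baseline_mean": mu,
            "dispersion": phi,
            "mean_shift_sd": np.where(de_label, mean_shift_sd * shift_sign, 0.0),
            "variance_factor": vfac,
        }
    )
    return CountMatrix(counts, samples, de_label=de_label, true_params=true_params)


def write_count_matrix(cm: CountMatrix, prefix: str | Path) -> None:
    """Write counts, sample sheet, and (if present) DE labels as TSVs."""
    prefix = Path(prefix)
    df = pd.DataFrame(cm.counts, index=cm.genes, columns=cm.samples["individual_id"])
    df.index.name = "gene_id"
    df.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    cm.samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index=False)
    if cm.de_label is not None:
        pd.DataFrame({"gene_id": cm.genes, "de_status": cm.de_label.astype(int)}).to_csv(
            prefix.with_suffix(".labels.tsv"), sep="\t", index=False
        )


def read_count_matrix(
    counts_tsv: str | Path,
    samples_tsv: str | Path,
    labels_tsv: str | Path | None = None,
) -> CountMatrix:
    df = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    samples = pd.read_csv(samples_tsv, sep="\t")
    de = None
    if labels_tsv is not None:
        lab = pd.read_csv(labels_tsv, sep="\t").set_index("gene_id")
        de = lab.loc[df.index, "de_status"].to_numpy().astype(bool)
    return CountMatrix(
        df.to_numpy().astype(np.int64),
        samples,
        genes=df.index.to_numpy(),
        de_label=de,
    )
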