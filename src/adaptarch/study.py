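"""Study-design presets and headline analyses.

Bundles the canonical experimental-evolution conditions — 189 founder
haplotypes, N = 300, 100 generations of selection (103 to the sampling
point), gamma effect sizes standardized to 1/M with a -0.7
frequency--effect correlation, the mild optimum shift (a = 1) over the
effect-shape x fitness-width grid, heritabilities from the default
distribution — into reusable drivers for the ensemble simulations and the
headline power numbers.
"""

from __future__ import annotations

import numpy as np

from .forward_sim import FitnessRegime, simulate_trait_ensemble
from .inference_power import group_power, single_trait_power
from .synthetic_data import HaplotypePanel, generate_founder_haplotypes
from .variance_dynamics import TraitTrajectory

__all__ = [
    "MILD_SHAPES",
    "MILD_WIDTHS",
    "default_panel",
    "neutral_reference_ensemble",
    "neutral_mean_F",
    "drift_exceedance_percent",
    "mild_shift_power_by_combo",
    "five_locus_group_power",
]

MILD_SHAPES = (0.5, 2.5, 100.0)
MILD_WIDTHS = (1.8, 3.6, 5.4)
DEFAULT_N = 300
SELECTION_GENERATIONS = 100
SAMPLING_GENERATION = 103
#: neutral reference architecture: the variance-decay pattern under
#: neutrality is insensitive to the architecture, so a mid-grid locus count
#: is used for the reference ensemble
NEUTRAL_M = 50
NEUTRAL_SHAPE = 2.5


def default_panel(seed: int = 0, n_loci: int = 2000) -> HaplotypePanel:
    """The 189-founder panel on the default 5-arm map."""
    return generate_founder_haplotypes(189, n_loci, ("beta", 1.0, 3.0), seed=seed)


def neutral_reference_ensemble(
    panel: HaplotypePanel,
    n_traits: int = 1000,
    seed: int = 0,
    generations: int = SAMPLING_GENERATION,
    record=(1, 100, 103),
    store_phenotypes=(1, 100),
) -> list[TraitTrajectory]:
    """Neutral traits evolved to the sampling generation (103)."""
    return simulate_trait_ensemble(
        panel, n_traits, M=NEUTRAL_M, shape=NEUTRAL_SHAPE,
        regime=FitnessRegime.neutral(), N=DEFAULT_N, generations=generations,
        record=record, store_phenotypes=store_phenotypes, seed=seed,
    )


def neutral_mean_F(
    ensemble, generation: int = SELECTION_GENERATIONS
) -> tuple[float, float]:
    """Mean variance change of a neutral ensemble and its Monte-Carlo SE."""
    F = np.array([t.F(generation) for t in ensemble])
    return float(F.mean()), float(F.std(ddof=1) / np.sqrt(F.size))


def drift_exceedance_percent(
    ensemble, generation: int = SAMPLING_GENERATION
) -> float:
    """Percent of traits whose mean drifted >= 1 ancestral phenotypic SD."""
    shift = np.array(
        [abs(t.mean_at(generation) - t.mean_at(1)) / np.sqrt(t.var_at(1)) for t in ensemble]
    )
    return float((shift >= 1.0).mean() * 100.0)


def mild_shift_power_by_combo(
    panel: HaplotypePanel,
    n_traits_total: int = 1000,
    F_neutral: float = 0.9,
    seed: int = 0,
    M: int = 5,
    generations: int = SELECTION_GENERATIONS,
    alpha: float = 0.05,
) -> dict[tuple[float, float], float]:
    """Census single-trait F-test power per mild-shift parameter combination.

    ``n_traits_total`` traits with M contributing loci are spread evenly over
    the 9 combinations of effect-size shape and fitness width (a = 1
    throughout); each trait is tested on its full-population variances at
    generations 1 and ``generations`` against ``F_neutral``. The power to
    rule out an architecture of <= M loci *whatever the nuisance parameters*
    is the minimum of these per-combination powers.
    """
    combos = [(s, b) for s in MILD_SHAPES for b in MILD_WIDTHS]
    per = [n_traits_total // len(combos)] * len(combos)
    for i in range(n_traits_total - sum(per)):
        per[i] += 1
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(combos))
    powers = {}
    for (shape, b), n_traits, s in zip(combos, per, seeds):
        ens = simulate_trait_ensemble(
            panel, n_traits, M=M, shape=shape,
            regime=FitnessRegime.single_trait(a=1.0, b=b),
            N=DEFAULT_N, generations=generations, record=(1, generations),
            seed=s,
        )
        powers[(shape, b)] = single_trait_power(
            ens, generation=generations, F_neutral=F_neutral, n=None, alpha=alpha
        )
    return powers


def five_locus_group_power(
    panel: HaplotypePanel,
    neutral_ensemble,
    n_selected: int = 1000,
    seed: int = 0,
    n: int = 20,
    iterations: int = 100,
    shape: float = 2.5,
    b: float = 3.6,
    generations: int = SELECTION_GENERATIONS,
) -> float:
    """Group t-test power: 5-locus selected traits vs the neutral ensemble.

    Selected traits use the mild shift (a = 1) with the reference effect
    shape and fitness width; per iteration every trait's F is re-estimated
    from ``n`` sampled individuals at generations 1 and 100.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    root = ss.spawn(2)
    selected = simulate_trait_ensemble(
        panel, n_selected, M=5, shape=shape,
        regime=FitnessRegime.single_trait(a=1.0, b=b),
        N=DEFAULT_N, generations=generations, record=(1, generations),
        store_phenotypes=(1, generations), seed=root[0],
    )
    return group_power(
        selected, neutral_ensemble, generation=generations,
        n=n, iterations=iterations, seed=np.random.default_rng(root[1]),
    )
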