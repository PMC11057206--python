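"""Statistical inference of adaptive architecture from variance dynamics.

Two complementary tests are provided. The single-trait F-test asks whether
one trait lost more phenotypic variance than expected under neutrality
(neutral F ~ 0.9 after 100 generations at N = 300): the observed variance
ratio, divided by the neutral expectation, is referred to the lower tail of
an F(n-1, n-1) distribution. The group test compares the full distribution
of variance changes between a set of putatively selected traits and a
neutral reference set with a Welch t-test — far more powerful at realistic
sample sizes (~20 phenotyped individuals). Power is always estimated by
simulation, and the lower bound on the number of contributing loci is the
largest locus count that still produces a detectable variance change across
all simulated parameter combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .variance_dynamics import TraitTrajectory, sample_variance_ratio

__all__ = [
    "TestResult",
    "PowerResult",
    "single_trait_variance_test",
    "group_variance_test",
    "single_trait_power",
    "group_power",
    "power_grid",
    "lower_bound_loci",
    "replicate_correlation_test",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class PowerResult:
    """Power of a variance-change test under one simulated scenario."""

    M: int
    shape: float
    a: float
    b: float
    n: int
    N: int
    generation: int
    iterations: int
    power: float
    mode: str = "group"

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must be in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def single_trait_variance_test(
    s1_sq: float,
    sx_sq: float,
    n: int,
    F_neutral: float = 0.9,
    alpha: float = 0.05,
) -> TestResult:
    """One-sided F-test for excess variance loss in a single trait.

    The statistic (sx^2 / s1^2) / F_neutral is referred to the lower tail of
    F(n-1, n-1); a small p-value means the trait lost significantly more
    variance than the neutral expectation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if F_neutral <= 0:
        raise ValueError("F_neutral must be positive")
    if s1_sq <= 0:
        raise ValueError("ancestral sample variance must be positive")
    statistic = (sx_sq / s1_sq) / F_neutral
    p = float(stats.f.cdf(statistic, n - 1, n - 1))
    return TestResult(statistic=float(statistic), p_value=p, significant=p < alpha)


def group_variance_test(
    F_selected: np.ndarray, F_neutral: np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Welch two-sample t-test between two distributions of variance changes."""
    F_selected = np.asarray(F_selected, dtype=float)
    F_neutral = np.asarray(F_neutral, dtype=float)
    if F_selected.size < 2 or F_neutral.size < 2:
        raise ValueError("both groups need at least 2 traits")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(F_selected, F_neutral, equal_var=False)
    if np.isnan(p):  # zero variance in both groups: no evidence of difference
        t, p = 0.0, 1.0
    return TestResult(statistic=float(t), p_value=float(p), significant=p < alpha)


def _phenos(traj: TraitTrajectory, generation: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        return traj.phenotypes[1], traj.phenotypes[generation]
    except KeyError:
        raise KeyError(
            f"trajectory lacks stored phenotypes at generations 1 and {generation}; "
            "pass store_phenotypes when simulating"
        )


def single_trait_power(
    trajectories: Sequence[TraitTrajectory],
    generation: int = 100,
    F_neutral: float = 0.9,
    n: int | None = None,
    iterations: int = 100,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Fraction of traits whose variance loss is detected by the F-test.

    With ``n`` = None the full census is used (each trait tested once on its
    population sample variances); otherwise each trait is tested
    ``iterations`` times on n randomly sampled individuals per time point
    and rejections are averaged.
    """
    rng = _as_rng(seed)
    hits, total = 0.0, 0
    for traj in trajectories:
        if n is None:
            res = single_trait_variance_test(
                traj.var_at(1), traj.var_at(generation), traj.meta.get("N", 300),
                F_neutral=F_neutral, alpha=alpha,
            )
            hits += res.significant
            total += 1
        else:
            p1, px = _phenos(traj, generation)
            for _ in range(iterations):
                s1 = np.var(rng.choice(p1, size=n, replace=False), ddof=1)
                sx = np.var(rng.choice(px, size=n, replace=False), ddof=1)
                res = single_trait_variance_test(s1, sx, n, F_neutral, alpha)
                hits += res.significant
                total += 1
    if total == 0:
        raise ValueError("no trajectories supplied")
    return hits / total


def group_power(
    selected: Sequence[TraitTrajectory],
    neutral: Sequence[TraitTrajectory],
    generation: int = 100,
    n: int = 20,
    iterations: int = 100,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Power of the group t-test with n phenotyped individuals per trait.

    Per iteration, every trait's variance change is re-estimated from a
    fresh sample of n individuals at generations 1 and ``generation``; the
    selected and neutral F distributions are compared by Welch's t-test and
    power is the fraction of significant iterations.
    """
    rng = _as_rng(seed)
    sel = [_phenos(t, generation) for t in selected]
    neu = [_phenos(t, generation) for t in neutral]

    def f_hat(pair):
        p1, px = pair
        s1 = np.var(rng.choice(p1, size=n, replace=False), ddof=1)
        sx = np.var(rng.choice(px, size=n, replace=False), ddof=1)
        return sx / s1

    hits = 0
    for _ in range(iterations):
        F_sel = np.array([f_hat(p) for p in sel])
        F_neu = np.array([f_hat(p) for p in neu])
        hits += group_variance_test(F_sel, F_neu, alpha).significant
    return hits / iterations


def power_grid(
    scenarios: Sequence[Mapping],
    mode: str = "group",
    n: int | None = 20,
    generation: int = 100,
    iterations: int = 100,
    F_neutral: float = 0.9,
    alpha: float = 0.05,
    seed=None,
) -> list[PowerResult]:
    """Estimate power for each scenario of a parameter grid.

    Each scenario is a mapping with keys ``M, shape, a, b, N, selected`` and
    (for group mode) ``neutral``, the last two being trajectory ensembles
    simulated under those parameters.
    """
    if mode not in ("group", "single"):
        raise ValueError("mode must be 'group' or 'single'")
    rng = _as_rng(seed)
    results = []
    for sc in scenarios:
        if "selected" not in sc:
            raise KeyError("scenario lacks a simulated 'selected' ensemble")
        if mode == "group":
            if "neutral" not in sc:
                raise KeyError("group mode needs a 'neutral' ensemble per scenario")
            power = group_power(
                sc["selected"], sc["neutral"], generation=generation,
                n=n, iterations=iterations, alpha=alpha, seed=rng,
            )
        else:
            power = single_trait_power(
                sc["selected"], generation=generation, F_neutral=F_neutral,
                n=n, iterations=iterations, alpha=alpha, seed=rng,
            )
        results.append(
            PowerResult(
                M=sc["M"], shape=sc.get("shape", np.nan), a=sc.get("a", np.nan),
                b=sc.get("b", np.nan), n=(n if n is not None else sc.get("N", 0)),
                N=sc.get("N", 300), generation=generation,
                iterations=iterations, power=power, mode=mode,
            )
        )
    return results


def lower_bound_loci(
    results: Sequence[PowerResult],
    criterion: Callable[[PowerResult], bool] | float = 0.8,
) -> int | None:
    """Largest locus count whose variance change stays detectable.

    A locus count M qualifies when ``criterion`` holds for *every* parameter
    combination simulated at that M (criterion is a power threshold or a
    predicate on PowerResult). The bound is the largest M such that M and
    every smaller simulated M qualify — i.e. the architecture sizes that can
    be ruled out when no variance change is observed. Returns None when even
    the smallest M fails.
    """
    if not results:
        raise ValueError("empty results")
    if not callable(criterion):
        thr = float(criterion)
        criterion = lambda r: r.power >= thr  # noqa: E731
    by_m: dict[int, bool] = {}
    for r in results:
        by_m[r.M] = by_m.get(r.M, True) and criterion(r)
    bound = None
    for m in sorted(by_m):
        if by_m[m]:
            bound = m
        else:
            break
    return bound


def replicate_correlation_test(
    F_rep1: np.ndarray,
    F_rep2: np.ndarray,
    de_label: np.ndarray,
    n_perm: int = 1000,
    seed=None,
) -> dict:
    """Is the between-replicate correlation of variance changes higher for DE genes?

    Computes the Pearson correlation of per-gene F values between two
    independently evolved replicates, separately for DE and non-DE genes,
    and builds a null by repeatedly drawing |DE| random non-DE genes; the
    p-value is the fraction of null draws whose correlation is at least the
    DE correlation. A small p indicates that variance evolution of DE genes
    is replicated (consistent with shared selection), while non-DE genes
    behave like independent drift.
    """
    F1 = np.asarray(F_rep1, dtype=float)
    F2 = np.asarray(F_rep2, dtype=float)
    de = np.asarray(de_label, dtype=bool)
    if not (F1.shape == F2.shape == de.shape):
        raise ValueError("inputs must be aligned per gene")
    n_de = int(de.sum())
    non_idx = np.flatnonzero(~de)
    if n_de == 0 or non_idx.size == 0:
        raise ValueError("both DE and non-DE classes must be non-empty")
    if n_de > non_idx.size:
        raise ValueError("more DE genes than non-DE genes to draw from")
    rng = _as_rng(seed)
    r_de = float(np.corrcoef(F1[de], F2[de])[0, 1])
    r_nonde = float(np.corrcoef(F1[~de], F2[~de])[0, 1])
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(non_idx, size=n_de, replace=False)
        null[i] = np.corrcoef(F1[pick], F2[pick])[0, 1]
    p = float((np.sum(null >= r_de) + 1) / (n_perm + 1))
    return {"r_de": r_de, "r_nonde": r_nonde, "p_value": p, "null": null}
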