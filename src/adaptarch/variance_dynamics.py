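"""Variance-change statistics F = sigma_x^2 / sigma_1^2 and ensemble summaries.

F compares the phenotypic variance at an evolved generation x with the
ancestral (generation-1) variance of the same population; F < 1 indicates a
loss of variance, the signature of an oligogenic response (or, more slowly,
of drift-driven fixation). F is always reported as evolved over ancestral,
so "variance dropped to 84%" reads F = 0.84.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitTrajectory",
    "VarianceChange",
    "variance_ratio",
    "sample_variance_ratio",
    "trajectory_band",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TraitTrajectory:
    """Per-generation phenotypic mean/variance records of one simulated trait.

    ``phenotypes`` optionally stores the full per-individual phenotype vector
    at selected generations (needed for finite-sample resampling of F).
    """

    generations: np.ndarray
    pheno_mean: np.ndarray
    pheno_var: np.ndarray
    geno_var: np.ndarray
    phenotypes: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=int)
        self.pheno_mean = np.asarray(self.pheno_mean, dtype=float)
        self.pheno_var = np.asarray(self.pheno_var, dtype=float)
        self.geno_var = np.asarray(self.geno_var, dtype=float)
        n = self.generations.size
        if not (self.pheno_mean.size == self.pheno_var.size == self.geno_var.size == n):
            raise ValueError("trajectory fields must have equal length")
        if np.any(self.pheno_var < 0) or np.any(self.geno_var < 0):
            raise ValueError("variances must be non-negative")
        if 1 not in self.generations:
            raise ValueError("generation 1 (the ancestral state) must be recorded")

    def _index(self, generation: int) -> int:
        idx = np.flatnonzero(self.generations == generation)
        if idx.size == 0:
            raise KeyError(f"generation {generation} was not recorded")
        return int(idx[0])

    def mean_at(self, generation: int) -> float:
        return float(self.pheno_mean[self._index(generation)])

    def var_at(self, generation: int) -> float:
        return float(self.pheno_var[self._index(generation)])

    def F(self, generation: int) -> float:
        """Variance change sigma_x^2 / sigma_1^2 at the requested generation."""
        s1 = self.var_at(1)
        if s1 == 0.0:
            raise ZeroDivisionError("ancestral phenotypic variance is zero")
        return self.var_at(generation) / s1

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "generation": self.generations,
                "pheno_mean": self.pheno_mean,
                "pheno_var": self.pheno_var,
                "geno_var": self.geno_var,
            }
        )
        df["F"] = self.pheno_var / self.var_at(1)
        for k, v in self.meta.items():
            df[k] = v
        return df


@dataclass(frozen=True)
class VarianceChange:
    F: float
    generation: int
    estimator: str = "population"

    def __post_init__(self):
        if self.F < 0:
            raise ValueError("F must be >= 0")


def variance_ratio(traj: TraitTrajectory, x: int) -> VarianceChange:
    """Population variance change F = sigma_x^2 / sigma_1^2 of a trajectory."""
    return VarianceChange(F=traj.F(x), generation=int(x), estimator="population")


def sample_variance_ratio(
    pheno_t1: np.ndarray,
    pheno_tx: np.ndarray,
    n: int = 20,
    iterations: int = 100,
    seed=None,
) -> np.ndarray:
    """Finite-sample estimates of F from n individuals per time point.

    Per iteration, n individuals are drawn without replacement,
    independently at the two time points (distinct flies are phenotyped at
    each generation), and F-hat is the ratio of unbiased sample variances.
    """
    pheno_t1 = np.asarray(pheno_t1, dtype=float)
    pheno_tx = np.asarray(pheno_tx, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    if n > pheno_t1.size or n > pheno_tx.size:
        raise ValueError("n exceeds the number of phenotyped individuals")
    rng = _as_rng(seed)
    out = np.empty(iterations)
    for i in range(iterations):
        s1 = np.var(rng.choice(pheno_t1, size=n, replace=False), ddof=1)
        sx = np.var(rng.choice(pheno_tx, size=n, replace=False), ddof=1)
        out[i] = sx / s1
    return out


def trajectory_band(ensemble: Sequence[TraitTrajectory]) -> pd.DataFrame:
    """Mean F and 95% envelope per generation across an ensemble of traits.

    All trajectories must share a recording schedule; returns one row per
    generation with columns mean_F, q2_5, q97_5 and n_traits.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 trajectories")
    gens = ensemble[0].generations
    for t in ensemble[1:]:
        if not np.array_equal(t.generations, gens):
            raise ValueError("trajectories have ragged recording schedules")
    F = np.stack([t.pheno_var / t.var_at(1) for t in ensemble])
    return pd.DataFrame(
        {
            "generation": gens,
            "mean_F": F.mean(axis=0),
            "q2_5": np.quantile(F, 0.025, axis=0),
            "q97_5": np.quantile(F, 0.975, axis=0),
            "n_traits": len(ensemble),
        }
    )


def plot_trajectory_bands(bands: dict, ax=None, colors=None):
    """Draw mean-F curves with translucent 95% bands, one per labelled ensemble."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, (label, band) in enumerate(bands.items()):
        c = None if colors is None else colors[i % len(colors)]
        line, = ax.plot(band["generation"], band["mean_F"], label=label, color=c)
        ax.fill_between(
            band["generation"], band["q2_5"], band["q97_5"],
            alpha=0.2, color=line.get_color(),
        )
    ax.axhline(1.0, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("generation")
    ax.set_ylabel("phenotypic variance change (F)")
    ax.legend(fontsize=8)
    return ax
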