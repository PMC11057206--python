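"""Vectorized gamete formation under the Markov (Haldane, no-interference) recombination model."""

from __future__ import annotations

import numpy as np


def meiosis(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    rfrac: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per selected parent.

    Parameters
    ----------
    haplotypes
        Array of shape (2, N, L): the two haplotypes of each of N diploids.
    parent_idx
        Length-K integer array of parent indices (one gamete per entry).
    rfrac
        Length L-1 recombination fractions between adjacent loci, each in
        [0, 0.5]. A fraction of 0.5 corresponds to free recombination
        (e.g. a chromosome boundary).
    rng
        Source of randomness.

    Returns
    -------
    (K, L) array of gamete haplotypes.

    Notes
    -----
    The starting phase at the first locus is uniform, and the phase switches
    between adjacent loci with probability equal to the recombination
    fraction. This Markov chain is exactly the marginal inheritance pattern
    of a Poisson crossover process mapped through Haldane's function, so mean
    crossover counts per gamete equal the genetic map length in Morgans.
    """
    hap_a = haplotypes[0, parent_idx, :]
    hap_b = haplotypes[1, parent_idx, :]
    k, n_loci = hap_a.shape
    draws = rng.random((k, n_loci))
    switch = np.empty((k, n_loci), dtype=bool)
    switch[:, 0] = draws[:, 0] < 0.5
    if n_loci > 1:
        switch[:, 1:] = draws[:, 1:] < rfrac[None, :]
    # parity of accumulated switches picks which parental haplotype is copied
    phase = (np.cumsum(switch, axis=1) & 1).astype(bool)
    return np.where(phase, hap_b, hap_a)


def haldane(morgans: np.ndarray | float) -> np.ndarray | float:
    """Map a genetic distance in Morgans to a recombination fraction.

    Haldane's function r = (1 - exp(-2d))/2 assumes crossovers occur as a
    Poisson process without interference; r saturates at 0.5.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(morgans, dtype=float)))


def inverse_haldane(rfrac: np.ndarray | float) -> np.ndarray | float:
    """Morgan distance implied by a recombination fraction (r < 0.5)."""
    r = np.asarray(rfrac, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fractions must lie in [0, 0.5)")
    return -0.5 * np.log(1.0 - 2.0 * r)
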