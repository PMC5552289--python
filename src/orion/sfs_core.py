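"""Folded site-frequency spectra and the Orion regional intolerance score.

The Orion score measures how strongly the standing variation observed in a
cohort of ``n`` diploid genomes departs from the variation expected under
neutral evolution.  Both sides of the comparison are folded site-frequency
spectra (SFS): vectors of length ``n + 1`` whose ``i``-th entry counts the
sites at which ``i`` copies of the minor allele segregate in the cohort
(index 0 holds the monomorphic sites).

Under the standard neutral model the expected number of segregating sites
with unfolded allele count ``j`` in ``2n`` sampled chromosomes is
``theta / j`` with ``theta = 4 * Ne * mu``.  Folding sums the ``j`` and
``2n - j`` classes, halving the self-paired class ``j = n``:

    psi_i = theta * (1/i + 1/(2n - i)) / (1 + delta_{i, 2n-i}),  i = 1..n

and the monomorphic class absorbs the remainder of the region,
``psi_0 = kappa - sum(psi_i)``, where ``kappa`` is the number of assessed
bases.  The score is the weighted mean of the pointwise difference
(observed minus expected), weighted towards rare alleles, divided by theta
to remove the region's mutability, and rescaled for readability:

    score = scale * sum_i w_i * (eta_i - psi_i) / theta

Depleted (intolerant) regions score high; regions with an excess of common
variation score low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "CohortModel",
    "SFSVector",
    "NeutralModel",
    "WeightVector",
    "expected_sfs",
    "observed_sfs",
    "weight_vector",
    "orion_score",
]


@dataclass(frozen=True)
class CohortModel:
    """Cohort size and population-genetic constants.

    Parameters
    ----------
    n_samples
        Number of diploid samples in the cohort.
    effective_pop_size
        Effective population size ``Ne`` used by the neutral model.
    score_scale
        Multiplier applied to the final score purely for readability.
    """

    n_samples: int
    effective_pop_size: int = 10_000
    score_scale: float = 100_000.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.effective_pop_size <= 0:
            raise ValueError("effective_pop_size must be positive")
        if self.score_scale <= 0:
            raise ValueError("score_scale must be positive")

    @property
    def n_alleles(self) -> int:
        """Total allele count ``2n`` in the cohort."""
        return 2 * self.n_samples


@dataclass
class SFSVector:
    """A folded site-frequency spectrum over a region of ``region_length`` bases.

    ``counts[i]`` is the number of sites whose folded minor-allele count is
    ``i``; ``counts[0]`` holds the monomorphic sites so that the vector
    conserves the region length: ``sum(counts) == region_length``.
    """

    counts: np.ndarray
    region_length: float
    kind: Literal["observed", "expected"]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.region_length < 0:
            raise ValueError("region_length must be non-negative")
        if self.kind == "observed" and np.any(self.counts < 0):
            raise ValueError("observed SFS counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.counts) - 1

    @property
    def segregating(self) -> float:
        """Number of polymorphic sites (classes i >= 1)."""
        return float(self.counts[1:].sum())


@dataclass(frozen=True)
class NeutralModel:
    """Population-scaled mutation rate of a region: ``theta = 4 * Ne * mu``."""

    theta: float
    mu_region: float

    def __post_init__(self) -> None:
        if self.theta < 0 or self.mu_region < 0:
            raise ValueError("theta and mu_region must be non-negative")


@dataclass
class WeightVector:
    """Rare-variant-favouring weights ``raw[i] = 2n / (i + 1)``, normalized to sum 1."""

    raw: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = self.raw / self.raw.sum()


def folded_class_shape(n_samples: int) -> np.ndarray:
    """Per-class neutral SFS shape ``q_i`` such that ``psi_i = theta * q_i``.

    ``q_i = (1/i + 1/(2n - i)) / (1 + delta_{i, 2n-i})`` for ``i = 1..n``;
    the returned array has length ``n_samples`` (classes 1..n).
    """
    n2 = 2 * n_samples
    i = np.arange(1, n_samples + 1, dtype=float)
    delta = (i == n2 - i).astype(float)
    return (1.0 / i + 1.0 / (n2 - i)) / (1.0 + delta)


def expected_sfs(cohort: CohortModel, mu_region: float, kappa: float) -> SFSVector:
    """Neutral-theory expected folded SFS for a region.

    Parameters
    ----------
    cohort
        Cohort size and ``Ne``.
    mu_region
        Haploid per-generation mutation rate summed over the region's
        assessed bases.
    kappa
        Number of assessed bases; anchors the monomorphic class.

    Raises
    ------
    ValueError
        If the expected number of segregating sites exceeds ``kappa``
        (mutation rate and region length are inconsistent).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if mu_region < 0:
        raise ValueError("mu_region must be non-negative")
    theta = 4.0 * cohort.effective_pop_size * mu_region
    counts = np.zeros(cohort.n_samples + 1)
    counts[1:] = theta * folded_class_shape(cohort.n_samples)
    seg = counts[1:].sum()
    if seg > kappa:
        raise ValueError(
            f"expected segregating sites ({seg:.4g}) exceed region length "
            f"({kappa:.4g}); mu_region and kappa are inconsistent"
        )
    counts[0] = kappa - seg
    return SFSVector(counts=counts, region_length=float(kappa), kind="expected")


def observed_sfs(
    folded_allele_counts: Iterable[int], kappa: float, cohort: CohortModel
) -> SFSVector:
    """Tally observed folded minor-allele counts into an SFS.

    ``folded_allele_counts`` holds one entry per variant site, each already
    folded into ``1..n``; the monomorphic class is ``kappa`` minus the number
    of variant sites.
    """
    ac = np.asarray(list(folded_allele_counts), dtype=int)
    n = cohort.n_samples
    if ac.size and (ac.min() < 0 or ac.max() > n):
        bad = ac[(ac < 0) | (ac > n)][0]
        raise ValueError(
            f"folded allele count {bad} outside [0, n={n}]; input may be unfolded"
        )
    if ac.size > kappa:
        raise ValueError(f"{ac.size} variant sites exceed region length {kappa}")
    counts = np.bincount(ac[ac >= 1], minlength=n + 1).astype(float)
    counts[0] = kappa - (ac >= 1).sum()
    return SFSVector(counts=counts, region_length=float(kappa), kind="observed")


def weight_vector(cohort: CohortModel) -> WeightVector:
    """Weights ``2n / (i + 1)`` for SFS classes ``i = 0..n``, favouring rare alleles."""
    i = np.arange(cohort.n_samples + 1, dtype=float)
    return WeightVector(raw=cohort.n_alleles / (i + 1.0))


def orion_score(
    observed: SFSVector,
    expected: SFSVector,
    weights: WeightVector,
    theta: float,
    scale: float = 100_000.0,
) -> float:
    """Weighted mean SFS departure, normalized by theta and rescaled.

    ``score = scale * sum_i w_i * (eta_i - psi_i) / theta`` with normalized
    weights ``w``.  A higher score marks a more intolerant (variation-
    depleted) region.

    Raises
    ------
    ValueError
        If ``theta == 0`` (a window with no mutability has no defined score)
        or the two spectra are incompatible.
    """
    if theta <= 0:
        raise ValueError("theta must be positive; zero-mutability window has no score")
    if len(observed.counts) != len(expected.counts):
        raise ValueError("observed and expected SFS lengths differ")
    if not np.isclose(observed.region_length, expected.region_length):
        raise ValueError(
            f"region length mismatch: observed kappa={observed.region_length}, "
            f"expected kappa={expected.region_length}"
        )
    diff = observed.counts - expected.counts
    return float(scale * (weights.normalized @ diff) / theta)
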