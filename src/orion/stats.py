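"""Validation statistics: permuted Mann-Whitney U, Fisher exact enrichment,
and chromosome-balanced random score sampling.

The permutation wrapper guards the Mann-Whitney test against its asymptotic
p-value being taken at face value on heavily tied, oddly shaped score
distributions: the labels are reshuffled ``n_p`` times and the reported
p-value is ``(G + 1) / (n_p + 1)``, where ``G`` counts permutations whose
p-value is less than or equal to the observed one.  Its floor with 1,000
permutations is therefore 1/1001 ≈ 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from orion.sfs_core import CohortModel
from orion.regions import OrionRegion
from orion.scan import OrionScoreTrack
from orion.tracks_io import IntervalSet

__all__ = [
    "ContingencyTable2x2",
    "PermutationTestResult",
    "permuted_mann_whitney",
    "fisher_enrichment",
    "sample_random_scores",
    "variants_in_regions",
    "maf_exclusion_threshold",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: case/control; columns: in-region/out-of-region."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b == 0 and self.c + self.d == 0:
            raise ValueError("at least one row must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class PermutationTestResult:
    observed_p: float
    G: int
    n_permutations: int

    @property
    def permuted_p(self) -> float:
        return (self.G + 1) / (self.n_permutations + 1)


def _mw_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0  # fully tied: no evidence of any shift
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def permuted_mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationTestResult:
    """Label-permutation Mann-Whitney U test.

    Computes the observed two-sided Mann-Whitney p, then reshuffles the
    group labels ``n_permutations`` times; ``G`` is the number of
    permutations whose p-value the observed p equals or exceeds, and the
    permutation p-value is ``(G + 1) / (n_permutations + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed_p = _mw_two_sided_p(x, y)
    pooled = np.concatenate([x, y])
    G = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if observed_p >= _mw_two_sided_p(perm[: x.size], perm[x.size :]):
            G += 1
    return PermutationTestResult(observed_p=observed_p, G=G, n_permutations=n_permutations)


def fisher_enrichment(table: ContingencyTable2x2) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p (point-probability method).

    The odds ratio is ``(a*d)/(b*c)``; infinite when ``b*c == 0`` with
    ``a*d > 0``, and 1 for the all-corners-zero degenerate product.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = float(sps.fisher_exact(table.as_array(), alternative="two-sided").pvalue)
    return float(odds), p


def variants_in_regions(
    variant_positions: Sequence[tuple[str, int]],
    regions: Sequence[OrionRegion] | IntervalSet,
) -> tuple[int, int]:
    """Count variants inside/outside regions (0-based positions, half-open
    interval membership)."""
    if not isinstance(regions, IntervalSet):
        regions = IntervalSet([(r.chrom, r.start, r.end) for r in regions])
    inside = sum(1 for chrom, pos in variant_positions if regions.contains(chrom, pos))
    return inside, len(list(variant_positions)) - inside


def maf_exclusion_threshold(cohort: CohortModel) -> float:
    """Minimal nonzero minor-allele frequency representable in the cohort.

    External variants at or above this frequency may be present in the
    scoring cohort itself and must be excluded from benign/control sets.
    """
    return 1.0 / cohort.n_alleles


def sample_random_scores(
    tracks: dict[str, OrionScoreTrack],
    k: int,
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, int, float]]:
    """Draw ``k`` scored positions, chromosome-first.

    Each draw first picks a chromosome uniformly, then a scored position
    uniformly within it, rejection-resampling draws that land in
    ``exclude`` — so chromosomes are represented roughly equally rather
    than in proportion to length.  Returns (chrom, 1-based position, score)
    tuples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(tracks)
    eligible: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pos = tracks[chrom].positions()
        if exclude is not None and pos.size:
            m = exclude.mask(chrom, tracks[chrom].length)
            pos = pos[~m[pos - 1]]
        if pos.size:
            eligible[chrom] = pos
    if not eligible:
        raise ValueError("no eligible scored positions outside the exclusion set")
    live = sorted(eligible)
    out: list[tuple[str, int, float]] = []
    while len(out) < k:
        chrom = live[rng.integers(len(live))]
        pos_arr = eligible[chrom]
        pos = int(pos_arr[rng.integers(pos_arr.size)])
        out.append((chrom, pos, float(tracks[chrom].score[pos - 1])))
    return out
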