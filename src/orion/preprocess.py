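"""Build the three scan input tracks from raw-ish inputs.

* a per-base haploid mutation-rate track from a trinucleotide-context rate
  matrix applied to a reference sequence;
* a coverage track: the fraction of cohort samples genotypable at GQ >= 20
  at each position;
* a folded minor-allele-count track from SNV site calls passing the quality
  rules (VQSR lowest-tranche exclusion; >= 50% of alleles genotyped at
  GQ >= 20; fractional AC projected onto the cohort, rounded and folded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from orion.sfs_core import CohortModel
from orion.tracks_io import PositionTrack

__all__ = [
    "TriNucRateMatrix",
    "SiteCall",
    "mutation_rate_track",
    "coverage_track",
    "allele_count_track",
    "fold_allele_count",
]

_BASES = "ACGT"
ALL_CONTEXTS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

GQ_THRESHOLD = 20.0
DEFAULT_TARGET_MEAN = 1.2e-8


class TriNucRateMatrix:
    """Haploid per-generation mutation rate of the center base of each of the
    64 trinucleotide contexts."""

    def __init__(self, rates: Mapping[str, float]) -> None:
        missing = set(ALL_CONTEXTS) - set(rates)
        if missing:
            raise ValueError(f"rate matrix missing {len(missing)} contexts, e.g. {sorted(missing)[:3]}")
        if any(r <= 0 for r in rates.values()):
            raise ValueError("all context rates must be > 0")
        self.rates = {ctx: float(rates[ctx]) for ctx in ALL_CONTEXTS}

    def normalized_to_mean(
        self, sequence: str, target_mean: float = DEFAULT_TARGET_MEAN
    ) -> "TriNucRateMatrix":
        """Rescale all rates so the mean over the sequence's assessed bases
        equals ``target_mean``."""
        track = mutation_rate_track(sequence, self)
        if len(track) == 0:
            raise ValueError("sequence has no assessable trinucleotide contexts")
        factor = target_mean / track.values.mean()
        return TriNucRateMatrix({c: r * factor for c, r in self.rates.items()})

    @classmethod
    def uniform(cls, rate: float) -> "TriNucRateMatrix":
        return cls({ctx: rate for ctx in ALL_CONTEXTS})

    @classmethod
    def read(cls, path: str) -> "TriNucRateMatrix":
        """Read a 2-column file: context<TAB>rate."""
        rates: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                ctx, rate = line.split()
                rates[ctx.upper()] = float(rate)
        return cls(rates)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for ctx in ALL_CONTEXTS:
                fh.write(f"{ctx}\t{self.rates[ctx]:.12g}\n")


@dataclass(frozen=True)
class SiteCall:
    """One SNV site summarized from cohort genotyping."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    fraction_alleles_genotyped: float  # fraction of cohort alleles at GQ >= 20
    fraction_nonref_of_covered: float  # non-ref fraction among covered alleles
    lowest_tranche_fail: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_alleles_genotyped <= 1.0:
            raise ValueError("fraction_alleles_genotyped outside [0, 1]")
        if not 0.0 <= self.fraction_nonref_of_covered <= 1.0:
            raise ValueError("fraction_nonref_of_covered outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1 and len(self.alt) == 1
            and self.ref in _BASES and self.alt in _BASES
        )


def mutation_rate_track(sequence: str, matrix: TriNucRateMatrix) -> PositionTrack:
    """Per-base mutation rate from the trinucleotide context centered on each base.

    The first and last base of the sequence and any base whose context
    contains an N get no value (value-absent, not zero).
    """
    seq = sequence.upper()
    positions, values = [], []
    for i in range(1, len(seq) - 1):
        ctx = seq[i - 1 : i + 2]
        if any(b not in _BASES for b in ctx):
            continue
        positions.append(i + 1)  # 1-based
        values.append(matrix.rates[ctx])
    return PositionTrack("", np.array(positions, dtype=np.int64), np.array(values))


def coverage_track(
    gq_by_position: Mapping[int, np.ndarray] | Iterable[tuple[int, np.ndarray]],
    n_samples: int,
    threshold: float = GQ_THRESHOLD,
) -> PositionTrack:
    """Fraction of samples with GQ >= threshold at each position.

    ``gq_by_position`` maps 1-based position to the per-sample GQ array
    (entries for samples with no genotype may be set negative or NaN).
    """
    items = gq_by_position.items() if isinstance(gq_by_position, Mapping) else gq_by_position
    positions, values = [], []
    for pos, gq in sorted(items):
        gq = np.asarray(gq, dtype=float)
        ok = np.sum(~np.isnan(gq) & (gq >= threshold))
        positions.append(pos)
        values.append(ok / n_samples)
    return PositionTrack("", np.array(positions, dtype=np.int64), np.array(values))


def fold_allele_count(ac: int, n_alleles: int) -> int:
    """Fold an allele count onto the minor side: ``min(ac, 2n - ac)``."""
    return min(ac, n_alleles - ac)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def allele_count_track(
    sites: Iterable[SiteCall],
    cohort: CohortModel,
    min_fraction_genotyped: float = 0.5,
    rounding: Literal["round", "floor", "fractional"] = "round",
) -> tuple[PositionTrack, dict[str, int]]:
    """Folded minor-allele-count track from SNV site calls.

    Filtering, in order: non-SNV records dropped; lowest-VQSR-tranche sites
    dropped; sites with < ``min_fraction_genotyped`` of cohort alleles at
    GQ >= 20 dropped.  The raw AC projects the non-reference fraction of
    covered alleles onto the full cohort (``frac * 2n``), is made integer
    per ``rounding`` (``round`` = half away from zero, ``floor``, or
    ``fractional`` = ceiling class) with a minimum of 1 for any polymorphic
    site, then folded; only folded AC >= 1 is emitted.  Multi-allelic sites
    (several records at one position) keep the highest-AC alternate.

    Returns the track and a tally of dropped/kept record counts.
    """
    stats = {"non_snv": 0, "tranche_fail": 0, "undercovered": 0,
             "folded_monomorphic": 0, "kept": 0}
    best: dict[int, int] = {}  # pos -> folded AC (max over alts)
    chrom = ""
    for site in sites:
        if not site.is_snv:
            stats["non_snv"] += 1
            continue
        if site.lowest_tranche_fail:
            stats["tranche_fail"] += 1
            continue
        if site.fraction_alleles_genotyped < min_fraction_genotyped:
            stats["undercovered"] += 1
            continue
        chrom = chrom or site.chrom
        ac_raw = site.fraction_nonref_of_covered * cohort.n_alleles
        if ac_raw == 0.0:
            stats["folded_monomorphic"] += 1
            continue
        if rounding == "round":
            ac = _round_half_away(ac_raw)
        elif rounding == "floor":
            ac = int(math.floor(ac_raw))
        elif rounding == "fractional":
            ac = int(math.ceil(ac_raw))
        else:
            raise ValueError(f"unknown rounding mode {rounding!r}")
        ac = max(1, ac)
        ac = fold_allele_count(ac, cohort.n_alleles)
        if ac > cohort.n_samples:  # impossible by construction
            raise AssertionError(f"folded AC {ac} > n at {site.chrom}:{site.pos}")
        if ac < 1:
            stats["folded_monomorphic"] += 1
            continue
        prev = best.get(site.pos)
        if prev is None:
            stats["kept"] += 1
            best[site.pos] = ac
        else:
            best[site.pos] = max(prev, ac)
    positions = np.array(sorted(best), dtype=np.int64)
    values = np.array([best[p] for p in positions], dtype=float)
    return PositionTrack(chrom, positions, values), stats
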