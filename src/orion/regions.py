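"""Detection of contiguous intolerant ("Orion") regions in a score track.

A region is a contiguous stretch of scored bases, 100-1000 bp by default,
whose mean and median score clear a floor and which contains no score below
a harder floor.  The default floors (-0.08 mean/median, -0.1 minimum) were
derived from the score populations of the most intolerant protein-coding
exons; `derive_thresholds` reproduces that calibration for any exon set.

The detector emits maximal, non-overlapping, criteria-satisfying intervals
deterministically: among all satisfying subintervals it repeatedly accepts
the longest (leftmost on ties), removes its bases, and recurses on the
remainder.  Satisfying runs longer than the length cap are therefore
clipped into cap-sized pieces rather than discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from orion.scan import OrionScoreTrack
from orion.tracks_io import IntervalSet

__all__ = [
    "RegionCriteria",
    "OrionRegion",
    "detect_regions",
    "derive_thresholds",
    "region_coverage_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionCriteria:
    """The five acceptance rules for an intolerant region."""

    min_length: int = 100
    max_length: int = 1000
    min_mean: float = -0.08
    min_median: float = -0.08
    min_score: float = -0.1

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")

    def satisfied_by(self, scores: np.ndarray) -> bool:
        """Check all five rules against the scores of one candidate interval."""
        k = len(scores)
        return (
            self.min_length <= k <= self.max_length
            and scores.min() >= self.min_score
            and scores.mean() >= self.min_mean
            and float(np.median(scores)) >= self.min_median
        )


@dataclass(frozen=True)
class OrionRegion:
    """A detected region with its score summary (0-based half-open coords)."""

    chrom: str
    start: int
    end: int
    mean: float
    median: float
    min: float
    max: float
    covered_size: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _best_in_segment(
    x: np.ndarray, criteria: RegionCriteria
) -> tuple[int, int] | None:
    """Longest (leftmost on ties) satisfying interval within a segment whose
    scores already all clear min_score.  Returns (start_offset, length)."""
    seg_len = len(x)
    if seg_len < criteria.min_length:
        return None
    s = pd.Series(x)
    # rolling stats prefilter with a hair of slack; exact arithmetic
    # (np.mean / np.median on the slice) decides threshold-borderline cases
    tol = 1e-9 * max(1.0, abs(criteria.min_mean), abs(criteria.min_median))
    for length in range(min(criteria.max_length, seg_len), criteria.min_length - 1, -1):
        roll = s.rolling(length)
        ok = (roll.mean().to_numpy()[length - 1 :] >= criteria.min_mean - tol) & (
            roll.median().to_numpy()[length - 1 :] >= criteria.min_median - tol
        )
        for hit in np.flatnonzero(ok):
            if criteria.satisfied_by(x[hit : hit + length]):
                return int(hit), length
    return None


def detect_regions(
    track: OrionScoreTrack, criteria: RegionCriteria = RegionCriteria()
) -> list[OrionRegion]:
    """All maximal non-overlapping criteria-satisfying regions of a track.

    Works on contiguous scored runs (computed or imputed positions) of the
    post-imputation, post-masking track.  Equivalent to exhaustively
    enumerating every satisfying subinterval and greedily accepting by
    (longer, then leftmost), skipping overlaps.
    """
    scored = track.scored
    x = track.score
    # contiguous scored runs, further split at positions below min_score:
    # any satisfying interval lies inside such a piece, making the min-score
    # rule implicit for all candidates.
    eligible = scored & (x >= criteria.min_score)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], eligible.view(np.int8), [0]))))
    segments: list[tuple[int, int]] = [
        (int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])
        if b - a >= criteria.min_length
    ]

    best: dict[tuple[int, int], tuple[int, int] | None] = {
        seg: _best_in_segment(x[seg[0] : seg[1]], criteria) for seg in segments
    }
    accepted: list[tuple[int, int]] = []
    while True:
        candidates = [
            (seg, hit) for seg, hit in best.items() if hit is not None
        ]
        if not candidates:
            break
        # global greedy: longest first, then leftmost absolute start
        seg, (off, length) = min(
            candidates, key=lambda c: (-c[1][1], c[0][0] + c[1][0])
        )
        start = seg[0] + off
        accepted.append((start, start + length))
        del best[seg]
        for sub in ((seg[0], start), (start + length, seg[1])):
            if sub[1] - sub[0] >= criteria.min_length:
                best[sub] = _best_in_segment(x[sub[0] : sub[1]], criteria)

    regions = []
    for start, end in sorted(accepted):
        s = x[start:end]
        regions.append(
            OrionRegion(
                chrom=track.chrom,
                start=start,
                end=end,
                mean=float(s.mean()),
                median=float(np.median(s)),
                min=float(s.min()),
                max=float(s.max()),
                covered_size=end - start,
            )
        )
    return regions


def derive_thresholds(
    tracks: Mapping[str, OrionScoreTrack] | OrionScoreTrack,
    exons: IntervalSet,
    sd_multiplier: float = 1.0,
    min_length: int = 100,
    max_length: int = 1000,
) -> RegionCriteria:
    """Calibrate region criteria from a reference set of intolerant exons.

    For each exon, the mean, median and minimum score over its scored bases
    are computed; each criterion is then the across-exon mean of that
    statistic plus ``sd_multiplier`` sample standard deviations.  Exons
    without any scored base are skipped with a warning.
    """
    by_chrom = {tracks.chrom: tracks} if isinstance(tracks, OrionScoreTrack) else tracks
    means, medians, mins = [], [], []
    for chrom, start, end in exons.intervals():
        track = by_chrom.get(chrom)
        if track is None:
            logger.warning("no score track for exon %s:%d-%d; skipped", chrom, start, end)
            continue
        sl = slice(max(0, start), min(track.length, end))
        s = track.score[sl][track.scored[sl]]
        if s.size == 0:
            logger.warning("exon %s:%d-%d has no scores; skipped", chrom, start, end)
            continue
        means.append(s.mean())
        medians.append(float(np.median(s)))
        mins.append(s.min())
    if len(means) < 2:
        raise ValueError(
            f"need >= 2 exons with scores to derive thresholds, got {len(means)}"
        )

    def _thresh(vals: list[float]) -> float:
        return float(np.mean(vals) + sd_multiplier * np.std(vals, ddof=1))

    return RegionCriteria(
        min_length=min_length,
        max_length=max_length,
        min_mean=_thresh(means),
        min_median=_thresh(medians),
        min_score=_thresh(mins),
    )


def region_coverage_fraction(
    regions: list[OrionRegion], universe: IntervalSet
) -> float:
    """Fraction of the universe's bases occupied by the regions."""
    if universe.total_length() == 0:
        raise ValueError("empty universe")
    region_set = IntervalSet([(r.chrom, r.start, r.end) for r in regions])
    return region_set.intersect(universe).total_length() / universe.total_length()


def write_regions_bed(regions: list[OrionRegion], path: str, header: str | None = None) -> None:
    """BED with summary columns: mean, median, min, max, covered_size."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write("#chrom\tstart\tend\tmean\tmedian\tmin\tmax\tcovered_size\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean:.6g}\t{r.median:.6g}"
                f"\t{r.min:.6g}\t{r.max:.6g}\t{r.covered_size}\n"
            )
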