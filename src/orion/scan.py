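"""Sliding-window genome scan producing per-base Orion scores.

For every center position whose full window lies inside the chromosome, the
window's observed folded SFS is compared with its neutral expectation and
the resulting score is assigned to the center base.  A site is *adequately
covered* when the fraction of samples genotypable at GQ >= 20 reaches
``min_site_coverage`` (default 0.7); a window is scored only when at least
``min_window_covered_fraction`` (default 0.5) of its bases are adequate.
Bases with no mutation-rate value (N contexts, chromosome ends) are
non-assessed: they contribute to neither kappa nor mu nor the observed
spectrum.

The scan is algebraically identical to composing ``observed_sfs`` /
``expected_sfs`` / ``orion_score`` per window but runs in O(L) via sliding
sums: with normalized weights ``w``, neutral class shape ``q_i``
(``psi_i = theta * q_i``) and per-window variant count ``V`` and summed
variant weight ``Sv = sum_sites w[AC]``,

    sum_i w_i (eta_i - psi_i) = -w_0 V + Sv + theta * (w_0 Q - W),
    Q = sum q_i,  W = sum w_i q_i,

so ``score = scale * (Sv - w_0 V) / theta + scale * (w_0 Q - W)``; note the
second term — the score of a window with no variants at all — is a constant
independent of the window's mutability.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from orion.sfs_core import CohortModel, folded_class_shape, weight_vector
from orion.tracks_io import IntervalSet, PositionTrack

__all__ = [
    "ScanConfig",
    "OrionScoreTrack",
    "FLAG_ABSENT",
    "FLAG_COMPUTED",
    "FLAG_IMPUTED",
    "FLAG_MASKED",
    "scan_chromosome",
    "impute_gaps",
    "mask_repeats",
    "compare_window_sizes",
    "depleted_window_score",
    "write_score_track",
    "read_score_track",
]

FLAG_ABSENT, FLAG_COMPUTED, FLAG_IMPUTED, FLAG_MASKED = 0, 1, 2, 3
_FLAG_NAMES = {FLAG_ABSENT: "absent", FLAG_COMPUTED: "computed",
               FLAG_IMPUTED: "imputed", FLAG_MASKED: "masked"}
_FLAG_CODES = {v: k for k, v in _FLAG_NAMES.items()}


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window scan parameters.

    ``kappa_mode`` selects whether the assessed region length kappa counts
    only adequately covered, rated bases (``covered``) or the nominal window
    size (``nominal``).
    """

    window_size: int = 501
    min_window_covered_fraction: float = 0.5
    min_site_coverage: float = 0.7
    max_impute_gap: int = 10
    kappa_mode: Literal["covered", "nominal"] = "covered"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd positive integer")
        for name in ("min_window_covered_fraction", "min_site_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_impute_gap < 0:
            raise ValueError("max_impute_gap must be non-negative")
        if self.kappa_mode not in ("covered", "nominal"):
            raise ValueError(f"unknown kappa_mode {self.kappa_mode!r}")

    @property
    def half(self) -> int:
        return (self.window_size - 1) // 2


@dataclass
class OrionScoreTrack:
    """Dense per-base scores for one chromosome (positions 1..length).

    ``score`` is NaN wherever ``flag`` is absent or masked; ``covered_fraction``
    holds the window coverage fraction of computed positions.
    """

    chrom: str
    score: np.ndarray
    covered_fraction: np.ndarray
    flag: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.score)
        if len(self.covered_fraction) != n or len(self.flag) != n:
            raise ValueError("score, covered_fraction and flag lengths differ")
        self.flag = np.asarray(self.flag, dtype=np.uint8)

    @property
    def length(self) -> int:
        return len(self.score)

    @property
    def scored(self) -> np.ndarray:
        """Boolean: positions carrying a score (computed or imputed)."""
        return (self.flag == FLAG_COMPUTED) | (self.flag == FLAG_IMPUTED)

    def positions(self) -> np.ndarray:
        """1-based positions carrying a score."""
        return np.flatnonzero(self.scored) + 1

    def tally(self) -> dict[str, int]:
        return {name: int(np.sum(self.flag == code)) for code, name in _FLAG_NAMES.items()}


def depleted_window_score(cohort: CohortModel, cfg: ScanConfig | None = None) -> float:
    """Score of a fully assessed window containing no variants.

    This is the maximum attainable score, ``scale * (w_0 Q - W)``; it
    depends only on the cohort size, not on the window's mutation rate.
    """
    w = weight_vector(cohort).normalized
    q = folded_class_shape(cohort.n_samples)
    return float(cohort.score_scale * (w[0] * q.sum() - w[1:] @ q))


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums of every length-w window of x (length len(x)-w+1)."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[w:] - c[:-w]


def scan_chromosome(
    rate: PositionTrack,
    coverage: PositionTrack,
    ac: PositionTrack,
    cohort: CohortModel,
    cfg: ScanConfig = ScanConfig(),
    chrom_length: int | None = None,
    chunk_size: int | None = None,
) -> OrionScoreTrack:
    """Score every eligible center position of one chromosome.

    All three tracks must be on the same chromosome.  ``chrom_length``
    defaults to the largest position seen in any track.  ``chunk_size``
    bounds the dense working set: the chromosome is processed in chunks
    (with window-sized margins) and the result is identical to a
    whole-chromosome scan.
    """
    chroms = {t.chrom for t in (rate, coverage, ac) if len(t)}
    if len(chroms) > 1:
        raise ValueError(f"tracks on different chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else rate.chrom
    if chrom_length is None:
        chrom_length = int(max((t.positions[-1] for t in (rate, coverage, ac) if len(t)),
                               default=0))
    L = chrom_length
    w, h = cfg.window_size, cfg.half
    n = cohort.n_samples

    weights = weight_vector(cohort).normalized
    q = folded_class_shape(n)
    Q = q.sum()
    W = float(weights[1:] @ q)
    w0 = float(weights[0])
    four_ne = 4.0 * cohort.effective_pop_size

    score = np.full(L, np.nan)
    covfrac = np.full(L, np.nan)
    flag = np.zeros(L, dtype=np.uint8)
    if L < w:
        return OrionScoreTrack(chrom, score, covfrac, flag)

    if chunk_size is None:
        chunk_size = L
    # centers c (0-based) range over [h, L-h-1]; process in chunks
    for a in range(h, L - h, chunk_size):
        b = min(a + chunk_size, L - h)  # centers [a, b)
        lo, hi = a - h, b + h  # dense base range [lo, hi)
        rate_d = np.zeros(hi - lo)
        rated = np.zeros(hi - lo, dtype=bool)
        sl = rate.slice(lo + 1, hi)
        rate_d[sl.positions - 1 - lo] = sl.values
        rated[sl.positions - 1 - lo] = True
        cov_sl = coverage.slice(lo + 1, hi)
        adequate = np.zeros(hi - lo, dtype=bool)
        adequate[cov_sl.positions - 1 - lo] = cov_sl.values >= cfg.min_site_coverage
        assessed = adequate & rated

        ac_sl = ac.slice(lo + 1, hi)
        ac_val = np.zeros(hi - lo)
        is_var = np.zeros(hi - lo, dtype=bool)
        acs = np.rint(ac_sl.values).astype(int)
        if acs.size and (acs.min() < 0 or acs.max() > n):
            raise ValueError(
                f"allele count outside [0, n={n}] in AC track (max {acs.max()}); "
                "input may be unfolded"
            )
        keep = acs >= 1
        ac_val[ac_sl.positions[keep] - 1 - lo] = acs[keep]
        is_var[ac_sl.positions[keep] - 1 - lo] = True
        is_var &= assessed  # only assessed sites enter the observed SFS
        site_w = np.zeros(hi - lo)
        idx = np.flatnonzero(is_var)
        site_w[idx] = weights[ac_val[idx].astype(int)]

        n_adequate = _sliding_sum(adequate.astype(float), w)
        n_assessed = _sliding_sum(assessed.astype(float), w)
        if cfg.kappa_mode == "covered":
            kappa = n_assessed
            mu = _sliding_sum(rate_d * assessed, w)
        else:
            kappa = np.full_like(n_assessed, float(w))
            mu = _sliding_sum(rate_d * rated, w)
        V = _sliding_sum(is_var.astype(float), w)
        Sv = _sliding_sum(site_w, w)

        theta = four_ne * mu
        gate = n_adequate / w >= cfg.min_window_covered_fraction
        valid = gate & (theta > 0) & (theta * Q <= kappa)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = cohort.score_scale * ((Sv - w0 * V) / theta + (w0 * Q - W))
        score[a:b] = np.where(valid, s, np.nan)
        covfrac[a:b] = np.where(valid, n_adequate / w, np.nan)
        flag[a:b] = np.where(valid, FLAG_COMPUTED, FLAG_ABSENT)

    return OrionScoreTrack(chrom, score, covfrac, flag)


def impute_gaps(track: OrionScoreTrack, cfg: ScanConfig = ScanConfig()) -> OrionScoreTrack:
    """Fill short gaps (<= ``max_impute_gap`` absent bases) between computed
    scores by linear interpolation; longer gaps are left untouched."""
    score = track.score.copy()
    flag = track.flag.copy()
    computed = np.flatnonzero(flag == FLAG_COMPUTED)
    if computed.size >= 2:
        gaps = np.diff(computed)
        for k in np.flatnonzero((gaps > 1) & (gaps <= cfg.max_impute_gap + 1)):
            i, j = computed[k], computed[k + 1]
            inner = np.arange(i + 1, j)
            if np.any(flag[inner] != FLAG_ABSENT):
                continue  # only bridge truly absent runs
            score[inner] = score[i] + (score[j] - score[i]) * (inner - i) / (j - i)
            flag[inner] = FLAG_IMPUTED
    return OrionScoreTrack(track.chrom, score, track.covered_fraction.copy(), flag)


def mask_repeats(track: OrionScoreTrack, repeats: IntervalSet) -> OrionScoreTrack:
    """Remove scores at positions inside repeat intervals.

    Windows that merely overlap a repeat but are centered outside keep
    their scores; only the center base's membership matters.
    """
    score = track.score.copy()
    flag = track.flag.copy()
    in_repeat = repeats.mask(track.chrom, track.length)
    hit = in_repeat & track.scored
    score[hit] = np.nan
    flag[hit] = FLAG_MASKED
    return OrionScoreTrack(track.chrom, score, track.covered_fraction.copy(), flag)


def compare_window_sizes(tracks: dict[int, OrionScoreTrack]) -> pd.DataFrame:
    """Pairwise Pearson correlation of score tracks over jointly scored positions."""
    if len(tracks) < 2:
        raise ValueError("need at least two window sizes to compare")
    sizes = sorted(tracks)
    out = pd.DataFrame(np.eye(len(sizes)), index=sizes, columns=sizes)
    for i, a in enumerate(sizes):
        for b in sizes[i + 1 :]:
            ta, tb = tracks[a], tracks[b]
            m = min(ta.length, tb.length)
            both = ta.scored[:m] & tb.scored[:m]
            if both.sum() < 2:
                raise ValueError(f"fewer than 2 jointly scored positions for {a} vs {b}")
            r = np.corrcoef(ta.score[:m][both], tb.score[:m][both])[0, 1]
            out.loc[a, b] = out.loc[b, a] = r
    return out


def write_score_track(track: OrionScoreTrack, path: str | os.PathLike,
                      header: str | None = None) -> None:
    """4-column output (chrom, pos, score, flag) for all non-absent positions."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for i in np.flatnonzero(track.flag != FLAG_ABSENT):
            s = track.score[i]
            fh.write(f"{track.chrom}\t{i + 1}\t{'' if np.isnan(s) else format(s, '.8g')}"
                     f"\t{_FLAG_NAMES[track.flag[i]]}\n")


def read_score_track(path: str | os.PathLike, length: int | None = None) -> OrionScoreTrack:
    rows: list[tuple[str, int, float, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, s, fl = line.rstrip("\n").split("\t")
            rows.append((chrom, int(pos), float(s) if s else np.nan, _FLAG_CODES[fl]))
    if not rows:
        raise ValueError(f"{path}: empty score track")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError(f"{path}: multiple chromosomes {sorted(chroms)}")
    L = length or max(r[1] for r in rows)
    score = np.full(L, np.nan)
    covfrac = np.full(L, np.nan)
    flag = np.zeros(L, dtype=np.uint8)
    for chrom, pos, s, fl in rows:
        score[pos - 1] = s
        flag[pos - 1] = fl
    return OrionScoreTrack(chroms.pop(), score, covfrac, flag)
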