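"""Deterministic synthetic input data for the whole pipeline.

The generator emulates what the scan consumes for a diploid cohort: a
reference sequence, a per-base mutation-rate track, a GQ-based coverage
track, and a folded minor-allele-count track whose variants are drawn from
the neutral expected SFS — so a fully neutral fixture scores ~0 on average
by construction.  Embedded segments with a depletion factor < 1 carry
proportionally fewer variants (factor 0 = no variants at all), emulating
purifying selection; their coordinates are returned as a truth set so
detection can be benchmarked.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from orion.sfs_core import CohortModel, folded_class_shape
from orion.tracks_io import IntervalSet, PositionTrack, write_intervals, write_track

__all__ = ["FixtureSpec", "FixtureData", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic chromosome set.

    ``depleted_segments`` holds ``(chrom, start, end, factor)`` 0-based
    half-open intervals whose variant intensity is multiplied by ``factor``
    in [0, 1]; 0 is fully depleted (maximally intolerant), 1 neutral.
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 20_000})
    n_samples: int = 1_662
    effective_pop_size: int = 10_000
    base_rate: float = 1.2e-8
    rate_jitter: float = 0.1  # lognormal sigma of per-base rate variation
    coverage_dropout: float = 0.01
    depleted_segments: tuple[tuple[str, int, int, float], ...] = ()
    repeat_intervals: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, start, end, factor in self.depleted_segments:
            if not 0.0 <= factor <= 1.0:
                raise ValueError(
                    f"depletion factor {factor} for {chrom}:{start}-{end} outside [0, 1]"
                )

    def cohort(self) -> CohortModel:
        return CohortModel(self.n_samples, self.effective_pop_size)


@dataclass
class FixtureData:
    """Generated inputs, per chromosome, plus the truth/repeat interval sets."""

    sequences: dict[str, str]
    rate: dict[str, PositionTrack]
    coverage: dict[str, PositionTrack]
    ac: dict[str, PositionTrack]
    repeats: IntervalSet
    truth: IntervalSet
    spec: FixtureSpec

    def write(self, out_dir: str | os.PathLike) -> None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "reference.fa"), "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        for name, tracks in (("rate", self.rate), ("coverage", self.coverage),
                             ("ac", self.ac)):
            path = os.path.join(out_dir, f"{name}.{{}}.tsv")
            for chrom, track in tracks.items():
                write_track(track, path.format(chrom))
        write_intervals(self.repeats, os.path.join(out_dir, "repeats.bed"))
        write_intervals(self.truth, os.path.join(out_dir, "truth_segments.bed"))


def generate(spec: FixtureSpec) -> FixtureData:
    """Generate all pipeline inputs for a fixture spec (deterministic per seed).

    Variant sites are placed as independent Bernoulli draws with per-base
    intensity ``4 Ne r_i * sum_i q_i`` (the neutral per-base density of
    segregating sites) scaled by the local depletion factor; each variant's
    folded allele count is drawn from the normalized expected-SFS class
    probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    q = folded_class_shape(n)
    class_p = q / q.sum()
    sequences: dict[str, str] = {}
    rate_tracks: dict[str, PositionTrack] = {}
    cov_tracks: dict[str, PositionTrack] = {}
    ac_tracks: dict[str, PositionTrack] = {}

    for chrom, L in spec.chrom_lengths.items():
        sequences[chrom] = "".join(rng.choice(list("ACGT"), size=L))

        # per-base haploid rates: jittered lognormal, renormalized to the
        # configured mean; chromosome end bases carry no rate (no context)
        pos = np.arange(2, L, dtype=np.int64)  # 1-based, interior bases
        raw = rng.lognormal(mean=0.0, sigma=spec.rate_jitter, size=pos.size)
        rates = raw * (spec.base_rate / raw.mean())
        rate_tracks[chrom] = PositionTrack(chrom, pos, rates)

        cov_pos = np.arange(1, L + 1, dtype=np.int64)
        cov = np.ones(L)
        drop = rng.random(L) < spec.coverage_dropout
        cov[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
        cov_tracks[chrom] = PositionTrack(chrom, cov_pos, cov)

        # neutral per-base variant intensity, modulated by depletion factors
        intensity = np.zeros(L)
        dense_rate = rate_tracks[chrom].to_dense(L, fill=0.0)
        intensity = 4.0 * spec.effective_pop_size * dense_rate * q.sum()
        factor = np.ones(L)
        for c, start, end, f in spec.depleted_segments:
            if c == chrom:
                factor[start:end] = f
        is_var = rng.random(L) < intensity * factor
        var_idx = np.flatnonzero(is_var)
        acs = rng.choice(np.arange(1, n + 1), size=var_idx.size, p=class_p)
        ac_tracks[chrom] = PositionTrack(chrom, var_idx + 1, acs.astype(float))

    return FixtureData(
        sequences=sequences,
        rate=rate_tracks,
        coverage=cov_tracks,
        ac=ac_tracks,
        repeats=IntervalSet(spec.repeat_intervals),
        truth=IntervalSet(
            [(c, s, e) for c, s, e, f in spec.depleted_segments]
        ) if spec.depleted_segments else IntervalSet(),
        spec=spec,
    )
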