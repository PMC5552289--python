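"""Forward-time Wright-Fisher simulation under purifying selection.

Used to verify that the regional score tracks selection strength: stronger
purifying selection removes standing variation, which the score registers
as intolerance.  Each new mutation arises at a fresh site (infinite-sites
bookkeeping) with a selection coefficient drawn from a gamma distribution;
genotype fitnesses are ``f_AA = 1``, ``f_Aa = 1 - 0.5 s`` and
``f_aa = 1 - s`` (codominance), and an individual's fitness is the product
over its segregating loci.  Reproduction is standard Wright-Fisher: each
offspring draws two fitness-weighted parents and inherits one (non-
recombining) haplotype from each.

The population-scale demography (81,000-generation burn-in of 8,100
individuals, 100-generation bottleneck at 7,900, exponential growth to
900,000 over 370 generations) emulates recent explosive human growth; a
desk-scale preset shrinks it to hundreds of individuals and thousands of
generations while holding the population-scaled mutation rate N*mu
comparable, so a full selection grid runs in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from orion.sfs_core import (
    CohortModel,
    SFSVector,
    expected_sfs,
    observed_sfs,
    orion_score,
    weight_vector,
)

__all__ = [
    "SelectionModel",
    "Demography",
    "SimConfig",
    "simulate",
    "score_selection_correlation",
    "sim_score",
]

# full-scale per-base haploid mutation rate and ancestral size
_FULL_MU = 1.8e-8
_FULL_N0 = 8_100
# desk preset holds N0 * mu constant: mu_desk = mu_full * N0_full / N0_desk
_DESK_N0 = 500
_DESK_MU = _FULL_MU * _FULL_N0 / _DESK_N0


@dataclass(frozen=True)
class SelectionModel:
    """Gamma-distributed selection coefficients; shape 0 = strict neutrality."""

    gamma_shape: float = 0.0
    gamma_scale: float = 0.32
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma_shape < 0:
            raise ValueError("gamma_shape must be >= 0")
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be > 0")

    def draw_s(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Selection coefficients, clamped to [0, 1] (s = 1 is lethal)."""
        if self.gamma_shape == 0.0:
            return np.zeros(size)
        return np.minimum(rng.gamma(self.gamma_shape, self.gamma_scale, size), 1.0)


@dataclass(frozen=True)
class Stage:
    """One demographic stage: ``growth=False`` holds ``size`` constant for
    ``generations``; ``growth=True`` grows exponentially from the previous
    stage's size to ``size``."""

    size: int
    generations: int
    growth: bool = False

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("population size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class Demography:
    stages: tuple[Stage, ...]

    def sizes(self) -> np.ndarray:
        """Per-generation population sizes over the whole run."""
        out: list[int] = []
        prev = self.stages[0].size
        for st in self.stages:
            if st.growth:
                g = np.arange(1, st.generations + 1)
                out.extend(np.round(prev * (st.size / prev) ** (g / st.generations))
                           .astype(int))
            else:
                out.extend([st.size] * st.generations)
            prev = st.size
        return np.array(out, dtype=int)

    @classmethod
    def full_scale(cls) -> "Demography":
        return cls((Stage(8_100, 81_000), Stage(7_900, 100),
                    Stage(900_000, 370, growth=True)))

    @classmethod
    def desk_scale(cls) -> "Demography":
        return cls((Stage(_DESK_N0, 5_000), Stage(450, 50),
                    Stage(5_000, 100, growth=True)))

    @classmethod
    def constant(cls, size: int, generations: int) -> "Demography":
        return cls((Stage(size, generations),))


@dataclass(frozen=True)
class SimConfig:
    """Sequence length, per-base haploid mutation rate, terminal sample size."""

    sequence_length: int = 2_000
    mutation_rate_per_base: float = _DESK_MU
    sample_size: int = 50
    seed: int = 0

    @classmethod
    def full_scale(cls, sample_size: int = 1662, seed: int = 0) -> "SimConfig":
        warnings.warn("full-scale simulation parameters: expect very long runtimes")
        return cls(63_000, _FULL_MU, sample_size, seed)


def simulate(
    sim: SimConfig,
    dem: Demography,
    sel: SelectionModel,
) -> tuple[SFSVector, float]:
    """Run the simulation and return the terminal sample's folded SFS and kappa.

    Returns ``(sfs, kappa)`` where kappa equals the sequence length (all
    bases assessed) and the SFS is over ``sim.sample_size`` diploids.
    """
    rng = np.random.default_rng(sim.seed)
    sizes = dem.sizes()
    N = int(sizes[0])
    # haplotypes x segregating sites; sites carry their selection coefficients
    H = np.zeros((2 * N, 0), dtype=bool)
    s = np.zeros(0)
    neutral = sel.gamma_shape == 0.0

    for N_next in sizes:
        N_next = int(N_next)
        # parent sampling, fitness-weighted
        if s.size and not neutral:
            G = H[0::2].astype(np.int8) + H[1::2].astype(np.int8)  # N x S genotypes
            fitness = np.prod(1.0 - s[None, :] * (G * 0.5), axis=1)
            total = fitness.sum()
            if total <= 0:
                raise RuntimeError("population extinct: all fitness zero")
            p = fitness / total
            parents = rng.choice(N, size=(N_next, 2), p=p)
        else:
            parents = rng.integers(0, N, size=(N_next, 2))
        # each offspring inherits one random haplotype per parent
        gamete = rng.integers(0, 2, size=(N_next, 2))
        hap_idx = (2 * parents + gamete).reshape(-1)  # 2*N_next haplotype picks
        H = H[hap_idx]

        # new mutations: Poisson(2 N L mu), each at a fresh site on one haplotype
        n_mut = rng.poisson(2 * N_next * sim.sequence_length * sim.mutation_rate_per_base)
        if n_mut:
            new = np.zeros((2 * N_next, n_mut), dtype=bool)
            new[rng.integers(0, 2 * N_next, size=n_mut), np.arange(n_mut)] = True
            H = np.concatenate([H, new], axis=1)
            s = np.concatenate([s, sel.draw_s(rng, n_mut)])

        # retire fixed and lost sites (infinite sites: fixed = new reference)
        if s.size:
            counts = H.sum(axis=0)
            seg = (counts > 0) & (counts < 2 * N_next)
            if not seg.all():
                H = H[:, seg]
                s = s[seg]
        N = N_next

    # terminal sample of diploids
    n_samp = min(sim.sample_size, N)
    chosen = rng.choice(N, size=n_samp, replace=False)
    hap = np.concatenate([2 * chosen, 2 * chosen + 1])
    counts = H[hap].sum(axis=0)
    counts = counts[(counts > 0) & (counts < 2 * n_samp)]
    folded = np.minimum(counts, 2 * n_samp - counts)
    cohort = CohortModel(n_samples=n_samp)
    sfs = observed_sfs(folded.tolist(), kappa=sim.sequence_length, cohort=cohort)
    return sfs, float(sim.sequence_length)


def sim_score(
    sfs: SFSVector,
    kappa: float,
    mutation_rate_per_base: float,
    effective_pop_size: int,
    score_scale: float = 100_000.0,
) -> float:
    """Orion score of a simulated sample against its neutral expectation."""
    cohort = CohortModel(n_samples=sfs.n_samples,
                         effective_pop_size=effective_pop_size,
                         score_scale=score_scale)
    mu_region = mutation_rate_per_base * kappa
    expected = expected_sfs(cohort, mu_region, kappa)
    theta = 4.0 * effective_pop_size * mu_region
    return orion_score(sfs, expected, weight_vector(cohort), theta, score_scale)


def score_selection_correlation(
    shapes: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    sim: SimConfig | None = None,
    dem: Demography | None = None,
    effective_pop_size: int | None = None,
) -> tuple[float, dict[float, float]]:
    """Spearman correlation of mean score against gamma selection shape.

    Runs ``replicates`` simulations per shape (distinct seeds derived from
    ``seed``), scores each terminal sample against the neutral expectation,
    and correlates the per-shape mean scores with the shapes.  Expected
    positive: stronger purifying selection depletes variation and raises
    the score.
    """
    shapes = list(shapes)
    if len(set(shapes)) < 2:
        raise ValueError("need at least two distinct gamma shapes")
    base = sim or SimConfig()
    demography = dem or Demography.desk_scale()
    ne = effective_pop_size or demography.stages[0].size
    means: dict[float, float] = {}
    for i, shape in enumerate(shapes):
        scores = []
        for r in range(replicates):
            cfg = SimConfig(base.sequence_length, base.mutation_rate_per_base,
                            base.sample_size, seed=(seed * 100_003 + i * 1_009 + r) % (2**31))
            sfs, kappa = simulate(cfg, demography, SelectionModel(gamma_shape=shape))
            scores.append(sim_score(sfs, kappa, base.mutation_rate_per_base, ne))
        means[shape] = float(np.mean(scores))
    vals = np.array([means[sh] for sh in shapes])
    if np.all(vals == vals[0]):
        raise ValueError("all mean scores identical; correlation undefined")
    rho = float(sps.spearmanr(shapes, vals).statistic)
    return rho, means
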