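import numpy as np
import pytest

from orion.fixtures import FixtureSpec, generate
from orion.scan import FLAG_ABSENT, FLAG_COMPUTED, OrionScoreTrack
from orion.sfs_core import CohortModel


@pytest.fixture(scope="session")
def small_cohort() -> CohortModel:
    return CohortModel(n_samples=5)


@pytest.fixture(scope="session")
def full_cohort() -> CohortModel:
    return CohortModel(n_samples=1662)


@pytest.fixture(scope="session")
def neutral_fixture():
    """A 6-kb neutral synthetic chromosome with a fully depleted 1.6-kb segment."""
    spec = FixtureSpec(
        chrom_lengths={"chr1": 6000},
        depleted_segments=(("chr1", 2500, 4100, 0.0),),
        seed=7,
    )
    return spec, generate(spec)


def make_score_track(scores, scored_mask=None, chrom="chr1") -> OrionScoreTrack:
    """Build a score track from a plain array (NaN or mask = unscored)."""
    x = np.asarray(scores, dtype=float)
    scored = ~np.isnan(x) if scored_mask is None else np.asarray(scored_mask, bool)
    flag = np.where(scored, FLAG_COMPUTED, FLAG_ABSENT).astype(np.uint8)
    return OrionScoreTrack(chrom, np.where(scored, x, np.nan),
                           np.full(x.size, np.nan), flag)
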