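"""Sliding-window scan: gating, oracle agreement, imputation, masking."""

import numpy as np
import pytest

from conftest import make_score_track
from orion.fixtures import FixtureSpec, generate
from orion.scan import (
    FLAG_ABSENT,
    FLAG_COMPUTED,
    FLAG_IMPUTED,
    FLAG_MASKED,
    OrionScoreTrack,
    ScanConfig,
    compare_window_sizes,
    depleted_window_score,
    impute_gaps,
    mask_repeats,
    scan_chromosome,
)
from orion.sfs_core import (
    CohortModel,
    expected_sfs,
    observed_sfs,
    orion_score,
    weight_vector,
)
from orion.tracks_io import IntervalSet, PositionTrack


def _window_oracle(rate_d, cov_d, ac_d, cohort, cfg, center):
    """Direct single-window computation through the SFS primitives."""
    h = cfg.half
    i = center - 1
    r = rate_d[i - h : i + h + 1]
    cv = cov_d[i - h : i + h + 1]
    ac = ac_d[i - h : i + h + 1]
    adequate = ~np.isnan(cv) & (cv >= cfg.min_site_coverage)
    if adequate.sum() / cfg.window_size < cfg.min_window_covered_fraction:
        return None
    assessed = adequate & ~np.isnan(r)
    kappa = assessed.sum()
    mu = r[assessed].sum()
    theta = 4 * cohort.effective_pop_size * mu
    if theta <= 0:
        return None
    folded = ac[assessed & (ac >= 1)].astype(int)
    return orion_score(
        observed_sfs(folded.tolist(), kappa, cohort),
        expected_sfs(cohort, mu, kappa),
        weight_vector(cohort),
        theta,
        cohort.score_scale,
    )


class TestScanChromosome:
    def test_agrees_with_per_window_oracle(self, neutral_fixture):
        spec, fx = neutral_fixture
        cohort, cfg = spec.cohort(), ScanConfig()
        track = scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"],
                                cohort, cfg)
        L = 6000
        rate_d = fx.rate["chr1"].to_dense(L)
        cov_d = fx.coverage["chr1"].to_dense(L)
        ac_d = fx.ac["chr1"].to_dense(L, fill=0.0)
        for center in [251, 700, 1500, 3300, 5749]:
            want = _window_oracle(rate_d, cov_d, ac_d, cohort, cfg, center)
            got = track.score[center - 1]
            if want is None:
                assert np.isnan(got)
            else:
                assert np.isclose(got, want, rtol=1e-9)

    def test_depleted_window_scores_positive(self, neutral_fixture):
        spec, fx = neutral_fixture
        track = scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"],
                                spec.cohort())
        # center of the fully depleted 1.6-kb segment: no variants in window
        center = (2500 + 4100) // 2
        assert track.score[center - 1] > 0
        assert np.isclose(track.score[center - 1],
                          depleted_window_score(spec.cohort()), rtol=1e-9)

    def test_coverage_gate_boundary(self):
        """249 of 501 adequate sites gates the window out (49.7% < 50%)."""
        cohort = CohortModel(5)
        L = 501
        pos = np.arange(1, L + 1)
        rate = PositionTrack("chr1", pos, np.full(L, 1e-8))
        cov_vals = np.zeros(L)
        cov_vals[:249] = 1.0
        cov = PositionTrack("chr1", pos, cov_vals)
        ac = PositionTrack("chr1", np.array([10]), np.array([1.0]))
        track = scan_chromosome(rate, cov, ac, cohort, ScanConfig())
        assert track.flag[250] == FLAG_ABSENT
        cov_vals[:251] = 1.0
        track = scan_chromosome(rate, PositionTrack("chr1", pos, cov_vals), ac,
                                cohort, ScanConfig())
        assert track.flag[250] == FLAG_COMPUTED

    def test_chromosome_ends_absent(self, neutral_fixture):
        spec, fx = neutral_fixture
        track = scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"],
                                spec.cohort())
        h = ScanConfig().half
        assert np.all(track.flag[:h] == FLAG_ABSENT)
        assert np.all(track.flag[-h:] == FLAG_ABSENT)

    def test_deterministic_and_chunking_invariant(self, neutral_fixture):
        spec, fx = neutral_fixture
        args = (fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"], spec.cohort())
        whole = scan_chromosome(*args)
        again = scan_chromosome(*args)
        chunked = scan_chromosome(*args, chunk_size=700)
        assert np.array_equal(whole.score, again.score, equal_nan=True)
        # chunking changes float accumulation order only
        assert np.allclose(whole.score, chunked.score, rtol=1e-12, atol=1e-6,
                           equal_nan=True)
        assert np.array_equal(whole.flag, chunked.flag)

    def test_locality_of_ac_change(self, neutral_fixture):
        spec, fx = neutral_fixture
        base = scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"],
                               spec.cohort())
        ac = fx.ac["chr1"]
        changed_pos = 1500
        new_pos = np.sort(np.append(ac.positions, changed_pos))
        new_vals = np.ones_like(new_pos, dtype=float)
        lookup = dict(zip(ac.positions, ac.values))
        new_vals = np.array([lookup.get(p, 5.0) for p in new_pos])
        perturbed = scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"],
                                    PositionTrack("chr1", new_pos, new_vals),
                                    spec.cohort())
        diff = np.flatnonzero(~np.isclose(base.score, perturbed.score, equal_nan=True))
        assert diff.size > 0
        assert np.all(np.abs(diff + 1 - changed_pos) <= ScanConfig().half)


class TestImputeGaps:
    def _with_gap(self, gap):
        scores = np.concatenate([[0.0], np.full(gap, np.nan), [0.2]])
        return make_score_track(scores)

    def test_midpoint(self):
        track = impute_gaps(self._with_gap(1))
        assert np.isclose(track.score[1], 0.1)
        assert track.flag[1] == FLAG_IMPUTED

    def test_ten_base_gap_linear_closed_form(self):
        scores = np.concatenate([[-0.3], np.full(10, np.nan), [0.1]])
        track = impute_gaps(make_score_track(scores))
        x = np.arange(1, 11)
        assert np.allclose(track.score[1:11], -0.3 + (0.1 - -0.3) * x / 11)
        assert np.all(track.flag[1:11] == FLAG_IMPUTED)

    def test_eleven_base_gap_untouched(self):
        track = impute_gaps(self._with_gap(11))
        assert np.all(np.isnan(track.score[1:12]))
        assert np.all(track.flag[1:12] == FLAG_ABSENT)


class TestMaskRepeats:
    def test_empty_set_identity(self):
        track = make_score_track([0.1, 0.2, 0.3])
        out = mask_repeats(track, IntervalSet())
        assert np.array_equal(out.score, track.score)

    def test_full_mask(self):
        track = make_score_track([0.1, 0.2, 0.3])
        out = mask_repeats(track, IntervalSet([("chr1", 0, 3)]))
        assert np.all(np.isnan(out.score))
        assert np.all(out.flag == FLAG_MASKED)

    def test_random_repeats_membership_oracle(self):
        rng = np.random.default_rng(5)
        track = make_score_track(rng.normal(size=200))
        ivs = IntervalSet([("chr1", int(s), int(s) + int(w))
                           for s, w in zip(rng.integers(0, 190, 8), rng.integers(1, 15, 8))])
        out = mask_repeats(track, ivs)
        for i in range(200):
            if ivs.contains("chr1", i):
                assert out.flag[i] == FLAG_MASKED and np.isnan(out.score[i])
            else:
                assert out.flag[i] == track.flag[i]


class TestCompareWindowSizes:
    def test_identical_tracks(self):
        t = make_score_track(np.linspace(-1, 1, 50))
        r = compare_window_sizes({251: t, 501: t})
        assert np.isclose(r.loc[251, 501], 1.0)

    def test_anticorrelated(self):
        x = np.linspace(-1, 1, 50)
        r = compare_window_sizes({3: make_score_track(x), 5: make_score_track(-x)})
        assert np.isclose(r.loc[3, 5], -1.0)

    def test_too_few_overlapping_positions(self):
        a = make_score_track([0.1, np.nan, np.nan])
        b = make_score_track([np.nan, 0.1, 0.2])
        with pytest.raises(ValueError, match="jointly scored"):
            compare_window_sizes({3: a, 5: b})

    def test_fixture_scan_sizes_correlate(self):
        spec = FixtureSpec(chrom_lengths={"chr1": 8000}, seed=11)
        fx = generate(spec)
        tracks = {
            w: scan_chromosome(fx.rate["chr1"], fx.coverage["chr1"], fx.ac["chr1"],
                               spec.cohort(), ScanConfig(window_size=w))
            for w in (251, 501)
        }
        assert compare_window_sizes(tracks).loc[251, 501] > 0.5
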