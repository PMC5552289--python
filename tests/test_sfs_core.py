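"""Expected/observed folded SFS construction and the intolerance score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orion.sfs_core import (
    CohortModel,
    expected_sfs,
    folded_class_shape,
    observed_sfs,
    orion_score,
    weight_vector,
)


class TestExpectedSFS:
    def test_single_sample_folding_collapses_to_theta(self):
        # n=1: the only class i=1 has i == 2n-i, so the delta halves the sum
        cohort = CohortModel(1)
        theta = 0.5
        sfs = expected_sfs(cohort, theta / (4 * cohort.effective_pop_size), kappa=100)
        assert np.allclose(sfs.counts, [99.5, 0.5])

    def test_zero_mutation_rate_all_monomorphic(self):
        sfs = expected_sfs(CohortModel(4), 0.0, kappa=250)
        assert sfs.counts[0] == 250 and np.all(sfs.counts[1:] == 0)

    def test_n2_classes_and_harmonic_sum(self):
        cohort = CohortModel(2)
        theta = 0.01
        sfs = expected_sfs(cohort, theta / (4 * cohort.effective_pop_size), kappa=1000)
        assert np.isclose(sfs.counts[1], theta * (1 + 1 / 3))
        assert np.isclose(sfs.counts[2], theta * (1 / 2 + 1 / 2) / 2)
        # oracle: sum over folded classes equals theta * sum_{j=1}^{2n-1} 1/j
        assert np.isclose(sfs.counts[1:].sum(), theta * sum(1 / j for j in range(1, 4)))

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 20, 50])
    def test_harmonic_identity(self, n):
        """sum(psi_i) == theta * a_{2n-1}, by direct harmonic summation."""
        theta = 0.37
        sfs = expected_sfs(CohortModel(n), theta / 40_000, kappa=10_000)
        harmonic = sum(1.0 / j for j in range(1, 2 * n))
        assert np.isclose(sfs.counts[1:].sum(), theta * harmonic, rtol=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_folding_matches_unfolded_expectation(self, n):
        """psi_i equals the unfolded theta/j spectrum folded by summing the
        j and 2n-j classes (the i == n class pairs with itself)."""
        theta = 1.0
        q = folded_class_shape(n)
        unfolded = {j: theta / j for j in range(1, 2 * n)}
        for i in range(1, n + 1):
            if i == 2 * n - i:
                want = unfolded[i]  # self-paired class appears once
            else:
                want = unfolded[i] + unfolded[2 * n - i]
            assert np.isclose(theta * q[i - 1], want)

    def test_conservation(self):
        sfs = expected_sfs(CohortModel(10), 1e-6, kappa=501)
        assert np.isclose(sfs.counts.sum(), 501, rtol=1e-9)

    def test_scale_equivariance(self):
        """Doubling mu doubles every polymorphic class."""
        c = CohortModel(6)
        a = expected_sfs(c, 1e-6, 5000)
        b = expected_sfs(c, 2e-6, 5000)
        assert np.allclose(b.counts[1:], 2 * a.counts[1:])

    def test_rejects_inconsistent_mu_kappa(self):
        with pytest.raises(ValueError, match="inconsist"):
            expected_sfs(CohortModel(5), mu_region=1.0, kappa=2)


class TestObservedSFS:
    def test_empty_input(self):
        sfs = observed_sfs([], kappa=501, cohort=CohortModel(3))
        assert sfs.counts[0] == 501 and sfs.counts[1:].sum() == 0

    def test_tally(self):
        sfs = observed_sfs([1, 1, 2], kappa=10, cohort=CohortModel(3))
        assert list(sfs.counts) == [7, 2, 1, 0]

    def test_rejects_unfolded_counts(self):
        with pytest.raises(ValueError, match="unfolded"):
            observed_sfs([4], kappa=10, cohort=CohortModel(3))

    @given(st.lists(st.integers(1, 8), max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, acs):
        sfs = observed_sfs(acs, kappa=100, cohort=CohortModel(8))
        assert sfs.counts.sum() == 100


class TestWeights:
    def test_n1(self):
        w = weight_vector(CohortModel(1))
        assert np.allclose(w.raw, [2, 1])
        assert np.allclose(w.normalized, [2 / 3, 1 / 3])

    def test_n2_direct_arithmetic(self):
        w = weight_vector(CohortModel(2))
        assert np.allclose(w.raw, [4, 2, 4 / 3])
        assert np.allclose(w.normalized, np.array([4, 2, 4 / 3]) / (22 / 3))

    @pytest.mark.parametrize("n", [1, 3, 10, 100])
    def test_strictly_decreasing_and_normalized(self, n):
        w = weight_vector(CohortModel(n))
        assert np.all(np.diff(w.raw) < 0)
        assert abs(w.normalized.sum() - 1.0) < 1e-12


class TestOrionScore:
    def test_identity_scores_zero(self):
        c = CohortModel(4)
        e = expected_sfs(c, 1e-6, 1000)
        obs = type(e)(counts=e.counts.copy(), region_length=1000, kind="observed")
        score = orion_score(obs, e, weight_vector(c), theta=4e-2)
        assert abs(score) < 1e-9

    def test_removing_singleton_raises_score(self):
        c = CohortModel(5)
        obs = observed_sfs([1, 1, 2, 3], 1000, c)
        exp = expected_sfs(c, 1e-6, 1000)
        w = weight_vector(c)
        theta = 4 * c.effective_pop_size * 1e-6
        before = orion_score(obs, exp, w, theta)
        depleted = observed_sfs([1, 2, 3], 1000, c)
        assert orion_score(depleted, exp, w, theta) > before

    @pytest.mark.parametrize("cls", [1, 2, 3, 5])
    def test_deleting_any_variant_class_strictly_increases(self, cls):
        """Moving one site from any polymorphic class to monomorphic raises
        the score: the monomorphic class carries the heaviest weight."""
        c = CohortModel(5)
        exp = expected_sfs(c, 1e-6, 1000)
        w = weight_vector(c)
        theta = 0.04
        full = observed_sfs([1, 1, 2, 2, 3, 3, 4, 5, 5], 1000, c)
        acs = [1, 1, 2, 2, 3, 3, 4, 5, 5]
        acs.remove(cls)
        assert orion_score(observed_sfs(acs, 1000, c), exp, w, theta) > orion_score(
            full, exp, w, theta
        )

    def test_hand_evaluated_score(self):
        """Brute-force arithmetic oracle, written out without package calls."""
        n, theta, kappa, scale = 2, 0.01, 1000, 100_000
        psi1 = theta * (1 / 1 + 1 / 3)
        psi2 = theta * (1 / 2 + 1 / 2) / 2
        psi0 = kappa - psi1 - psi2
        raw = [4 / 1, 4 / 2, 4 / 3]
        w = [r / sum(raw) for r in raw]
        eta = [998, 1, 1]
        want = scale * sum(wi * (o - e) for wi, o, e in zip(w, eta, [psi0, psi1, psi2])) / theta

        c = CohortModel(2)
        got = orion_score(
            observed_sfs([1, 2], kappa, c),
            expected_sfs(c, theta / (4 * c.effective_pop_size), kappa),
            weight_vector(c),
            theta,
            scale,
        )
        assert np.isclose(got, want, rtol=1e-10)

    def test_zero_theta_rejected(self):
        c = CohortModel(2)
        e = expected_sfs(c, 0.0, 100)
        o = observed_sfs([], 100, c)
        with pytest.raises(ValueError, match="theta"):
            orion_score(o, e, weight_vector(c), theta=0.0)

    def test_neutral_draw_at_doubled_rate_still_centered(self):
        """Scale equivariance: spectra drawn from the doubled-rate expectation
        still score ~0 in expectation."""
        rng = np.random.default_rng(0)
        c = CohortModel(4)
        mu = 2e-6
        exp = expected_sfs(c, mu, 2000)
        theta = 4 * c.effective_pop_size * mu
        w = weight_vector(c)
        scores = []
        for _ in range(400):
            counts = rng.poisson(exp.counts[1:])
            acs = np.repeat(np.arange(1, 5), counts)
            scores.append(orion_score(observed_sfs(acs, 2000, c), exp, w, theta))
        se = np.std(scores) / np.sqrt(len(scores))
        assert abs(np.mean(scores)) < 4 * se + 1e-9
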