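"""Permutation null, Hungarian component matching, bootstrap intervals."""

import itertools

import numpy as np
import pytest

from chronomodes import bootstrap_loadings, match_components, permutation_test
from chronomodes.inference import _empirical_p


def _planted_xy(rng, n=300, p=20, strength=3.0):
    z = rng.standard_normal(n)
    y = np.where(z + 0.5 * rng.standard_normal(n) > 0, 1.0, -1.0)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    X = strength * np.outer(z, v) + rng.standard_normal((n, p))
    return X, y


class TestEmpiricalP:
    def test_observation_beating_every_draw_attains_floor(self):
        p = _empirical_p(np.array([0.9]), np.full((1000, 1), 0.1))
        assert p[0] == pytest.approx(1 / 1001)
        assert p[0] < 0.001

    def test_all_draws_tying_gives_one(self):
        p = _empirical_p(np.array([0.5]), np.full((200, 1), 0.5))
        assert p[0] == pytest.approx(1.0)

    def test_magnitude_comparison_ignores_sign(self):
        null = np.array([[-0.3], [0.2], [-0.1]])
        assert _empirical_p(np.array([0.25]), null)[0] == pytest.approx(2 / 4)
        assert _empirical_p(np.array([-0.25]), null)[0] == pytest.approx(2 / 4)

    def test_weakly_decreasing_in_observed_magnitude(self, rng):
        null = rng.standard_normal((100, 1)) * 0.1
        ps = [_empirical_p(np.array([obs]), null)[0]
              for obs in np.linspace(0, 0.4, 50)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))


class TestPermutationTest:
    @pytest.mark.parametrize("scheme", ["projection", "refit"])
    def test_fixed_seed_reproducible(self, rng, scheme):
        X, y = _planted_xy(rng)
        a = permutation_test(X, y, 2, B=30, seed=7, null_scheme=scheme)
        b = permutation_test(X, y, 2, B=30, seed=7, null_scheme=scheme)
        assert np.array_equal(a.null_rho, b.null_rho)
        assert np.array_equal(a.p_values, b.p_values)

    def test_strong_signal_attains_minimum_p(self, rng):
        X, y = _planted_xy(rng, strength=5.0)
        res = permutation_test(X, y, 1, B=100, seed=0)
        assert res.p_values[0] == pytest.approx(1 / 101)

    def test_null_scheme_validated(self, rng):
        X, y = _planted_xy(rng)
        with pytest.raises(ValueError, match="null_scheme"):
            permutation_test(X, y, 1, B=10, seed=0, null_scheme="jackknife")

    def test_refit_type_one_error_controlled(self):
        """Pure-noise target: refit-null rejection rate at alpha=0.05 is at
        the nominal level (the exchangeable scheme is exactly calibrated)."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            X = rng.standard_normal((300, 30))
            y = rng.choice([-1.0, 1.0], 300)
            res = permutation_test(X, y, 2, B=200, seed=rep, null_scheme="refit")
            rejections += res.p_values[0] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_budget_warning_not_failure(self, rng):
        X, y = _planted_xy(rng, n=60, p=6)
        with pytest.warns(RuntimeWarning, match="budget"):
            res = permutation_test(X, y, 2, B=5, seed=0,
                                   null_scheme="refit", refit_budget=4)
        assert res.null_rho.shape == (5, 2)


class TestMatchComponents:
    def test_identity(self, rng):
        L = rng.standard_normal((30, 4))
        perm, signs = match_components(L, L)
        assert perm.tolist() == [0, 1, 2, 3]
        assert signs.tolist() == [1, 1, 1, 1]

    def test_swap_and_flip_recovered(self, rng):
        L = rng.standard_normal((30, 3))
        shuffled = L[:, [1, 0, 2]].copy()
        shuffled[:, 1] *= -1  # the column holding original component 0
        perm, signs = match_components(shuffled, L)
        aligned = shuffled[:, perm] * signs
        for j in range(3):
            r = np.corrcoef(aligned[:, j], L[:, j])[0, 1]
            assert r > 0.999

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_total_similarity_matches_exhaustive_search(self, rng, k):
        L_ref = rng.standard_normal((25, k))
        L_boot = rng.standard_normal((25, k))
        perm, _ = match_components(L_boot, L_ref)

        def abscorr(a, b):
            a = a - a.mean(); b = b - b.mean()
            return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))

        got = sum(abscorr(L_boot[:, perm[j]], L_ref[:, j]) for j in range(k))
        best = max(
            sum(abscorr(L_boot[:, pi[j]], L_ref[:, j]) for j in range(k))
            for pi in itertools.permutations(range(k)))
        assert got == pytest.approx(best, abs=1e-12)

    def test_constant_column_rejected(self, rng):
        L = rng.standard_normal((20, 2))
        bad = L.copy()
        bad[:, 0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            match_components(bad, L)

    def test_returned_permutation_is_bijection(self, rng):
        L_ref = rng.standard_normal((40, 6))
        L_boot = rng.standard_normal((40, 6))
        perm, signs = match_components(L_boot, L_ref)
        assert sorted(perm.tolist()) == list(range(6))
        assert set(signs.tolist()) <= {-1.0, 1.0}


class TestBootstrap:
    def test_noiseless_rank_one_data_has_zero_width_intervals(self, rng):
        z = rng.standard_normal(120)
        v = rng.standard_normal(8)
        v[5] = 0.0  # a genuinely zero loading
        v /= np.linalg.norm(v)
        X = np.outer(z, v)
        y = np.where(z > 0, 1.0, -1.0)
        res = bootstrap_loadings(X, y, 1, B=30, seed=1)
        width = res.ci_high[:, 0] - res.ci_low[:, 0]
        assert np.abs(width).max() < 1e-10
        assert np.array_equal(res.significant[:, 0], v != 0)

    def test_ci_bounds_match_sorted_percentile_oracle(self, rng):
        X, y = _planted_xy(rng, n=150, p=10)
        res = bootstrap_loadings(X, y, 2, B=40, seed=3)

        def percentile(sorted_draws, q):
            # linear interpolation between closest ranks, as an
            # independent re-derivation of the percentile definition
            pos = q / 100 * (len(sorted_draws) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            frac = pos - lo
            return sorted_draws[lo] * (1 - frac) + sorted_draws[hi] * frac

        for i in (0, 4, 9):
            for j in (0, 1):
                draws = np.sort(res.loading_draws[:, i, j])
                assert res.ci_low[i, j] == pytest.approx(percentile(draws, 5))
                assert res.ci_high[i, j] == pytest.approx(percentile(draws, 95))

    def test_significance_mask_is_zero_exclusion(self, rng):
        X, y = _planted_xy(rng, n=150, p=10)
        res = bootstrap_loadings(X, y, 1, B=30, seed=9)
        expected = (res.ci_low > 0) | (res.ci_high < 0)
        assert np.array_equal(res.significant, expected)
        assert np.all(res.ci_low <= res.ci_high)

    def test_single_class_resamples_redrawn(self, rng):
        X = rng.standard_normal((9, 4))
        y = np.array([1.0] + [-1.0] * 8)  # resamples frequently lose the +1
        res = bootstrap_loadings(X, y, 1, B=25, seed=2)
        assert res.n_redraws > 0
        assert res.loading_draws.shape == (25, 4, 1)

    def test_fixed_seed_reproducible(self, rng):
        X, y = _planted_xy(rng, n=100, p=8)
        a = bootstrap_loadings(X, y, 2, B=20, seed=11)
        b = bootstrap_loadings(X, y, 2, B=20, seed=11)
        assert np.array_equal(a.loading_draws, b.loading_draws)
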