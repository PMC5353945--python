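"""Unit and oracle tests for the statistical kernels."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neuromark.core_stats import (
    ContingencyTable,
    bh_adjust,
    fisher_enrichment,
    mann_whitney,
    mann_whitney_screen,
    principal_components,
    spearman,
    spearman_screen,
)
from neuromark.errors import DegenerateInputError, InsufficientDataError

# ---------------------------------------------------------------------------
# independent oracles


def oracle_spearman_rho(x, y):
    """Midrank-Pearson computed from first principles."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx @ dy) / math.sqrt((dx @ dx) * (dy @ dy)))


def oracle_spearman_perm_p(x, y):
    """Two-sided p by full enumeration of y-orderings."""
    obs = abs(oracle_spearman_rho(x, y))
    y = np.asarray(y, dtype=float)
    hits = total = 0
    for perm in permutations(y):
        total += 1
        if abs(oracle_spearman_rho(x, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def oracle_mw_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(b) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def oracle_hypergeom_tail(overlap, set_size, module_size, universe):
    """P(X >= overlap) as an explicit sum of point masses."""
    total = 0.0
    for k in range(overlap, min(set_size, module_size) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, module_size - k)
            / math.comb(universe, module_size)
        )
    return min(total, 1.0)


def oracle_bh(p):
    """Step-up BH computed by the textbook recursion."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------------------
# spearman


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_perfect_antitone(self):
        assert spearman([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle_and_enumeration(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        res = spearman(x, y)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(oracle_spearman_rho(x, y))
        assert res.statistic == pytest.approx(0.9486832980505139)
        assert res.p_value == pytest.approx(oracle_spearman_perm_p(x, y))
        assert res.p_value == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_n_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        assert res.statistic == pytest.approx(oracle_spearman_rho(x, y))
        assert res.p_value == pytest.approx(oracle_spearman_perm_p(x, y))

    def test_missing_pairs_dropped_and_n_eff_reported(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 5.0, np.nan]
        res = spearman(x, y)
        assert res.n_eff == 3

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transforms(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y)
        trans = spearman(np.exp(scale * x), scale * y + 1.0)
        assert trans.statistic == pytest.approx(base.statistic)
        assert trans.p_value == pytest.approx(base.p_value)

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [3, 4])
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_screen_variant_agrees_with_scalar_path(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 12))
        y = rng.normal(size=12)
        rho, p = spearman_screen(X, y)
        for i in range(50):
            ref = spearman(X[i], y)
            assert rho[i] == pytest.approx(ref.statistic)
            assert p[i] == pytest.approx(ref.p_value)


# ---------------------------------------------------------------------------
# mann-whitney


class TestMannWhitney:
    def test_no_overlap_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_near_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_labeling_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(oracle_mw_exact_p(a, b))

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        assert mann_whitney(a, b).method == "normal_approx"
        assert mann_whitney([1, 1, 2], [2, 3, 3]).method == "normal_approx"

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=12), rng.normal(size=9)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(np.exp(a), np.exp(b))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_screen_variant_agrees_with_scalar_path(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 24))
        mask = np.zeros(24, dtype=bool)
        mask[:11] = True
        u, p = mann_whitney_screen(X, mask)
        for i in range(40):
            ref = mann_whitney(X[i, mask], X[i, ~mask])
            assert u[i] == pytest.approx(ref.statistic)
            assert p[i] == pytest.approx(ref.p_value)


# ---------------------------------------------------------------------------
# fisher


class TestFisherEnrichment:
    def test_zero_overlap_when_attainable_gives_one(self):
        assert fisher_enrichment(ContingencyTable(0, 10, 10, 80)).p_value == 1.0

    def test_full_overlap_point_mass(self):
        res = fisher_enrichment(ContingencyTable(10, 0, 0, 90))
        assert res.p_value == pytest.approx(1 / math.comb(100, 10), rel=1e-12)

    def test_exhaustive_equivalence_small_universes(self):
        for n_univ in (5, 10, 20, 40):
            for set_size in range(0, n_univ + 1, 3):
                for mod_size in range(0, n_univ + 1, 3):
                    lo = max(0, set_size + mod_size - n_univ)
                    for ov in range(lo, min(set_size, mod_size) + 1):
                        table = ContingencyTable(
                            ov, set_size - ov, mod_size - ov, n_univ - set_size - mod_size + ov
                        )
                        expected = oracle_hypergeom_tail(ov, set_size, mod_size, n_univ)
                        got = fisher_enrichment(table).p_value
                        assert got == pytest.approx(max(expected, 5e-324), rel=1e-9), (
                            n_univ,
                            set_size,
                            mod_size,
                            ov,
                        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# BH adjustment


class TestBhAdjust:
    def test_examples(self):
        assert bh_adjust([0.01]).tolist() == [0.01]
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
        assert bh_adjust(p) == pytest.approx(oracle_bh(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------------------
# principal components


class TestPrincipalComponents:
    def test_rank_one_matrix_concentrates_variance(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        scores, frac = principal_components(np.outer(u, v), 1)
        assert frac[0] == pytest.approx(1.0)
        assert scores.shape == (8, 1)

    def test_two_block_design_matches_eigendecomposition(self):
        # orthogonal two-block 6x4 design: samples load on two disjoint
        # feature pairs; compare against a covariance eigendecomposition
        M = np.array(
            [
                [2.0, 2.0, 0.0, 0.0],
                [-2.0, -2.0, 0.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 3.0, 3.0],
                [0.0, 0.0, -3.0, -3.0],
                [0.0, 0.0, 1.0, 1.0],
            ]
        )
        scores, frac = principal_components(M, 2)
        Xc = M - M.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for j in range(2):
            expected = Xc @ evecs[:, order[j]]
            r = np.corrcoef(scores[:, j], expected)[0, 1]
            assert abs(r) == pytest.approx(1.0)
        assert frac[0] >= frac[1]

    def test_k_zero_returns_empty(self):
        scores, frac = principal_components(np.eye(4), 0)
        assert scores.shape == (4, 0)
        assert frac.size == 0

    def test_reconstruction_at_full_rank(self, rng):
        M = rng.normal(size=(9, 6))
        rank = np.linalg.matrix_rank(M - M.mean(axis=0))
        scores, _ = principal_components(M, rank)
        Xc = M - M.mean(axis=0)
        # at full rank the scores span the centred row space exactly
        proj = scores @ np.linalg.lstsq(scores, Xc, rcond=None)[0]
        err = np.linalg.norm(Xc - proj) / np.linalg.norm(Xc)
        assert err < 1e-8

    def test_rank_deficient_warns_and_truncates(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=4)
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            scores, _ = principal_components(np.outer(u, v), 3)
        assert scores.shape[1] == 1

    def test_sign_convention_largest_loading_positive(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=4)
        scores, _ = principal_components(np.outer(u, v), 1)
        # PC1 must align with u oriented so the dominant loading is positive
        expected = (u - u.mean()) * np.sign(v[np.argmax(np.abs(v))])
        assert np.corrcoef(scores[:, 0], expected)[0, 1] == pytest.approx(1.0)
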