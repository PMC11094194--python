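import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sprde.data_model import DegenerateInputError, StructuralError
from sprde.smr import (
    build_rank_views,
    mrr_decompose,
    rank_transform,
    salient_matrix,
    spearman_rho,
)


class TestRankTransform:
    def test_sorted_input(self):
        np.testing.assert_array_equal(rank_transform([10, 20, 30]), [1, 2, 3])

    def test_average_rank_ties(self):
        np.testing.assert_array_equal(rank_transform([5, 5, 1]), [2.5, 2.5, 1])

    def test_matches_comparison_count_oracle(self, rng):
        v = rng.uniform(0, 1, 40)
        v[rng.integers(0, 40, 8)] = 0.5  # force ties
        ranks = rank_transform(v)
        # O(N^2) oracle: rank = (# strictly smaller) + (1 + # equal) / 2
        for i, x in enumerate(v):
            smaller = sum(1 for u in v if u < x)
            equal = sum(1 for u in v if u == x)
            assert ranks[i] == pytest.approx(smaller + (equal + 1) / 2)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            rank_transform([1.0])


class TestSpearmanRho:
    def test_perfect_concordance(self, rng):
        x = rng.permutation(20).astype(float)
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_perfect_discordance(self, rng):
        x = np.sort(rng.uniform(0, 1, 15))
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_textbook_no_tie_value(self):
        # 1 - 6*sum(d^2)/(N(N^2-1)) with d = (−1, 1, −1, 1)
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.5:  # inject ties
                x = np.round(x, 1)
                y = np.round(y, 1)
            expected = stats.spearmanr(x, y).statistic
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)


class TestRankViews:
    def test_monotone_columns_give_normalized_arange(self, rng):
        Z = np.sort(rng.uniform(0, 100, (11, 11)), axis=0)
        views = build_rank_views(Z)
        ref = np.arange(1.0, 12.0)
        ref = (ref - ref.mean()) / np.linalg.norm(ref - ref.mean())
        for j in range(11):
            np.testing.assert_allclose(views.RX[:, j], ref, atol=1e-12)

    def test_scale_invariance(self, rng):
        Z = rng.uniform(0, 50, (11, 11))
        a, b = build_rank_views(Z), build_rank_views(3.7 * Z)
        np.testing.assert_allclose(a.RX, b.RX, atol=1e-12)
        np.testing.assert_allclose(a.RY, b.RY, atol=1e-12)

    def test_columns_are_unit_norm_and_centered(self, rng):
        Z = rng.uniform(0, 50, (11, 11))
        views = build_rank_views(Z)
        for R in (views.RX, views.RY):
            np.testing.assert_allclose(np.diag(R.T @ R), np.ones(11), atol=1e-12)
            np.testing.assert_allclose(R.sum(axis=0), np.zeros(11), atol=1e-12)

    def test_constant_column_flagged_not_fatal(self, rng):
        Z = rng.uniform(1, 50, (11, 11))
        Z[:, 4] = 2.0
        views = build_rank_views(Z)
        assert views.degenerate_x == [4]
        np.testing.assert_array_equal(views.RX[:, 4], np.zeros(11))


class TestMrrDecompose:
    def test_two_view_collapse(self, rng):
        """With RX = RY the spectrum is the square of the Gram spectrum."""
        Z = rng.uniform(0, 50, (11, 11))
        views = build_rank_views(Z)
        views.RY = views.RX.copy()
        decomp = mrr_decompose(views, theta=1.0, k_max=11)
        gram_eigs = np.sort(np.linalg.eigvalsh(views.RX.T @ views.RX))[::-1]
        np.testing.assert_allclose(decomp.eigenvalues, gram_eigs ** 2, atol=1e-8)

    def test_spectrum_nonnegative_and_sorted(self, rng):
        views = build_rank_views(rng.uniform(0, 50, (11, 11)))
        decomp = mrr_decompose(views)
        assert (decomp.eigenvalues >= 0).all()
        assert (np.diff(decomp.eigenvalues) <= 1e-12).all()

    def test_loadings_orthonormal(self, rng):
        views = build_rank_views(rng.uniform(0, 50, (11, 11)))
        P = mrr_decompose(views, theta=1.0, k_max=7).loadings
        np.testing.assert_allclose(P.T @ P, np.eye(P.shape[1]), atol=1e-10)

    def test_leading_pair_beats_random_search(self, rng):
        """(alpha_1, beta_1) maximize the rank-correlation objective."""
        for _ in range(3):
            RX = rng.normal(size=(6, 4))
            RY = rng.normal(size=(6, 4))
            views = build_rank_views(rng.uniform(0, 1, (6, 6)))
            views.RX, views.RY = RX, RY
            decomp = mrr_decompose(views, theta=1.0, k_max=4)
            K = RX.T @ RY
            attained = float(decomp.loadings[:, 0] @ K @ decomp.paired_loadings[:, 0])
            a = rng.normal(size=(4, 2000))
            b = rng.normal(size=(4, 2000))
            a /= np.linalg.norm(a, axis=0)
            b /= np.linalg.norm(b, axis=0)
            best_random = np.abs((a * (K @ b)).sum(axis=0)).max()
            assert attained >= best_random - 1e-9

    def test_cumulative_contribution_reaches_theta(self, rng):
        views = build_rank_views(rng.uniform(0, 50, (11, 11)))
        decomp = mrr_decompose(views, theta=0.9, k_max=11)
        retained = decomp.contributions[: decomp.k_retained].sum()
        assert retained >= 0.9
        # smallest such prefix
        if decomp.k_retained > 1:
            assert decomp.contributions[: decomp.k_retained - 1].sum() < 0.9

    def test_sign_convention_deterministic(self, rng):
        views = build_rank_views(rng.uniform(0, 50, (11, 11)))
        P = mrr_decompose(views).loadings
        for j in range(P.shape[1]):
            assert P[np.argmax(np.abs(P[:, j])), j] > 0

    def test_zero_matrix_rejected(self):
        views = build_rank_views(np.arange(121.0).reshape(11, 11))
        views.RX = np.zeros((11, 11))
        with pytest.raises(DegenerateInputError):
            mrr_decompose(views)


class TestSalientMatrix:
    def test_identity_prefix_selects_columns(self, rng):
        Z = rng.uniform(0, 10, (11, 11))
        views = build_rank_views(Z)
        decomp = mrr_decompose(views, theta=1.0, k_max=3)
        decomp.loadings = np.eye(11)[:, :3]
        np.testing.assert_array_equal(salient_matrix(Z, decomp), Z[:, :3])

    def test_zero_input_gives_zero(self, rng):
        views = build_rank_views(rng.uniform(0, 10, (11, 11)))
        decomp = mrr_decompose(views)
        np.testing.assert_array_equal(salient_matrix(np.zeros((11, 11)), decomp),
                                      np.zeros((11, decomp.k_retained)))

    def test_matches_triple_loop_product(self, rng):
        Z = rng.uniform(0, 10, (11, 11))
        decomp = mrr_decompose(build_rank_views(Z), theta=1.0, k_max=7, k_min=7)
        T = salient_matrix(Z, decomp)
        P = decomp.loadings
        assert T.shape == (11, 7)
        for i in range(11):
            for j in range(7):
                expected = sum(Z[i, m] * P[m, j] for m in range(11))
                assert T[i, j] == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        decomp = mrr_decompose(build_rank_views(rng.uniform(0, 10, (11, 11))))
        with pytest.raises(StructuralError):
            salient_matrix(np.zeros((11, 12)), decomp)
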