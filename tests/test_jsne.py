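import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jembed.affinity import modality_P
from jembed.datatypes import JointConfig, ModalityView, entropy_objective
from jembed.jsne import (
    aggregate_P,
    jsne_gradient,
    kl_term,
    low_dim_Q,
    run_jsne,
    tsne_embed,
    update_weights,
)


def random_P(rng, n):
    raw = rng.random((n, n))
    raw = raw + raw.T
    np.fill_diagonal(raw, 0.0)
    return raw / raw.sum()


class TestAggregateP:
    def test_single_modality_identity(self, rng):
        P = random_P(rng, 6)
        np.testing.assert_array_equal(aggregate_P([P], np.array([1.0])), P)

    def test_half_half_is_elementwise_mean(self, rng):
        P1, P2 = random_P(rng, 5), random_P(rng, 5)
        np.testing.assert_allclose(
            aggregate_P([P1, P2], np.array([0.5, 0.5])), (P1 + P2) / 2
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_convexity_preserves_normalization(self, seed):
        r = np.random.default_rng(seed)
        Ps = [random_P(r, 7) for _ in range(3)]
        w = r.random(3)
        w /= w.sum()
        P_bar = aggregate_P(Ps, w)
        assert P_bar.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diag(P_bar) == 0)


class TestLowDimQ:
    def test_two_points_always_half(self, rng):
        Y = rng.normal(size=(2, 2)) * 10
        Q = low_dim_Q(Y)
        assert Q[0, 1] == pytest.approx(0.5)
        assert Q[1, 0] == pytest.approx(0.5)

    def test_equilateral_triangle_uniform(self):
        Y = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        Q = low_dim_Q(Y)
        off = Q[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 6.0, atol=1e-12)

    def test_hand_computed_collinear_points(self):
        # pairwise squared distances 1, 9, 4 -> kernels 1/2, 1/10, 1/5
        Y = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        Q = low_dim_Q(Y)
        total = 2 * (0.5 + 0.1 + 0.2)
        assert Q[0, 1] == pytest.approx(0.5 / total)
        assert Q[0, 2] == pytest.approx(0.1 / total)
        assert Q[1, 2] == pytest.approx(0.2 / total)


class TestKlTerm:
    def test_identical_distributions_zero(self, rng):
        P = random_P(rng, 5)
        assert kl_term(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Q = np.array([[0.0, 0.9], [0.1, 0.0]])
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_term(P, Q) == pytest.approx(expected)
        assert expected == pytest.approx(0.5108, abs=1e-4)

    def test_nonnegative_for_valid_pairs(self, rng):
        for _ in range(10):
            P, Q = random_P(rng, 6), random_P(rng, 6)
            assert kl_term(P, Q) >= -1e-12

    def test_zero_Q_where_P_positive_raises(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Q = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="KL undefined"):
            kl_term(P, Q)


class TestJsneGradient:
    def test_two_points_zero_gradient(self, rng):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Y = rng.normal(size=(2, 2))
        np.testing.assert_allclose(jsne_gradient(P, Y), 0.0, atol=1e-12)

    def test_matches_central_finite_differences(self, rng):
        n, d, h = 15, 2, 1e-6
        P = random_P(rng, n)
        Y = rng.normal(size=(n, d))
        grad = jsne_gradient(P, Y)
        num = np.zeros_like(Y)
        for i in range(n):
            for j in range(d):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, j] += h
                Ym[i, j] -= h
                num[i, j] = (
                    kl_term(P, low_dim_Q(Yp)) - kl_term(P, low_dim_Q(Ym))
                ) / (2 * h)
        rel = np.abs(grad - num) / max(np.abs(num).max(), 1e-12)
        assert rel.max() < 1e-4

    def test_translation_invariance(self, rng):
        P = random_P(rng, 8)
        Y = rng.normal(size=(8, 2))
        g1 = jsne_gradient(P, Y)
        g2 = jsne_gradient(P, Y + np.array([5.0, -3.0]))
        np.testing.assert_allclose(g1, g2, atol=1e-9)


def simplex_grid_minimizer(L, lam, resolution=1e-3):
    """Brute-force minimization of the weight objective on a simplex grid."""
    L = np.asarray(L, float)
    ticks = np.arange(0.0, 1.0 + resolution / 2, resolution)
    if len(L) == 2:
        cands = np.stack([ticks, 1.0 - ticks], axis=1)
    elif len(L) == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        mask = a + b <= 1.0 + 1e-12
        cands = np.stack([a[mask], b[mask], 1.0 - a[mask] - b[mask]], axis=1)
        cands = np.clip(cands, 0.0, 1.0)
    else:
        raise NotImplementedError
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(cands > 0, cands * np.log(cands), 0.0).sum(axis=1)
    obj = cands @ L + lam * ent
    return cands[np.argmin(obj)]


class TestUpdateWeights:
    def test_huge_lambda_gives_uniform(self):
        alpha = update_weights(np.array([0.1, 5.0, 2.0]), 1e6)
        np.testing.assert_allclose(alpha, 1.0 / 3.0, atol=1e-4)

    def test_lambda_zero_selects_most_informative_modality(self):
        alpha = update_weights(np.array([0.4, 0.2, 0.9]), 0.0)
        np.testing.assert_array_equal(alpha, [0.0, 1.0, 0.0])

    def test_lambda_zero_tie_breaks_to_first(self):
        alpha = update_weights(np.array([0.3, 0.3]), 0.0)
        np.testing.assert_array_equal(alpha, [1.0, 0.0])

    def test_closed_form_two_losses(self):
        alpha = update_weights(np.array([1.0, 2.0]), 1.0)
        np.testing.assert_allclose(alpha, [0.7311, 0.2689], atol=1e-4)

    def test_matches_simplex_grid_search(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 4))
            L = rng.random(K) * 3
            lam = float(rng.random() * 3 + 0.05)
            alpha = update_weights(L, lam)
            brute = simplex_grid_minimizer(L, lam)
            np.testing.assert_allclose(alpha, brute, atol=2e-3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_simplex_and_monotone(self, seed):
        r = np.random.default_rng(seed)
        L = r.random(4) * 5
        alpha = update_weights(L, float(r.random() * 5 + 1e-3))
        assert alpha.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(alpha >= 0)
        # smaller loss never gets smaller weight
        order = np.argsort(L)
        assert np.all(np.diff(alpha[order]) <= 1e-12)

    def test_empty_losses_raise(self):
        with pytest.raises(ValueError):
            update_weights(np.array([]), 1.0)


class TestRunJsne:
    def test_single_modality_reduces_to_plain_tsne(self, rng, quick_config):
        view = ModalityView(rng.normal(size=(40, 4)), "m")
        res = run_jsne([view], quick_config)
        assert all(np.allclose(rec.alpha, [1.0]) for rec in res.history)
        P = modality_P(view, quick_config.perplexity)
        ref = tsne_embed(P, quick_config)
        np.testing.assert_allclose(res.embedding, ref, atol=1e-12)

    def test_objective_non_increasing_across_weight_update(self, rng, quick_config):
        views = [
            ModalityView(rng.normal(size=(40, 4)), "a"),
            ModalityView(rng.normal(size=(40, 4)) * 2, "b"),
        ]
        res = run_jsne(views, quick_config)
        prev_alpha = np.full(2, 0.5)
        for rec in res.history:
            before = entropy_objective(rec.losses, prev_alpha, quick_config.lambda_reg)
            assert rec.objective <= before + 1e-9
            prev_alpha = rec.alpha

    def test_deterministic_given_seed(self, rng, quick_config):
        views = [ModalityView(rng.normal(size=(30, 3)), "a")]
        r1 = run_jsne(views, quick_config)
        r2 = run_jsne(views, quick_config)
        np.testing.assert_array_equal(r1.embedding, r2.embedding)
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_fixed_uniform_weight_baseline(self, rng, quick_config):
        from dataclasses import replace

        views = [
            ModalityView(rng.normal(size=(30, 3)), "a"),
            ModalityView(rng.normal(size=(30, 5)), "b"),
        ]
        res = run_jsne(views, replace(quick_config, fixed_uniform_weights=True))
        for rec in res.history:
            np.testing.assert_allclose(rec.alpha, 0.5)

    def test_mismatched_cell_counts_raise(self, rng, quick_config):
        views = [
            ModalityView(rng.normal(size=(30, 3)), "a"),
            ModalityView(rng.normal(size=(20, 3)), "b"),
        ]
        with pytest.raises(ValueError, match="cells"):
            run_jsne(views, quick_config)

    def test_default_max_outer_iterations(self):
        assert JointConfig().max_outer_iter == 10
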