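"""Fusion rules: Gompertz ranking, weighted average, Sugeno integral, tuner."""

import math

import numpy as np
import pytest

from mammofuse import (
    FusionConfig,
    GompertzParams,
    ScoreTensor,
    compute_ranks,
    fuzzy_rank_fusion,
    gompertz_rank,
    solve_lambda,
    sugeno_fusion,
    top_k_sets,
    tune_gompertz_params,
    weighted_average_fusion,
)

from conftest import brute_force_fuzzy_rank, random_tensor, scalar_gompertz


class TestGompertzRank:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.0, 0.6321206), (0.5, 0.3077994), (1.0, 0.1265770)],
    )
    def test_default_form_scalar_values(self, score, expected):
        """Defaults give 1 - exp(-exp(-2 s)); frozen high-precision values."""
        assert gompertz_rank(score) == pytest.approx(expected, abs=5e-8)

    def test_confident_scores_get_lower_ranks(self):
        assert gompertz_rank(1.0) < gompertz_rank(0.5) < gompertz_rank(0.0)

    def test_strictly_decreasing_on_grid(self):
        """Monotonicity of the rank transform on a 1,000-point grid."""
        grid = np.linspace(0, 1, 1000)
        ranks = gompertz_rank(grid)
        assert np.all(np.diff(ranks) < 0)
        assert np.all((ranks > 0) & (ranks < 1))

    def test_custom_params_match_closed_form(self):
        p = GompertzParams(m=0.8, n_shift=0.5, p=3.0)
        s = 0.37
        assert gompertz_rank(s, p) == pytest.approx(
            1 - 0.8 * math.exp(-math.exp(0.5 - 3.0 * s)), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan"), float("inf")])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            gompertz_rank(bad)

    @pytest.mark.parametrize(
        "kwargs", [{"m": 0.0}, {"m": 1.5}, {"p": 0.0}, {"p": -1.0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GompertzParams(**kwargs)


class TestComputeRanks:
    def test_constant_input_constant_output(self):
        t = ScoreTensor(np.full((2, 3, 4), 0.25))
        ranks = compute_ranks(t)
        assert np.allclose(ranks, gompertz_rank(0.25))

    def test_frozen_elementwise_values(self, worked_tensor):
        ranks = compute_ranks(ScoreTensor(np.array([[[0.7, 0.2, 0.1]]])))
        assert ranks.flatten() == pytest.approx(
            [0.2185444, 0.4884552, 0.5590090], abs=5e-8
        )

    def test_rank_order_reverses_score_order(self, rng):
        t = random_tensor(rng, n=3, samples=10, l=4)
        ranks = compute_ranks(t)
        assert np.array_equal(
            np.argsort(ranks, axis=-1), np.argsort(-t.scores, axis=-1)
        )


class TestTopKSets:
    def test_two_smallest_selected(self):
        member = top_k_sets(np.array([[[0.2, 0.5, 0.6]]]), k=2)
        assert member.tolist() == [[[True, True, False]]]

    def test_ties_break_to_lowest_class_index(self):
        member = top_k_sets(np.full((1, 1, 3), 0.4), k=2)
        assert member.tolist() == [[[True, True, False]]]

    def test_k_equals_l_selects_all(self):
        assert top_k_sets(np.random.default_rng(0).random((2, 3, 4)), k=4).all()

    @pytest.mark.parametrize("k", [0, 5])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            top_k_sets(np.zeros((1, 1, 4)), k=k)


class TestFuzzyRankFusion:
    def test_worked_example(self, worked_tensor):
        """Hand-enumerated three-classifier case, frozen before vectorising."""
        res = fuzzy_rank_fusion(worked_tensor)
        assert res.frs.flatten() == pytest.approx(
            [1.1584643, 1.1708853, 1.6866053], abs=5e-7
        )
        assert res.ccfs.flatten() == pytest.approx(
            [0.6, 0.6333333, 0.9], abs=5e-7
        )
        assert res.fused_score.flatten() == pytest.approx(
            [0.6950786, 0.7415607, 1.5179448], abs=5e-7
        )
        assert res.fused_class.tolist() == [1]

    def test_single_model_full_k_reduces_to_argmax(self, rng):
        t = random_tensor(rng, n=1, samples=25, l=4)
        res = fuzzy_rank_fusion(t, FusionConfig(k=4))
        assert np.array_equal(res.fused_class - 1, np.argmax(t.scores[0], axis=1))

    def test_uniform_scores_tie_break_to_first_class(self):
        t = ScoreTensor(np.full((3, 2, 3), 1 / 3))
        res = fuzzy_rank_fusion(t)
        assert np.allclose(res.fused_score[:, 0], res.fused_score[:, 1])
        assert np.all(res.fused_score[:, 2] > res.fused_score[:, 0])
        assert res.fused_class.tolist() == [1, 1]

    def test_matches_brute_force_oracle_on_random_tensors(self, rng):
        """Vectorised path equals a scalar loop re-implementation (200 draws)."""
        for _ in range(200):
            t = random_tensor(rng)
            k = int(rng.integers(1, t.n_classes + 1))
            res = fuzzy_rank_fusion(t, FusionConfig(k=k))
            classes, scores = brute_force_fuzzy_rank(t.scores.tolist(), k=k)
            assert res.fused_class.tolist() == classes
            assert np.allclose(res.fused_score, scores, atol=1e-9)

    def test_decision_is_argmin_of_product(self, rng):
        t = random_tensor(rng, n=4, samples=30, l=3)
        res = fuzzy_rank_fusion(t)
        assert np.array_equal(res.fused_class - 1, np.argmin(res.fused_score, axis=1))

    def test_classifier_order_invariance(self, rng):
        t = random_tensor(rng, n=4, samples=10, l=3)
        perm = rng.permutation(4)
        res_a = fuzzy_rank_fusion(t)
        res_b = fuzzy_rank_fusion(ScoreTensor(t.scores[perm]))
        assert np.array_equal(res_a.fused_class, res_b.fused_class)
        assert np.allclose(res_a.fused_score, res_b.fused_score)

    def test_class_relabel_equivariance(self, rng):
        t = random_tensor(rng, n=3, samples=40, l=4)
        perm = rng.permutation(4)
        res_a = fuzzy_rank_fusion(t)
        res_b = fuzzy_rank_fusion(ScoreTensor(t.scores[:, :, perm]))
        assert np.allclose(res_a.fused_score[:, perm], res_b.fused_score)
        unique_min = (
            np.sum(
                np.isclose(res_a.fused_score, res_a.fused_score.min(axis=1)[:, None]),
                axis=1,
            )
            == 1
        )
        inv = np.empty(4, dtype=int)
        inv[perm] = np.arange(4)
        assert np.array_equal(
            (res_b.fused_class - 1)[unique_min],
            inv[res_a.fused_class - 1][unique_min],
        )

    def test_k_larger_than_l_rejected(self, worked_tensor):
        with pytest.raises(ValueError):
            fuzzy_rank_fusion(worked_tensor, FusionConfig(k=4))

    def test_penalty_below_best_rank_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(penalty_rank=0.01)


class TestScoreTensorValidation:
    def test_mild_row_sum_violation_renormalised_with_warning(self):
        scores = np.array([[[0.5004, 0.5]]])
        with pytest.warns(UserWarning, match="renormalising"):
            t = ScoreTensor(scores)
        assert np.allclose(t.scores.sum(axis=2), 1.0)

    def test_gross_row_sum_violation_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScoreTensor(np.array([[[0.5, 0.3]]]))

    @pytest.mark.parametrize(
        "scores", [np.full((1, 1, 1), 1.0), -np.ones((1, 1, 2)) / 2]
    )
    def test_shape_and_sign_invariants(self, scores):
        with pytest.raises(ValueError):
            ScoreTensor(scores)


class TestWeightedAverage:
    def test_identical_classifiers_idempotent(self, rng):
        base = rng.dirichlet(np.ones(3), size=10)
        t = ScoreTensor(np.stack([base] * 4))
        res = weighted_average_fusion(t)
        assert np.allclose(res.fused_score, base)

    def test_hand_arithmetic_and_tie_break(self):
        t = ScoreTensor(np.array([[[0.6, 0.4]], [[0.3, 0.7]]]))
        res = weighted_average_fusion(t, weights=[2, 1])
        assert res.fused_score.flatten() == pytest.approx([0.5, 0.5])
        assert res.fused_class.tolist() == [1]

    def test_weight_scale_invariance(self, rng):
        t = random_tensor(rng, n=3, samples=15, l=3)
        w = [0.2, 0.5, 0.3]
        res_a = weighted_average_fusion(t, w)
        res_b = weighted_average_fusion(t, [7.3 * x for x in w])
        assert np.array_equal(res_a.fused_class, res_b.fused_class)
        assert np.allclose(res_a.fused_score, res_b.fused_score)

    def test_fused_rows_are_probability_vectors(self, rng):
        for _ in range(20):
            t = random_tensor(rng)
            w = rng.random(t.n_classifiers) + 0.01
            res = weighted_average_fusion(t, w)
            assert np.allclose(res.fused_score.sum(axis=1), 1.0, atol=1e-9)
            assert np.all((res.fused_score >= 0) & (res.fused_score <= 1))

    def test_classifier_permutation_with_co_permuted_weights(self, rng):
        t = random_tensor(rng, n=4, samples=10, l=3)
        w = np.array([0.1, 0.2, 0.3, 0.4])
        perm = rng.permutation(4)
        res_a = weighted_average_fusion(t, w)
        res_b = weighted_average_fusion(ScoreTensor(t.scores[perm]), w[perm])
        assert np.allclose(res_a.fused_score, res_b.fused_score)

    @pytest.mark.parametrize("weights", [[0, 0], [-1, 2], [1, 2, 3]])
    def test_invalid_weights_rejected(self, weights):
        t = ScoreTensor(np.full((2, 1, 2), 0.5))
        with pytest.raises(ValueError):
            weighted_average_fusion(t, weights)


class TestSolveLambda:
    def test_additive_densities_give_zero(self):
        assert solve_lambda([0.5, 0.5]) == 0.0

    def test_subunit_densities_match_quadratic_root(self):
        """For three equal densities g the measure equation collapses to
        g^3 l^2 + 3 g^2 l + (3 g - 1) = 0; compare with the analytic root."""
        g = 0.3
        analytic = (-3 * g**2 + math.sqrt(9 * g**4 - 4 * g**3 * (3 * g - 1))) / (
            2 * g**3
        )
        assert solve_lambda([g, g, g]) == pytest.approx(analytic, abs=1e-9)
        assert analytic == pytest.approx(0.3575838, abs=5e-7)

    def test_superunit_densities_give_negative_lambda(self):
        lam = solve_lambda([0.6, 0.6])
        assert -1 < lam < 0

    def test_residual_vanishes_on_random_densities(self, rng):
        for _ in range(25):
            g = rng.uniform(0.05, 0.95, size=int(rng.integers(2, 6)))
            lam = solve_lambda(g)
            assert abs(np.prod(1 + lam * g) - 1 - lam) < 1e-9

    @pytest.mark.parametrize("dens", [[0.0, 0.5], [1.0, 0.5], [-0.2, 0.3]])
    def test_invalid_densities_rejected(self, dens):
        with pytest.raises(ValueError):
            solve_lambda(dens)


class TestSugenoFusion:
    def test_identical_scores_idempotent(self):
        t = ScoreTensor(np.tile([[0.7, 0.2, 0.1]], (3, 5, 1)))
        res = sugeno_fusion(t, [0.4, 0.4, 0.4])
        assert np.allclose(res.fused_score, [0.7, 0.2, 0.1])

    def test_hand_evaluation_two_classifiers(self):
        t = ScoreTensor(np.array([[[0.9, 0.1]], [[0.2, 0.8]]]))
        res = sugeno_fusion(t, [0.5, 0.5])
        # class 1: max(min(0.9, 0.5), min(0.2, 1.0)) = 0.5
        assert res.fused_score[0, 0] == pytest.approx(0.5)

    def test_bounded_by_classifier_scores(self, rng):
        for _ in range(20):
            t = random_tensor(rng)
            g = rng.uniform(0.1, 0.9, size=t.n_classifiers)
            res = sugeno_fusion(t, g)
            lo = t.scores.min(axis=0) - 1e-12
            hi = t.scores.max(axis=0) + 1e-12
            assert np.all((res.fused_score >= lo) & (res.fused_score <= hi))

    def test_classifier_permutation_with_co_permuted_densities(self, rng):
        t = random_tensor(rng, n=4, samples=10, l=3)
        g = np.array([0.2, 0.3, 0.25, 0.15])
        perm = rng.permutation(4)
        res_a = sugeno_fusion(t, g)
        res_b = sugeno_fusion(ScoreTensor(t.scores[perm]), g[perm])
        assert np.allclose(res_a.fused_score, res_b.fused_score)
        assert np.array_equal(res_a.fused_class, res_b.fused_class)


class TestTuneGompertz:
    def _tensor_and_labels(self, rng, sep):
        labels = rng.integers(1, 4, size=30)
        scores = np.full((2, 30, 3), (1 - sep) / 2)
        scores[:, np.arange(30), labels - 1] = sep
        return ScoreTensor(scores), labels

    def _loss(self, tensor, labels, params, targets_params):
        t_true = gompertz_rank(1.0, targets_params)
        t_false = gompertz_rank(0.0, targets_params)
        onehot = np.eye(3, dtype=bool)[labels - 1]
        targets = np.where(onehot, t_true, t_false)[None]
        return float(np.mean((gompertz_rank(tensor.scores, params) - targets) ** 2))

    def test_zero_learning_rate_is_noop(self, rng):
        t, labels = self._tensor_and_labels(rng, 0.8)
        init = GompertzParams()
        assert tune_gompertz_params(t, labels, init, learning_rate=0.0,
                                    iterations=1) == init

    def test_perfect_separation_defaults_are_local_optimum(self, rng):
        """With true-class score 1, the default parameters already beat every
        +-0.1 perturbation on the frozen-target loss (grid oracle)."""
        labels = rng.integers(1, 4, size=20)
        scores = np.zeros((2, 20, 3))
        scores[:, np.arange(20), labels - 1] = 1.0
        t = ScoreTensor(scores)
        init = GompertzParams()
        base = self._loss(t, labels, init, init)
        for dm in (-0.1, 0, 0.1):
            for dn in (-0.1, 0, 0.1):
                for dp in (-0.1, 0, 0.1):
                    if dm == dn == dp == 0:
                        continue
                    pert = GompertzParams(m=1.0 + min(dm, 0), n_shift=dn, p=2 + dp)
                    assert self._loss(t, labels, pert, init) >= base - 1e-12

    def test_final_loss_never_exceeds_initial(self, rng):
        t, labels = self._tensor_and_labels(rng, 0.6)
        init = GompertzParams(m=0.9, n_shift=1.0, p=1.0)
        tuned = tune_gompertz_params(t, labels, init, learning_rate=0.1,
                                     iterations=25)
        assert self._loss(t, labels, tuned, init) <= self._loss(
            t, labels, init, init
        ) + 1e-15

    def test_misaligned_labels_rejected(self, rng):
        t, labels = self._tensor_and_labels(rng, 0.8)
        with pytest.raises(ValueError):
            tune_gompertz_params(t, labels[:-1])
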