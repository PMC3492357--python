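"""CRF engine: exact inference vs enumeration, gradients vs finite
differences, training behaviour, thresholded decoding, serialization."""

import io
import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from turnkit.crf import (
    CRFModel,
    TrainConfig,
    forward_backward,
    load_model,
    log_likelihood_and_gradient,
    path_score,
    predict,
    save_model,
    sequence_log_potentials,
    train,
    viterbi,
)
from turnkit.features import expand_context
from turnkit.simulate import SyntheticCorpusSpec, sample_crf_corpus


def enumerate_paths(node, edge):
    """Brute-force scores of all 2^L labelings."""
    L = node.shape[0]
    scores = {}
    for y in itertools.product((0, 1), repeat=L):
        s = node[0, y[0]]
        for t in range(1, L):
            s += edge[y[t - 1], y[t]] + node[t, y[t]]
        scores[y] = s
    return scores


def brute_force_inference(node, edge):
    scores = enumerate_paths(node, edge)
    vals = np.array(list(scores.values()))
    log_z = logsumexp(vals)
    L = node.shape[0]
    marg = np.zeros((L, 2))
    for y, s in scores.items():
        w = np.exp(s - log_z)
        for i, st in enumerate(y):
            marg[i, st] += w
    best = max(scores.values())
    return log_z, marg, best


class TestSequenceLogPotentials:
    def test_zero_weights_give_zero_scores(self):
        model = CRFModel(np.zeros((4, 2)), np.zeros((2, 2)))
        node, edge = sequence_log_potentials(model, np.ones((3, 4)))
        assert np.all(node == 0) and np.all(edge == 0)

    def test_one_hot_observation_selects_single_weight(self, rng):
        W = rng.normal(size=(5, 2))
        model = CRFModel(W, np.zeros((2, 2)))
        x = np.zeros((1, 5))
        x[0, 3] = 1.0
        node, _ = sequence_log_potentials(model, x)
        assert np.allclose(node[0], W[3])

    def test_dot_products_match_hand_arithmetic(self, rng):
        W = rng.normal(size=(4, 2))
        X = rng.normal(size=(3, 4))
        model = CRFModel(W, np.zeros((2, 2)))
        node, _ = sequence_log_potentials(model, X)
        assert np.allclose(node, X @ W)

    def test_dimension_mismatch_rejected(self):
        model = CRFModel(np.zeros((4, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            sequence_log_potentials(model, np.ones((3, 5)))


class TestForwardBackward:
    def test_single_position_closed_form(self):
        node = np.array([[1.3, -0.4]])
        lz, marg, _ = forward_backward(node, np.zeros((2, 2)))
        assert lz == pytest.approx(logsumexp(node[0]))
        assert np.allclose(marg[0], np.exp(node[0] - lz))

    def test_uniform_scores_give_uniform_marginals(self):
        lz, marg, _ = forward_backward(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.allclose(marg, 0.5)
        assert lz == pytest.approx(np.log(4.0))

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            L = int(rng.integers(1, 9))
            node = rng.normal(scale=2.0, size=(L, 2))
            edge = rng.normal(scale=2.0, size=(2, 2))
            lz, marg, _ = forward_backward(node, edge)
            lz_b, marg_b, _ = brute_force_inference(node, edge)
            assert abs(lz - lz_b) < 1e-8
            assert np.max(np.abs(marg - marg_b)) < 1e-8

    def test_marginal_rows_sum_to_one(self, rng):
        node = rng.normal(size=(50, 2))
        edge = rng.normal(size=(2, 2))
        _, marg, pair = forward_backward(node, edge)
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(pair.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_long_chain_no_underflow(self, rng):
        node = rng.normal(scale=5.0, size=(20000, 2))
        edge = rng.normal(size=(2, 2))
        lz, marg, _ = forward_backward(node, edge)
        assert np.isfinite(lz) and np.isfinite(marg).all()

    def test_non_finite_scores_rejected(self):
        node = np.array([[np.inf, 0.0]])
        with pytest.raises(ValueError):
            forward_backward(node, np.zeros((2, 2)))


class TestViterbi:
    def test_single_position_argmax(self):
        assert viterbi(np.array([[0.1, 0.7]]), np.zeros((2, 2)))[0] == 1

    def test_ties_break_toward_nonturn(self):
        path = viterbi(np.zeros((5, 2)), np.zeros((2, 2)))
        assert np.all(path == 0)

    def test_matches_enumeration_best_score(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = int(rng.integers(2, 7))
            node = rng.normal(scale=2.0, size=(L, 2))
            edge = rng.normal(scale=2.0, size=(2, 2))
            path = viterbi(node, edge)
            _, _, best = brute_force_inference(node, edge)
            assert path_score(node, edge, path) == pytest.approx(best)


class TestLikelihoodAndGradient:
    def test_zero_weights_uniform_loglik(self):
        model = CRFModel(np.zeros((3, 2)), np.zeros((2, 2)), l2_sigma=1e12)
        X = np.ones((1, 3))
        y = np.array([1])
        ll, _, _ = log_likelihood_and_gradient(model, [(X, y)])
        assert ll == pytest.approx(-np.log(2.0))

    def test_gradient_matches_finite_differences(self, rng):
        D = 4
        data = [(rng.normal(size=(int(rng.integers(1, 6)), D)), None)
                for _ in range(3)]
        data = [(X, rng.integers(0, 2, X.shape[0])) for X, _ in data]
        for _ in range(10):
            W = rng.normal(scale=0.5, size=(D, 2))
            T = rng.normal(scale=0.5, size=(2, 2))
            model = CRFModel(W, T, l2_sigma=2.0)
            ll, gW, gT = log_likelihood_and_gradient(model, data)
            eps = 1e-6
            for idx in [(0, 0), (2, 1), (3, 0)]:
                Wp = W.copy(); Wp[idx] += eps
                Wm = W.copy(); Wm[idx] -= eps
                lp, _, _ = log_likelihood_and_gradient(
                    CRFModel(Wp, T, l2_sigma=2.0), data)
                lm, _, _ = log_likelihood_and_gradient(
                    CRFModel(Wm, T, l2_sigma=2.0), data)
                fd = (lp - lm) / (2 * eps)
                assert gW[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)
            Tp = T.copy(); Tp[0, 1] += eps
            Tm = T.copy(); Tm[0, 1] -= eps
            lp, _, _ = log_likelihood_and_gradient(
                CRFModel(W, Tp, l2_sigma=2.0), data)
            lm, _, _ = log_likelihood_and_gradient(
                CRFModel(W, Tm, l2_sigma=2.0), data)
            assert gT[0, 1] == pytest.approx((lp - lm) / (2 * eps),
                                             rel=1e-5, abs=1e-7)

    def test_large_sigma_recovers_unpenalized_likelihood(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([0, 1, 1, 0])
        W = rng.normal(size=(3, 2))
        T = rng.normal(size=(2, 2))
        ll_big, _, _ = log_likelihood_and_gradient(
            CRFModel(W, T, l2_sigma=1e9), [(X, y)])
        ll_small, _, _ = log_likelihood_and_gradient(
            CRFModel(W, T, l2_sigma=1.0), [(X, y)])
        penalty = (np.sum(W ** 2) + np.sum(T ** 2)) / 2.0
        assert ll_big == pytest.approx(ll_small + penalty, rel=1e-6)

    def test_label_swap_symmetry(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array([0, 1, 1, 0, 1, 0])
        W = rng.normal(size=(3, 2))
        T = rng.normal(size=(2, 2))
        ll, _, _ = log_likelihood_and_gradient(
            CRFModel(W, T, l2_sigma=3.0), [(X, y)])
        ll_swap, _, _ = log_likelihood_and_gradient(
            CRFModel(W[:, ::-1], T[::-1, ::-1], l2_sigma=3.0), [(X, 1 - y)])
        assert ll == pytest.approx(ll_swap)


class TestTraining:
    def test_separable_data_high_heldout_accuracy(self, small_corpus):
        expanded = [(expand_context(ft), y) for ft, y in small_corpus]
        model = train(expanded[:9], TrainConfig(max_iterations=150))
        correct = total = 0
        for X, y in expanded[9:]:
            res = predict(model, X)
            correct += int(np.sum(res.labels == y))
            total += len(y)
        assert correct / total >= 0.9

    def test_single_observation_moves_toward_label(self):
        X = np.ones((1, 2))
        with pytest.warns(UserWarning):  # one sequence, one class
            model = train([(X, np.array([1]))], TrainConfig(max_iterations=50))
        assert predict(model, X).turn_probability[0] > 0.5

    def test_training_is_deterministic(self, small_corpus):
        expanded = [(expand_context(ft), y) for ft, y in small_corpus[:4]]
        cfg = TrainConfig(max_iterations=30, seed=5)
        m1 = train(expanded, cfg)
        m2 = train(expanded, cfg)
        assert np.array_equal(m1.unigram_weights, m2.unigram_weights)
        assert np.array_equal(m1.transition_weights, m2.transition_weights)

    def test_fitted_model_beats_zero_model(self, small_corpus):
        expanded = [(expand_context(ft), y) for ft, y in small_corpus[:6]]
        model = train(expanded, TrainConfig(max_iterations=80))
        ll_fit, _, _ = log_likelihood_and_gradient(model, expanded)
        zero = CRFModel(np.zeros_like(model.unigram_weights),
                        np.zeros((2, 2)), l2_sigma=model.l2_sigma)
        ll_zero, _, _ = log_likelihood_and_gradient(zero, expanded)
        assert ll_fit >= ll_zero

    def test_single_class_dataset_warns(self):
        X = np.ones((5, 2))
        y = np.zeros(5, dtype=int)
        with pytest.warns(UserWarning, match="single label class"):
            train([(X, y)], TrainConfig(max_iterations=10))

    def test_parameter_recovery_posterior_correlation(self):
        # sample from a known generating process, refit, compare held-out
        # posteriors with the truth labels
        spec = SyntheticCorpusSpec(n_sequences=80, length_low=50,
                                   length_high=50, seed=21)
        corpus = sample_crf_corpus(spec)
        expanded = [(expand_context(ft), y) for ft, y in corpus]
        model = train(expanded[:60], TrainConfig(max_iterations=150))
        probs, ys = [], []
        for X, y in expanded[60:]:
            probs.append(predict(model, X).turn_probability)
            ys.append(y)
        r = np.corrcoef(np.concatenate(probs), np.concatenate(ys))[0, 1]
        assert r >= 0.9


class TestPredict:
    def test_threshold_is_inclusive(self):
        model = CRFModel(np.zeros((2, 2)), np.zeros((2, 2)))
        res = predict(model, np.ones((3, 2)), threshold=0.5)
        assert np.allclose(res.turn_probability, 0.5)
        assert np.all(res.labels == 1)   # marginal 0.5 >= threshold 0.5

    def test_lower_threshold_labels_superset(self, small_corpus):
        X = expand_context(small_corpus[0][0])
        expanded = [(expand_context(ft), y) for ft, y in small_corpus[:6]]
        model = train(expanded, TrainConfig(max_iterations=60))
        lo = predict(model, X, threshold=0.2).labels
        hi = predict(model, X, threshold=0.5).labels
        assert np.all(hi <= lo)

    def test_monotone_decision_in_threshold(self, rng):
        model = CRFModel(rng.normal(size=(4, 2)), rng.normal(size=(2, 2)))
        X = rng.normal(size=(30, 4))
        sizes = [predict(model, X, threshold=t).labels.sum()
                 for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_model_round_trip_is_exact(rng):
    model = CRFModel(rng.normal(size=(6, 2)), rng.normal(size=(2, 2)),
                     l2_sigma=0.7, feature_names=[f"f{i}" for i in range(6)])
    buf = io.StringIO()
    save_model(model, buf)
    buf.seek(0)
    back = load_model(buf)
    assert np.array_equal(back.unigram_weights, model.unigram_weights)
    assert np.array_equal(back.transition_weights, model.transition_weights)
    assert back.feature_names == model.feature_names
    assert back.l2_sigma == model.l2_sigma
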