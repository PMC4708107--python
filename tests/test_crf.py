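"""Linear-chain CRF mechanics: decoding optimality, gradients, training."""

import itertools
import random

import numpy as np
import pytest

from cytolex.crf import (
    CRFTrainingError,
    LABELS,
    L,
    LinearChainCRF,
    _Batch,
    _corpus_nll_grad,
)


def random_model(rng, n_feats=6, reg=1.0, bias=1.0, bias_mode="train"):
    crf = LinearChainCRF(reg=reg, label_bias=bias, bias_mode=bias_mode)
    crf.feature_vocab = {f"f{i}": i for i in range(n_feats)}
    crf.W = rng.normal(size=(n_feats, L))
    crf.trans = rng.normal(size=(L, L))
    crf.start = rng.normal(size=L)
    crf.stop = rng.normal(size=L)
    return crf


def random_sentence(rng, n_feats=6, max_len=8):
    T = rng.integers(1, max_len + 1)
    return [
        [f"f{i}" for i in rng.choice(n_feats, size=rng.integers(1, 4), replace=False)]
        for _ in range(T)
    ]


class TestViterbi:
    @pytest.mark.parametrize("bias_mode, bias", [("train", 1.0), ("train", 3.0), ("decode", 2.0)])
    def test_matches_exhaustive_enumeration(self, bias_mode, bias):
        rng = np.random.default_rng(0)
        crf = random_model(rng, bias=bias, bias_mode=bias_mode)
        for _ in range(50):
            sent = random_sentence(rng)
            best = max(
                itertools.product(LABELS, repeat=len(sent)),
                key=lambda path: crf.sequence_score(sent, list(path)),
            )
            vit = crf.predict(sent)
            assert crf.sequence_score(sent, vit) == pytest.approx(
                crf.sequence_score(sent, list(best))
            )

    def test_empty_sentence(self):
        crf = random_model(np.random.default_rng(1))
        assert crf.predict([]) == []

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        crf = random_model(rng)
        sent = random_sentence(rng)
        assert crf.predict(sent) == crf.predict(sent)

    def test_path_score_bounds_gold_and_random_paths(self):
        rng = np.random.default_rng(3)
        crf = random_model(rng)
        pyrng = random.Random(3)
        for _ in range(20):
            sent = random_sentence(rng)
            vit_score = crf.sequence_score(sent, crf.predict(sent))
            for _ in range(10):
                path = [pyrng.choice(LABELS) for _ in sent]
                assert vit_score >= crf.sequence_score(sent, path) - 1e-9

    def test_unfitted_model_rejects_prediction(self):
        with pytest.raises(CRFTrainingError):
            LinearChainCRF().predict([["f0"]])


class TestGradients:
    @pytest.mark.parametrize("bias", [1.0, 2.5])
    def test_analytic_gradient_matches_finite_differences(self, bias):
        rng = np.random.default_rng(4)
        vocab: dict[str, int] = {}
        sents, labs = [], []
        for _ in range(4):
            sent = random_sentence(rng, max_len=5)
            sents.append([[vocab.setdefault(f, len(vocab)) for f in fs] for fs in sent])
            labs.append(list(rng.integers(0, L, size=len(sent))))
        batch = _Batch(sents, labs)
        W = rng.normal(size=(len(vocab), L))
        trans, start, stop = rng.normal(size=(L, L)), rng.normal(size=L), rng.normal(size=L)
        scale = np.array([1.0, bias, bias])
        nll, dW, dtrans, dstart, dstop = _corpus_nll_grad(batch, W, trans, start, stop, scale)
        eps = 1e-6
        checks = [(W, dW, (0, 1)), (W, dW, (2, 2)), (trans, dtrans, (1, 2)),
                  (start, dstart, (0,)), (stop, dstop, (2,))]
        for arr, grad, idx in checks:
            arr[idx] += eps
            nll2 = _corpus_nll_grad(batch, W, trans, start, stop, scale)[0]
            arr[idx] -= eps
            assert (nll2 - nll) / eps == pytest.approx(grad[idx], abs=1e-4)


class TestTraining:
    def small_corpus(self):
        X = [
            [["w=the"], ["w=K562", "shape=A0"], ["w=line"]],
            [["w=we"], ["w=used"], ["w=GOS", "shape=A"], ["w=-"], ["w=3", "shape=0"]],
            [["w=plain"], ["w=words"]],
        ] * 4
        y = [["O", "B", "O"], ["O", "O", "B", "I", "I"], ["O", "O"]] * 4
        return X, y

    def test_memorizable_corpus_recovered(self):
        X, y = self.small_corpus()
        crf = LinearChainCRF(reg=0.1, max_iter=100).fit(X, y)
        assert crf.predict(X[0]) == y[0]
        assert crf.predict(X[1]) == y[1]

    def test_training_reproducible(self):
        X, y = self.small_corpus()
        a = LinearChainCRF(reg=0.1, max_iter=50).fit(X, y)
        b = LinearChainCRF(reg=0.1, max_iter=50).fit(X, y)
        assert np.array_equal(a.W, b.W)

    def test_all_o_corpus_rejected(self):
        with pytest.raises(CRFTrainingError):
            LinearChainCRF().fit([[["w=a"]], [["w=b"]]], [["O"], ["O"]])

    def test_empty_corpus_rejected(self):
        with pytest.raises(CRFTrainingError):
            LinearChainCRF().fit([], [])

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            LinearChainCRF(reg=0.0)
        with pytest.raises(ValueError):
            LinearChainCRF(label_bias=-1.0)
        with pytest.raises(ValueError):
            LinearChainCRF(bias_mode="magic")


class TestSerialization:
    def test_state_dict_round_trip_preserves_predictions(self):
        X = [[["w=the"], ["w=K562"]], [["w=GOS"], ["w=-"], ["w=3"]]] * 3
        y = [["O", "B"], ["B", "I", "I"]] * 3
        crf = LinearChainCRF(reg=0.5, max_iter=60).fit(X, y)
        clone = LinearChainCRF.from_state_dict(crf.state_dict())
        for sent in X:
            assert clone.predict(sent) == crf.predict(sent)
        assert np.array_equal(np.array(clone.W), np.array(crf.W))
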