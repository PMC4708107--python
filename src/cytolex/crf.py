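"""First-order linear-chain conditional random field over BIO labels.

The model assigns a sequence of labels :math:`y_{1..T}` to a token sequence
with score

.. math::

    s(x, y) = a_{y_1} + \\sum_t s_b \\, w_{y_t} \\cdot f(x, t)
             + \\sum_t A_{y_{t-1} y_t} + b_{y_T}

where :math:`f(x, t)` is a sparse binary feature vector, :math:`A` is the
label transition matrix, :math:`a, b` are start/stop scores and
:math:`s_b` is a per-label scale implementing the *label bias*: non-O
emission features are scaled by the bias, which (under L2 regularization)
makes non-O scores cheaper to express and tilts the precision/recall
balance toward recall as the bias grows. Training maximizes the penalized
conditional log-likelihood with L-BFGS; decoding is exact Viterbi. An
alternative bias mechanism adds ``log(bias)`` to non-O emissions at decode
time only (``bias_mode="decode"``).

Sentences are padded into batch arrays so the forward–backward recursions
run vectorized across the whole corpus per optimizer iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

LABELS: tuple[str, ...] = ("O", "B", "I")
L = len(LABELS)
LABEL_TO_ID = {lab: i for i, lab in enumerate(LABELS)}


class CRFTrainingError(ValueError):
    """Training input is unusable (empty corpus, no entity labels...)."""


class _Batch:
    """Padded batch view of a corpus of feature-indexed sentences."""

    def __init__(self, xs: list[list[list[int]]], ys: list[list[int]] | None):
        self.n = len(xs)
        self.lengths = np.array([len(s) for s in xs], dtype=np.int64)
        self.tmax = int(self.lengths.max()) if self.n else 0
        sent_idx, pos_idx, feat_idx = [], [], []
        for si, sent in enumerate(xs):
            for ti, feats in enumerate(sent):
                for f in feats:
                    sent_idx.append(si)
                    pos_idx.append(ti)
                    feat_idx.append(f)
        self.sent_idx = np.array(sent_idx, dtype=np.int64)
        self.pos_idx = np.array(pos_idx, dtype=np.int64)
        self.feat_idx = np.array(feat_idx, dtype=np.int64)
        self.mask = np.zeros((self.n, self.tmax), dtype=bool)
        for si, ln in enumerate(self.lengths):
            self.mask[si, :ln] = True
        if ys is not None:
            self.y = np.zeros((self.n, self.tmax), dtype=np.int64)
            for si, labs in enumerate(ys):
                self.y[si, : len(labs)] = labs
        else:
            self.y = None

    def emissions(self, W: np.ndarray, scale: np.ndarray) -> np.ndarray:
        """Emission score array (n, tmax, L) from sparse feature triples."""
        E = np.zeros((self.n, self.tmax, L))
        if len(self.feat_idx):
            np.add.at(E, (self.sent_idx, self.pos_idx), W[self.feat_idx])
        return E * scale[None, None, :]


class LinearChainCRF:
    """Linear-chain CRF with L2 penalty and a recall-tilting label bias.

    Parameters
    ----------
    reg:
        L2 regularization strength (coefficient of ``0.5 * ||theta||^2``).
    label_bias:
        Weight > 0 on non-O labels; 1.0 is neutral, larger values favour
        recall.
    bias_mode:
        ``"train"`` scales non-O emission features during training and
        decoding (per-class regularization relief); ``"decode"`` trains
        unbiased and adds ``log(label_bias)`` to non-O emissions at
        decoding only.
    max_iter:
        L-BFGS iteration cap.
    seed:
        Recorded for provenance; the optimization itself is deterministic
        given input order (zero initialization).
    """

    def __init__(
        self,
        reg: float = 1.0,
        label_bias: float = 1.0,
        bias_mode: str = "train",
        max_iter: int = 100,
        seed: int = 42,
    ):
        if reg <= 0:
            raise ValueError("reg must be > 0")
        if label_bias <= 0:
            raise ValueError("label_bias must be > 0")
        if bias_mode not in {"train", "decode"}:
            raise ValueError(f"unknown bias_mode {bias_mode!r}")
        self.reg = float(reg)
        self.label_bias = float(label_bias)
        self.bias_mode = bias_mode
        self.max_iter = int(max_iter)
        self.seed = int(seed)
        self.feature_vocab: dict[str, int] = {}
        self.W: np.ndarray | None = None
        self.trans: np.ndarray | None = None
        self.start: np.ndarray | None = None
        self.stop: np.ndarray | None = None

    # -- parameter packing ---------------------------------------------------

    def _pack(self, W, trans, start, stop) -> np.ndarray:
        return np.concatenate([W.ravel(), trans.ravel(), start, stop])

    def _unpack(self, theta: np.ndarray):
        F = len(self.feature_vocab)
        W = theta[: F * L].reshape(F, L)
        off = F * L
        trans = theta[off : off + L * L].reshape(L, L)
        off += L * L
        start = theta[off : off + L]
        stop = theta[off + L : off + 2 * L]
        return W, trans, start, stop

    @property
    def _train_scale(self) -> np.ndarray:
        s = np.ones(L)
        if self.bias_mode == "train":
            s[1:] = self.label_bias
        return s

    def _decode_offset(self) -> np.ndarray:
        off = np.zeros(L)
        if self.bias_mode == "decode":
            off[1:] = np.log(self.label_bias)
        return off

    # -- training ------------------------------------------------------------

    def fit(
        self, X: list[list[list[str]]], y: list[list[str]]
    ) -> "LinearChainCRF":
        """Fit on a corpus of sentences.

        ``X[i][t]`` is the feature-string list of token ``t`` in sentence
        ``i``; ``y[i][t]`` its BIO label. Sentences must be non-empty and
        IOB2-valid; the corpus must contain at least one ``B`` label.
        """
        X = [s for s in X if s]
        y = [labs for labs in y if labs]
        if not X or len(X) != len(y) or any(len(s) != len(l) for s, l in zip(X, y)):
            raise CRFTrainingError("empty corpus or mismatched features/labels")
        if not any("B" in labs for labs in y):
            raise CRFTrainingError("corpus contains no B labels; nothing to learn")

        vocab: dict[str, int] = {}
        xs: list[list[list[int]]] = []
        for sent in X:
            xs.append(
                [[vocab.setdefault(f, len(vocab)) for f in feats] for feats in sent]
            )
        self.feature_vocab = vocab
        ys = [[LABEL_TO_ID[lab] for lab in labs] for labs in y]
        batch = _Batch(xs, ys)
        scale = self._train_scale

        n_params = len(vocab) * L + L * L + 2 * L
        theta0 = np.zeros(n_params)

        def objective(theta: np.ndarray):
            W, trans, start, stop = self._unpack(theta)
            nll, dW, dtrans, dstart, dstop = _corpus_nll_grad(
                batch, W, trans, start, stop, scale
            )
            nll += 0.5 * self.reg * float(theta @ theta)
            grad = self._pack(dW, dtrans, dstart, dstop) + self.reg * theta
            return nll, grad

        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-8},
        )
        self.W, self.trans, self.start, self.stop = self._unpack(res.x)
        return self

    # -- scoring and decoding --------------------------------------------------

    def _token_scores(self, feats_seq: list[list[str]]) -> np.ndarray:
        """Decode-time emission matrix (T, L) for one sentence."""
        assert self.W is not None, "model not fitted"
        E = np.zeros((len(feats_seq), L))
        for t, feats in enumerate(feats_seq):
            for f in feats:
                idx = self.feature_vocab.get(f)
                if idx is not None:
                    E[t] += self.W[idx]
        E *= self._train_scale[None, :]
        E += self._decode_offset()[None, :]
        return E

    def sequence_score(self, feats_seq: list[list[str]], labels: list[str]) -> float:
        """Decode-consistent score of one label path (used by exhaustive
        enumeration checks)."""
        if not feats_seq:
            return 0.0
        E = self._token_scores(feats_seq)
        ids = [LABEL_TO_ID[lab] for lab in labels]
        s = self.start[ids[0]] + self.stop[ids[-1]]
        s += sum(E[t, i] for t, i in enumerate(ids))
        s += sum(self.trans[ids[t - 1], ids[t]] for t in range(1, len(ids)))
        return float(s)

    def predict(self, feats_seq: list[list[str]]) -> list[str]:
        """Exact maximum-a-posteriori (Viterbi) label path; deterministic,
        ties broken toward the lowest label index (O before B before I)."""
        if self.W is None:
            raise CRFTrainingError("model not fitted")
        T = len(feats_seq)
        if T == 0:
            return []
        E = self._token_scores(feats_seq)
        delta = self.start + E[0]
        back = np.zeros((T, L), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + self.trans  # (prev, cur)
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(L)] + E[t]
        delta = delta + self.stop
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [LABELS[i] for i in path]

    # -- serialization ---------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "reg": self.reg,
            "label_bias": self.label_bias,
            "bias_mode": self.bias_mode,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "features": list(self.feature_vocab),
            "W": self.W.tolist() if self.W is not None else None,
            "trans": self.trans.tolist() if self.trans is not None else None,
            "start": self.start.tolist() if self.start is not None else None,
            "stop": self.stop.tolist() if self.stop is not None else None,
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "LinearChainCRF":
        crf = cls(
            reg=state["reg"],
            label_bias=state["label_bias"],
            bias_mode=state["bias_mode"],
            max_iter=state["max_iter"],
            seed=state["seed"],
        )
        crf.feature_vocab = {f: i for i, f in enumerate(state["features"])}
        if state["W"] is not None:
            crf.W = np.array(state["W"])
            crf.trans = np.array(state["trans"])
            crf.start = np.array(state["start"])
            crf.stop = np.array(state["stop"])
        return crf


def _corpus_nll_grad(
    batch: _Batch,
    W: np.ndarray,
    trans: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    scale: np.ndarray,
):
    """Negative log-likelihood and gradients over a padded batch.

    Runs forward–backward vectorized over all sentences at once; padded
    positions are masked out of every sum.
    """
    n, tmax = batch.n, batch.tmax
    E = batch.emissions(W, scale)  # (n, tmax, L), already bias-scaled
    lengths = batch.lengths
    last = lengths - 1

    # forward
    alpha = np.full((n, tmax, L), -np.inf)
    alpha[:, 0] = start[None, :] + E[:, 0]
    for t in range(1, tmax):
        new = logsumexp(alpha[:, t - 1][:, :, None] + trans[None], axis=1) + E[:, t]
        active = batch.mask[:, t]
        alpha[:, t] = np.where(active[:, None], new, alpha[:, t])
    logZ = logsumexp(alpha[np.arange(n), last] + stop[None, :], axis=1)

    # backward
    beta = np.full((n, tmax, L), -np.inf)
    beta[np.arange(n), last] = stop[None, :]
    for t in range(tmax - 2, -1, -1):
        inner = E[:, t + 1] + beta[:, t + 1]  # (n, L)
        new = logsumexp(trans[None] + inner[:, None, :], axis=2)
        active = t < last  # position t is not this sentence's final one
        beta[:, t] = np.where(active[:, None], new, beta[:, t])

    # node marginals
    marg = np.exp(alpha + beta - logZ[:, None, None])
    marg[~batch.mask] = 0.0

    # gold one-hots
    gold = np.zeros((n, tmax, L))
    gold[np.arange(n)[:, None], np.arange(tmax)[None, :], batch.y] = 1.0
    gold[~batch.mask] = 0.0

    diff = marg - gold  # (n, tmax, L)

    dW = np.zeros_like(W)
    if len(batch.feat_idx):
        np.add.at(dW, batch.feat_idx, diff[batch.sent_idx, batch.pos_idx] * scale[None, :])

    # edge marginals / transition gradient
    dtrans = np.zeros((L, L))
    for t in range(1, tmax):
        active = batch.mask[:, t]
        if not active.any():
            break
        lp = (
            alpha[:, t - 1][:, :, None]
            + trans[None]
            + (E[:, t] + beta[:, t])[:, None, :]
            - logZ[:, None, None]
        )
        em = np.exp(lp)
        em[~active] = 0.0
        dtrans += em.sum(axis=0)
        prev_y, cur_y = batch.y[:, t - 1][active], batch.y[:, t][active]
        np.subtract.at(dtrans, (prev_y, cur_y), 1.0)

    dstart = diff[:, 0].sum(axis=0)
    dstop = diff[np.arange(n), last].sum(axis=0)

    # gold path score
    gold_em = (E * gold).sum()
    gold_start = start[batch.y[:, 0]].sum()
    gold_stop = stop[batch.y[np.arange(n), last]].sum()
    gold_trans = 0.0
    for t in range(1, tmax):
        active = batch.mask[:, t]
        if not active.any():
            break
        gold_trans += trans[batch.y[:, t - 1][active], batch.y[:, t][active]].sum()
    nll = float(logZ.sum() - (gold_em + gold_start + gold_stop + gold_trans))
    return nll, dW, dtrans, dstart, dstop
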