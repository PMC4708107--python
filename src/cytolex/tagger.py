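"""CRF tagger with orthographic and lexicon features.

Wraps the linear-chain CRF with: a feature template (surface form,
casing, affixes, compressed character shape, boolean orthographic flags,
strict-dictionary flags, all projected over a +-window context), grid
search over regularization and label-bias values on a development set,
and a final fit on the concatenation of training and development data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from cytolex.corpus import LabeledToken, Mention, decode_mentions, repair_bio
from cytolex.crf import CRFTrainingError, LinearChainCRF
from cytolex.dictionary import Lexicon
from cytolex.evaluation import EvalResult, evaluate_overlap
from cytolex.matcher import dictionary_features

Sentence = list[LabeledToken]
Corpus = list[Sentence]

DEFAULT_REG_GRID = (0.01, 0.1, 1.0, 10.0)
DEFAULT_BIAS_GRID = (0.5, 1.0, 2.0, 4.0)


def token_shape(surface: str) -> str:
    """Compressed orthographic shape: uppercase → A, lowercase → a,
    digit → 0, other → _, consecutive runs collapsed ("K562" → "A0")."""
    out: list[str] = []
    for ch in surface:
        if ch.isupper():
            c = "A"
        elif ch.islower():
            c = "a"
        elif ch.isdigit():
            c = "0"
        else:
            c = "_"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def _token_unigrams(
    t: LabeledToken, dict_flag: str | None, annotations: dict[str, str] | None
) -> list[str]:
    s = t.surface
    feats = [f"w={s}", f"low={s.lower()}", f"shape={token_shape(s)}"]
    for k in range(1, 5):
        if len(s) >= k:
            feats.append(f"pre{k}={s[:k]}")
            feats.append(f"suf{k}={s[-k:]}")
    if any(c.isdigit() for c in s):
        feats.append("has-digit")
    if "-" in s:
        feats.append("has-hyphen")
    if s.isupper() and any(c.isalpha() for c in s):
        feats.append("all-caps")
    if s[:1].isupper():
        feats.append("initial-cap")
    if dict_flag:
        feats.append(f"dict={dict_flag}")
    if annotations:
        for key, val in annotations.items():
            feats.append(f"{key}={val}")
    return feats


def extract_features(
    tokens: Sequence[LabeledToken],
    lexicon: Lexicon | None = None,
    window: int = 2,
    annotators: Sequence[Callable[[Sequence[LabeledToken]], list[dict[str, str]]]] = (),
) -> list[list[str]]:
    """Per-token feature lists for one sentence.

    Each token gets its own unigram features plus the unigram features of
    every neighbour within ``+-window``, prefixed by the relative position;
    positions beyond the sentence edge yield boundary sentinels. When a
    lexicon is given, strict-matching dictionary flags (DICT-B / DICT-I)
    are included. ``annotators`` may supply extra per-token annotations
    (e.g. lemma or POS columns) as ``{name: value}`` dicts.
    """
    n = len(tokens)
    flags = dictionary_features(tokens, lexicon) if lexicon is not None else [None] * n
    extra: list[dict[str, str]] = [{} for _ in range(n)]
    for ann in annotators:
        for i, d in enumerate(ann(tokens)):
            extra[i].update(d)
    unigrams = [
        _token_unigrams(t, flags[i], extra[i] or None) for i, t in enumerate(tokens)
    ]
    out: list[list[str]] = []
    for i in range(n):
        feats: list[str] = []
        for off in range(-window, window + 1):
            j = i + off
            if 0 <= j < n:
                feats.extend(f"[{off}]{u}" for u in unigrams[j])
            else:
                feats.append(f"[{off}]w=<{'BOS' if j < 0 else 'EOS'}>")
        out.append(feats)
    return out


def _template_hash(window: int, use_dict: bool) -> str:
    payload = json.dumps({"window": window, "use_dict": use_dict, "version": 1})
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def corpus_fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha1()
    for sent in corpus:
        for t in sent:
            h.update(f"{t.surface}\x00{t.bio_label}\x01".encode())
        h.update(b"\x02")
    return h.hexdigest()[:12]


@dataclass
class TaggerModel:
    """A trained CRF tagger plus the configuration needed to reapply it."""

    crf: LinearChainCRF
    window: int
    use_dict: bool
    metadata: dict = field(default_factory=dict)

    @property
    def template_hash(self) -> str:
        return _template_hash(self.window, self.use_dict)

    def save(self, path: str | Path) -> None:
        """Write the model as a directory: JSON weights payload plus a
        plain-text manifest (template hash, hyperparameters, seed)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "weights.json").write_text(json.dumps(self.crf.state_dict()))
        manifest = {
            "template_hash": self.template_hash,
            "window": self.window,
            "use_dict": self.use_dict,
            "reg": self.crf.reg,
            "label_bias": self.crf.label_bias,
            "bias_mode": self.crf.bias_mode,
            "seed": self.crf.seed,
            **self.metadata,
        }
        (path / "manifest.txt").write_text(
            "".join(f"{k}\t{v}\n" for k, v in manifest.items())
        )

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        path = Path(path)
        manifest: dict[str, str] = {}
        for line in (path / "manifest.txt").read_text().splitlines():
            k, v = line.split("\t", 1)
            manifest[k] = v
        crf = LinearChainCRF.from_state_dict(json.loads((path / "weights.json").read_text()))
        model = cls(
            crf=crf,
            window=int(manifest["window"]),
            use_dict=manifest["use_dict"] == "True",
            metadata={
                k: v
                for k, v in manifest.items()
                if k not in {"template_hash", "window", "use_dict", "reg",
                             "label_bias", "bias_mode", "seed"}
            },
        )
        if model.template_hash != manifest["template_hash"]:
            raise ValueError(
                "feature template incompatible with stored model "
                f"(expected {manifest['template_hash']}, got {model.template_hash})"
            )
        return model


def train(
    corpus: Corpus,
    lexicon: Lexicon | None = None,
    reg: float = 1.0,
    label_bias: float = 1.0,
    window: int = 2,
    bias_mode: str = "train",
    max_iter: int = 80,
    seed: int = 42,
) -> TaggerModel:
    """Fit a CRF tagger on an IOB2-labeled corpus.

    ``lexicon`` switches dictionary features on. Raises
    :class:`~cytolex.crf.CRFTrainingError` on an empty corpus or one with
    no entity (B) labels.
    """
    if not corpus:
        raise CRFTrainingError("empty training corpus")
    X = [extract_features(sent, lexicon, window) for sent in corpus]
    y = [[t.bio_label for t in sent] for sent in corpus]
    crf = LinearChainCRF(
        reg=reg, label_bias=label_bias, bias_mode=bias_mode, max_iter=max_iter, seed=seed
    )
    crf.fit(X, y)
    return TaggerModel(
        crf=crf,
        window=window,
        use_dict=lexicon is not None,
        metadata={"train_fingerprint": corpus_fingerprint(corpus)},
    )


def predict(
    model: TaggerModel, tokens: Sequence[LabeledToken], lexicon: Lexicon | None = None
) -> list[str]:
    """Viterbi-decode one sentence; output repaired to IOB2 validity."""
    if model.use_dict and lexicon is None:
        raise ValueError("model was trained with dictionary features; pass the lexicon")
    feats = extract_features(
        tokens, lexicon if model.use_dict else None, model.window
    )
    return repair_bio(model.crf.predict(feats))


def tag_sentences(
    model: TaggerModel,
    sentences: Sequence[Sequence[LabeledToken]],
    doc_id: str = "doc",
    text: str | None = None,
    lexicon: Lexicon | None = None,
) -> list[Mention]:
    """Tag a tokenized document and return decoded mentions."""
    mentions: list[Mention] = []
    for sent in sentences:
        labels = predict(model, sent, lexicon)
        mentions.extend(decode_mentions(sent, labels, doc_id=doc_id, text=text))
    return mentions


@dataclass
class GridSearchReport:
    """Per-configuration development-set results and the selected cell.

    The selected configuration maximizes dev F-score; ties go to the
    smaller regularization, then the smaller label bias.
    """

    results: dict[tuple[float, float], EvalResult]
    selected: tuple[float, float]

    def selected_result(self) -> EvalResult:
        return self.results[self.selected]


def _eval_on_corpus(
    model: TaggerModel, corpus: Corpus, lexicon: Lexicon | None
) -> EvalResult:
    pred: list[Mention] = []
    gold: list[Mention] = []
    for i, sent in enumerate(corpus):
        doc_id = f"s{i}"
        gold_labels = [t.bio_label for t in sent]
        gold.extend(decode_mentions(sent, gold_labels, doc_id=doc_id))
        labels = predict(model, sent, lexicon)
        pred.extend(decode_mentions(sent, labels, doc_id=doc_id))
    return evaluate_overlap(pred, gold)


def grid_search(
    train_corpus: Corpus,
    dev_corpus: Corpus,
    lexicon: Lexicon | None = None,
    reg_values: Sequence[float] = DEFAULT_REG_GRID,
    bias_values: Sequence[float] = DEFAULT_BIAS_GRID,
    window: int = 2,
    bias_mode: str = "train",
    max_iter: int = 80,
    seed: int = 42,
) -> GridSearchReport:
    """Train one model per (reg, bias) grid cell and score it on dev with
    the overlap criterion."""
    if not reg_values or not bias_values:
        raise ValueError("empty hyperparameter grid")
    results: dict[tuple[float, float], EvalResult] = {}
    for reg in reg_values:
        for bias in bias_values:
            model = train(
                train_corpus, lexicon, reg=reg, label_bias=bias, window=window,
                bias_mode=bias_mode, max_iter=max_iter, seed=seed,
            )
            results[(reg, bias)] = _eval_on_corpus(model, dev_corpus, lexicon)
    selected = max(
        results, key=lambda cfg: (results[cfg].f_score, -cfg[0], -cfg[1])
    )
    return GridSearchReport(results=results, selected=selected)


def finalize(
    train_corpus: Corpus,
    dev_corpus: Corpus,
    selected_config: tuple[float, float],
    lexicon: Lexicon | None = None,
    window: int = 2,
    bias_mode: str = "train",
    max_iter: int = 80,
    seed: int = 42,
) -> TaggerModel:
    """Train the final model on train+dev (in that order) under the grid
    winner; model metadata records both corpus fingerprints."""
    reg, bias = selected_config
    model = train(
        list(train_corpus) + list(dev_corpus), lexicon,
        reg=reg, label_bias=bias, window=window, bias_mode=bias_mode,
        max_iter=max_iter, seed=seed,
    )
    model.metadata["train_fingerprint"] = corpus_fingerprint(list(train_corpus))
    model.metadata["dev_fingerprint"] = corpus_fingerprint(list(dev_corpus))
    return model
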