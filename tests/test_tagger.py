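"""Feature template, grid search, finalization and model persistence."""

import pytest

from cytolex.corpus import tokenize
from cytolex.crf import CRFTrainingError
from cytolex.synthetic import corpus_to_sentences, gen_corpus, gen_records
from cytolex.dictionary import build_lexicon
from cytolex.tagger import (
    GridSearchReport,
    TaggerModel,
    extract_features,
    finalize,
    grid_search,
    predict,
    token_shape,
    train,
)


class TestFeatures:
    @pytest.mark.parametrize(
        "surface, shape",
        [("GOS", "A"), ("K562", "A0"), ("HeLa", "AaAa"), ("mcf-7", "a_0"), ("3T3", "0A0")],
    )
    def test_compressed_shape(self, surface, shape):
        assert token_shape(surface) == shape

    def test_token_unigram_content(self, gos3_lexicon):
        toks = tokenize("GOS-3 cells")
        feats = extract_features(toks, gos3_lexicon, window=1)
        own = [f for f in feats[0] if f.startswith("[0]")]
        assert "[0]w=GOS" in own
        assert "[0]low=gos" in own
        assert "[0]shape=A" in own
        assert "[0]all-caps" in own
        assert "[0]pre1=G" in own and "[0]suf2=OS" in own
        assert "[0]dict=DICT-B" in own

    def test_flags(self):
        toks = tokenize("K562")
        feats = extract_features(toks, window=0)
        assert "[0]has-digit" in feats[0]
        assert "[0]initial-cap" in feats[0]

    def test_window_boundary_sentinels(self):
        toks = tokenize("one")
        feats = extract_features(toks, window=1)
        assert "[-1]w=<BOS>" in feats[0]
        assert "[1]w=<EOS>" in feats[0]

    def test_neighbor_features_present(self):
        toks = tokenize("GOS-3 cells")
        feats = extract_features(toks, window=2)
        assert "[1]w=-" in feats[0]
        assert "[-1]w=3" in feats[3]

    def test_custom_annotator_plugs_in(self):
        toks = tokenize("K562 cells")
        ann = lambda ts: [{"pos": "NN"} for _ in ts]
        feats = extract_features(toks, window=0, annotators=[ann])
        assert "[0]pos=NN" in feats[0]


@pytest.fixture(scope="module")
def tiny_setup():
    records, _ = gen_records(20, seed=5)
    lexicon = build_lexicon(records)
    corpus = gen_corpus(lexicon, 60, seed=6, variant_rate=0.2)
    train_sents = [s for _, _, s in corpus_to_sentences(corpus, "train")]
    dev_sents = [s for _, _, s in corpus_to_sentences(corpus, "dev")]
    return lexicon, train_sents, dev_sents


class TestTrainPredict:
    def test_train_and_predict_smoke(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        model = train(train_sents, lexicon, reg=0.1, max_iter=60)
        labeled = next(s for s in dev_sents if any(t.bio_label == "B" for t in s))
        labels = predict(model, labeled, lexicon)
        assert len(labels) == len(labeled)
        assert set(labels) <= {"B", "I", "O"}

    def test_predict_output_is_iob2_valid(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        model = train(train_sents, lexicon, reg=0.1, max_iter=60)
        for sent in dev_sents:
            labels = predict(model, sent, lexicon)
            prev = "O"
            for lab in labels:
                assert not (lab == "I" and prev == "O")
                prev = lab

    def test_dict_model_requires_lexicon_at_predict(self, tiny_setup):
        lexicon, train_sents, _ = tiny_setup
        model = train(train_sents[:20], lexicon, max_iter=30)
        with pytest.raises(ValueError, match="lexicon"):
            predict(model, train_sents[0], None)

    def test_label_bias_raises_recall(self, tiny_setup):
        """Larger label bias trades precision for recall (trained variant)."""
        from cytolex.tagger import _eval_on_corpus

        lexicon, train_sents, dev_sents = tiny_setup
        low = train(train_sents, None, reg=1.0, label_bias=1.0, max_iter=60)
        high = train(train_sents, None, reg=1.0, label_bias=4.0, max_iter=60)
        r_low = _eval_on_corpus(low, dev_sents, None)
        r_high = _eval_on_corpus(high, dev_sents, None)
        assert r_high.recall >= r_low.recall


class TestGridSearch:
    def test_selected_maximizes_dev_f(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        report = grid_search(
            train_sents, dev_sents, lexicon,
            reg_values=[0.1, 1.0], bias_values=[1.0], max_iter=40,
        )
        assert len(report.results) == 2
        best_f = max(r.f_score for r in report.results.values())
        assert report.selected_result().f_score == best_f

    def test_singleton_grid_selected(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        report = grid_search(
            train_sents[:20], dev_sents[:10], lexicon,
            reg_values=[0.5], bias_values=[2.0], max_iter=30,
        )
        assert report.selected == (0.5, 2.0)

    def test_empty_grid_rejected(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        with pytest.raises(ValueError):
            grid_search(train_sents, dev_sents, lexicon, reg_values=[], bias_values=[1.0])

    def test_tie_break_prefers_smaller_config(self):
        from cytolex.evaluation import EvalResult

        tied = EvalResult(10, 10, 9, 9)
        report = GridSearchReport(
            results={(0.1, 1.0): tied, (1.0, 1.0): tied, (0.1, 0.5): tied},
            selected=(0.1, 0.5),
        )
        best = max(report.results, key=lambda c: (report.results[c].f_score, -c[0], -c[1]))
        assert best == (0.1, 0.5)


class TestFinalize:
    def test_finalize_trains_on_train_plus_dev(self, tiny_setup):
        lexicon, train_sents, dev_sents = tiny_setup
        model = finalize(train_sents, dev_sents, (0.1, 1.0), lexicon, max_iter=40)
        assert "train_fingerprint" in model.metadata
        assert "dev_fingerprint" in model.metadata
        assert model.metadata["train_fingerprint"] != model.metadata["dev_fingerprint"]

    def test_empty_corpus_propagates_error(self):
        with pytest.raises(CRFTrainingError):
            train([], None)


class TestPersistence:
    def test_save_load_identical_predictions(self, tiny_setup, tmp_path):
        lexicon, train_sents, dev_sents = tiny_setup
        model = train(train_sents[:30], lexicon, max_iter=40)
        model.save(tmp_path / "model")
        loaded = TaggerModel.load(tmp_path / "model")
        for sent in dev_sents[:10]:
            assert predict(loaded, sent, lexicon) == predict(model, sent, lexicon)

    def test_template_mismatch_detected(self, tiny_setup, tmp_path):
        lexicon, train_sents, _ = tiny_setup
        model = train(train_sents[:20], lexicon, max_iter=20)
        model.save(tmp_path / "model")
        manifest = (tmp_path / "model" / "manifest.txt").read_text()
        (tmp_path / "model" / "manifest.txt").write_text(
            manifest.replace("window\t2", "window\t3")
        )
        with pytest.raises(ValueError, match="template"):
            TaggerModel.load(tmp_path / "model")
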