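"""Corpus formats: tokenization, brat standoff, IOB2, BIO bridging."""

from io import StringIO

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytolex.corpus import (
    BratValidationError,
    Document,
    Mention,
    SentenceBoundaryError,
    decode_mentions,
    encode_bio,
    read_brat,
    read_iob2,
    read_mentions_tsv,
    repair_bio,
    sentence_spans,
    tokenize,
    write_brat,
    write_mentions_tsv,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text, surfaces, offsets",
        [
            ("GOS-3 cells", ["GOS", "-", "3", "cells"], [(0, 3), (3, 4), (4, 5), (6, 11)]),
            ("", [], []),
            ("K562.", ["K562", "."], [(0, 4), (4, 5)]),
        ],
    )
    def test_examples(self, text, surfaces, offsets):
        toks = tokenize(text)
        assert [t.surface for t in toks] == surfaces
        assert [(t.start, t.end) for t in toks] == offsets

    @given(st.text(max_size=60))
    def test_partition_properties(self, text):
        toks = tokenize(text)
        # offsets exact, ordered, non-overlapping
        prev_end = 0
        for t in toks:
            assert text[t.start : t.end] == t.surface
            assert t.start >= prev_end
            prev_end = t.end
        # full coverage of non-whitespace characters
        covered = {i for t in toks for i in range(t.start, t.end)}
        expected = {i for i, ch in enumerate(text) if not ch.isspace()}
        assert covered == expected


def test_sentence_spans_cover_text():
    text = "First sentence. Second one?\nThird line without stop"
    spans = sentence_spans(text)
    assert len(spans) == 3
    assert text[slice(*spans[0])] == "First sentence."
    assert text[slice(*spans[2])] == "Third line without stop"


class TestBrat:
    def test_read_example(self):
        doc, mentions = read_brat(
            StringIO("The GOS-3 cells"), StringIO("T1\tCellLine 4 9\tGOS-3\n")
        )
        assert mentions == [Mention("doc", 4, 9, "GOS-3")]
        assert mentions[0].surface == doc.text[4:9]

    def test_surface_mismatch_names_annotation(self):
        with pytest.raises(BratValidationError, match="T1"):
            read_brat(StringIO("The GOS-3 cells"), StringIO("T1\tCellLine 4 9\tWRONG\n"))

    def test_offset_outside_text(self):
        with pytest.raises(BratValidationError, match="T7"):
            read_brat(StringIO("short"), StringIO("T7\tCellLine 2 99\tort\n"))

    def test_empty_ann_and_non_t_lines(self):
        _, mentions = read_brat(
            StringIO("text"), StringIO("#1\tAnnotatorNotes T1\tcomment\n")
        )
        assert mentions == []

    def test_round_trip(self):
        doc = Document("d1", "K562 and GOS-3 cells were used.")
        mentions = [Mention("d1", 0, 4, "K562"), Mention("d1", 9, 14, "GOS-3")]
        t, a = StringIO(), StringIO()
        write_brat(doc, mentions, t, a)
        t.seek(0), a.seek(0)
        doc2, mentions2 = read_brat(t, a, doc_id="d1")
        assert doc2.text == doc.text
        assert mentions2 == mentions
        assert len(a.getvalue().splitlines()) == 2  # offset order, one line each

    def test_duplicate_spans_written_once(self):
        doc = Document("d1", "K562 cells")
        t, a = StringIO(), StringIO()
        write_brat(doc, [Mention("d1", 0, 4, "K562"), Mention("d1", 0, 4, "K562")], t, a)
        assert len(a.getvalue().splitlines()) == 1


class TestIob2:
    def test_keep_label_filtering(self):
        stream = StringIO("MCF-7\tB-cell_line\nIL-2\tB-protein\ncells\tO\n")
        (sent,) = read_iob2(stream, keep_label="cell_line")
        assert [t.bio_label for t in sent] == ["B", "O", "O"]

    def test_orphan_i_repaired_to_b(self):
        (sent,) = read_iob2(StringIO("X\tI-cell_line\nY\tI-cell_line\n"))
        assert [t.bio_label for t in sent] == ["B", "I"]

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_iob2(StringIO("ok\tO\nno-tab-here\n"))

    def test_blank_lines_delimit_sentences(self):
        sents = read_iob2(StringIO("a\tO\n\nb\tO\nc\tO\n\n"))
        assert [len(s) for s in sents] == [1, 2]


class TestBioBridge:
    def test_encode_decode_example(self):
        text = "The GOS-3 cells"
        toks = tokenize(text)
        mention = Mention("doc", 4, 9, "GOS-3")
        labels = encode_bio(toks, [mention])
        assert labels == ["O", "B", "I", "I", "O"]
        assert decode_mentions(toks, labels, text=text) == [mention]

    def test_all_o_decodes_to_nothing(self):
        toks = tokenize("nothing here")
        assert decode_mentions(toks, ["O", "O"]) == []

    def test_overlapping_gold_keeps_longer(self):
        text = "AB CD EF"
        toks = tokenize(text)
        long = Mention("doc", 0, 5, "AB CD")
        short = Mention("doc", 3, 5, "CD")
        assert encode_bio(toks, [short, long]) == ["B", "I", "O"]

    def test_mention_outside_sentence_rejected(self):
        toks = tokenize("only tokens")
        with pytest.raises(SentenceBoundaryError):
            encode_bio(toks, [Mention("doc", 50, 55, "xxxxx")])

    def test_repair_bio(self):
        assert repair_bio(["I", "I", "O", "I", "B"]) == ["B", "I", "O", "B", "B"]

    @given(st.data())
    def test_encode_decode_inverse_on_generated_sentences(self, data):
        n = data.draw(st.integers(2, 8))
        words = [f"w{i}" for i in range(n)]
        text = " ".join(words)
        toks = tokenize(text)
        # choose non-overlapping token-aligned spans
        starts = sorted(data.draw(st.sets(st.integers(0, n - 1), max_size=3)))
        mentions, used = [], -1
        for s in starts:
            if s <= used:
                continue
            e = min(n - 1, s + data.draw(st.integers(0, 1)))
            mentions.append(
                Mention("doc", toks[s].start, toks[e].end, text[toks[s].start : toks[e].end])
            )
            used = e
        labels = encode_bio(toks, mentions)
        assert decode_mentions(toks, labels, text=text) == mentions


def test_mentions_tsv_round_trip():
    mentions = [
        Mention("d1", 0, 4, "K562", accessions=frozenset({"CVCL_0004"}), match_level="exact"),
        Mention("d1", 10, 15, "other", match_level="none"),
    ]
    buf = StringIO()
    write_mentions_tsv(mentions, buf)
    buf.seek(0)
    assert read_mentions_tsv(buf) == mentions
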