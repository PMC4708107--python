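"""Annotated-corpus I/O: brat standoff, IOB2 token-per-line, BIO bridging.

Offsets are 0-based half-open character offsets into the document text
(the brat convention). Tokenization is deterministic: maximal runs of
letters/digits form one token; every other non-whitespace character is a
single-character token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass(frozen=True, order=True)
class Mention:
    """A labeled character span in a document.

    ``surface`` must equal ``text[start:end]`` of the owning document.
    ``accessions`` and ``match_level`` are filled by normalization
    (match_level in {"exact", "approximate", "none"}) or by the dictionary
    tagger.
    """

    doc_id: str
    start: int
    end: int
    surface: str = field(compare=False)
    label: str = field(default="CellLine", compare=False)
    accessions: frozenset[str] | None = field(default=None, compare=False)
    match_level: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlaps(self, other: "Mention") -> bool:
        return (
            self.doc_id == other.doc_id
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass
class LabeledToken:
    """A token with character offsets, a BIO label and sparse features."""

    surface: str
    start: int
    end: int
    bio_label: str = "O"
    features: list[str] = field(default_factory=list)


def tokenize(text: str) -> list[LabeledToken]:
    """Split text into offset-exact tokens.

    Maximal alphanumeric runs are single tokens; any other non-whitespace
    character is its own token. The concatenation of token surfaces with the
    original inter-token gaps reconstructs the text.
    """
    tokens: list[LabeledToken] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch.isalnum():
            j = i + 1
            while j < n and text[j].isalnum():
                j += 1
        else:
            j = i + 1
        tokens.append(LabeledToken(surface=text[i:j], start=i, end=j))
        i = j
    return tokens


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Split text into sentence character spans.

    Sentences end at a newline or at a period/question/exclamation mark
    followed by whitespace. Returns half-open spans covering all
    non-whitespace text.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n" or (ch in ".?!" and (i + 1 == n or text[i + 1].isspace())):
            end = i + 1 if ch != "\n" else i
            if text[start:end].strip():
                spans.append((start, end))
            start = i + 1
        i += 1
    if text[start:].strip():
        spans.append((start, n))
    return spans


def tokenize_sentences(text: str) -> list[list[LabeledToken]]:
    """Tokenize text sentence by sentence, keeping document-level offsets."""
    out = []
    for s, e in sentence_spans(text):
        toks = tokenize(text[s:e])
        for t in toks:
            t.start += s
            t.end += s
        if toks:
            out.append(toks)
    return out


# ---------------------------------------------------------------------------
# brat standoff


class BratValidationError(ValueError):
    """An .ann line is inconsistent with its document text."""


def read_brat(
    text_stream: IO[str], ann_stream: IO[str], doc_id: str = "doc"
) -> tuple[Document, list[Mention]]:
    """Read a brat ``.txt`` + ``.ann`` pair.

    Only text-bound lines (``Tid<TAB>Label start end<TAB>surface``) are
    interpreted; every other annotation kind is ignored. Each mention's
    stated surface is validated against the corresponding text slice.
    """
    text = text_stream.read()
    doc = Document(doc_id=doc_id, text=text)
    mentions: list[Mention] = []
    for lineno, raw in enumerate(ann_stream, 1):
        line = raw.rstrip("\n")
        if not line or not line.startswith("T"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise BratValidationError(f"line {lineno}: malformed T-line {line!r}")
        tid, span_part, surface = parts[0], parts[1], parts[2]
        try:
            label, start_s, end_s = span_part.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BratValidationError(f"{tid}: malformed span field {span_part!r}") from exc
        if not (0 <= start < end <= len(text)):
            raise BratValidationError(f"{tid}: span ({start}, {end}) outside text")
        if text[start:end] != surface:
            raise BratValidationError(
                f"{tid}: surface {surface!r} != text slice {text[start:end]!r}"
            )
        mentions.append(Mention(doc_id=doc_id, start=start, end=end, surface=surface, label=label))
    return doc, mentions


def write_brat(
    document: Document, mentions: Sequence[Mention], text_stream: IO[str], ann_stream: IO[str]
) -> None:
    """Write a document and its mentions as a brat pair (round-trip partner
    of :func:`read_brat`); mentions are emitted in offset order with fresh
    sequential T ids, duplicates of identical spans collapsed to one line."""
    text_stream.write(document.text)
    seen: set[tuple[int, int, str]] = set()
    tid = 0
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        key = (m.start, m.end, m.label)
        if key in seen:
            continue
        seen.add(key)
        tid += 1
        ann_stream.write(f"T{tid}\t{m.label} {m.start} {m.end}\t{document.text[m.start:m.end]}\n")


# ---------------------------------------------------------------------------
# IOB2 token-per-line


def read_iob2(stream: IO[str], keep_label: str = "cell_line") -> list[list[LabeledToken]]:
    """Read CoNLL-style two-column TSV (token<TAB>tag, blank line between
    sentences), keeping only annotations of ``keep_label``.

    Tags ``B-<keep_label>`` / ``I-<keep_label>`` map to ``B`` / ``I``; every
    other tag (other entity types included) maps to ``O``. Sequences are then
    repaired to IOB2 validity: an ``I`` not preceded by ``B``/``I`` becomes
    ``B``. Character offsets are synthesized (tokens separated by one space).
    """
    sentences: list[list[LabeledToken]] = []
    current: list[LabeledToken] = []
    offset = 0
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(_repair_iob2(current))
                current, offset = [], 0
            continue
        if "\t" not in line:
            raise ValueError(f"line {lineno}: expected token<TAB>tag, got {line!r}")
        token, tag = line.split("\t", 1)
        if tag == f"B-{keep_label}":
            bio = "B"
        elif tag == f"I-{keep_label}":
            bio = "I"
        else:
            bio = "O"
        current.append(
            LabeledToken(surface=token, start=offset, end=offset + len(token), bio_label=bio)
        )
        offset += len(token) + 1
    if current:
        sentences.append(_repair_iob2(current))
    return sentences


def _repair_iob2(tokens: list[LabeledToken]) -> list[LabeledToken]:
    prev = "O"
    for t in tokens:
        if t.bio_label == "I" and prev == "O":
            t.bio_label = "B"
        prev = t.bio_label
    return tokens


def repair_bio(labels: Sequence[str]) -> list[str]:
    """Repair a raw BIO label sequence to IOB2 validity (orphan I → B)."""
    out: list[str] = []
    prev = "O"
    for lab in labels:
        if lab == "I" and prev == "O":
            lab = "B"
        out.append(lab)
        prev = lab
    return out


# ---------------------------------------------------------------------------
# BIO encode/decode bridge


class SentenceBoundaryError(ValueError):
    """A gold mention crosses a sentence boundary."""


def encode_bio(
    tokens: Sequence[LabeledToken], mentions: Sequence[Mention]
) -> list[str]:
    """Project character-span mentions onto a token sequence as BIO labels.

    Mentions not aligned with token boundaries are snapped outward to the
    covering tokens (with a warning). Overlapping mentions: the longer one
    wins, the shorter is dropped. Mentions with no overlapping token at all
    raise :class:`SentenceBoundaryError`.
    """
    labels = ["O"] * len(tokens)
    kept: list[Mention] = []
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start)):
        if any(k.overlaps(m) for k in kept):
            logger.warning("dropping mention %r overlapped by a longer one", m.surface)
            continue
        kept.append(m)
    for m in kept:
        idx = [i for i, t in enumerate(tokens) if max(t.start, m.start) < min(t.end, m.end)]
        if not idx:
            raise SentenceBoundaryError(
                f"mention ({m.start}, {m.end}) {m.surface!r} covers no token of this sentence"
            )
        if tokens[idx[0]].start != m.start or tokens[idx[-1]].end != m.end:
            logger.warning(
                "mention (%d, %d) snapped to token span (%d, %d)",
                m.start, m.end, tokens[idx[0]].start, tokens[idx[-1]].end,
            )
        labels[idx[0]] = "B"
        for i in idx[1:]:
            labels[i] = "I"
    return labels


def decode_mentions(
    tokens: Sequence[LabeledToken],
    labels: Sequence[str],
    doc_id: str = "doc",
    text: str | None = None,
    label: str = "CellLine",
) -> list[Mention]:
    """Convert a BIO label sequence back into character-span mentions.

    Each maximal ``B (I)*`` run becomes one mention from the first token's
    start to the last token's end. Inverse of :func:`encode_bio` on aligned,
    non-overlapping input.
    """
    if len(tokens) != len(labels):
        raise ValueError("tokens and labels differ in length")
    labels = repair_bio(labels)
    mentions: list[Mention] = []
    i = 0
    while i < len(labels):
        if labels[i] == "B":
            j = i + 1
            while j < len(labels) and labels[j] == "I":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            surface = text[start:end] if text is not None else " ".join(
                t.surface for t in tokens[i:j]
            )
            mentions.append(
                Mention(doc_id=doc_id, start=start, end=end, surface=surface, label=label)
            )
            i = j
        else:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# mention TSV

MENTION_TSV_HEADER = "doc_id\tstart\tend\tsurface\tlabel\taccessions\tmatch_level"


def write_mentions_tsv(mentions: Iterable[Mention], stream: IO[str]) -> None:
    stream.write(MENTION_TSV_HEADER + "\n")
    for m in sorted(mentions, key=lambda m: (m.doc_id, m.start, m.end)):
        accs = "|".join(sorted(m.accessions)) if m.accessions else ""
        stream.write(
            f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.label}\t{accs}\t{m.match_level or ''}\n"
        )


def read_mentions_tsv(stream: IO[str]) -> list[Mention]:
    header = stream.readline().rstrip("\n")
    if header != MENTION_TSV_HEADER:
        raise ValueError(f"unexpected mention TSV header: {header!r}")
    out: list[Mention] = []
    for raw in stream:
        if not raw.strip():
            continue
        doc_id, start, end, surface, label, accs, level = raw.rstrip("\n").split("\t")
        out.append(
            Mention(
                doc_id=doc_id,
                start=int(start),
                end=int(end),
                surface=surface,
                label=label,
                accessions=frozenset(accs.split("|")) if accs else None,
                match_level=level or None,
            )
        )
    return out
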