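"""Dictionary-based tagging of raw text under exact or approximate matching.

Serves two roles: a standalone baseline tagger (high precision in exact
mode, high recall in approximate mode) and the source of lexicon features
for the CRF tagger (strict, case-sensitive matching only).
"""

from __future__ import annotations

from typing import Sequence

from cytolex.corpus import Document, LabeledToken, Mention, tokenize
from cytolex.dictionary import Lexicon, canonicalize


def _eligible_keys(lexicon: Lexicon, allow_short: bool) -> set[str]:
    """Exact keys admitted to matching.

    Single-character and all-digit keys are excluded by default: such
    symbols overlap heavily with other entity types (units, gene symbols,
    figure labels) and destroy precision.
    """
    keys = set(lexicon.exact_index)
    if not allow_short:
        keys = {k for k in keys if len(k) > 1 and not k.isdigit()}
    return keys


def max_key_tokens(lexicon: Lexicon, margin: int = 2) -> int:
    """Longest lexicon key in tokens, plus a safety margin — the default
    window cap for :func:`tag_dictionary`."""
    longest = max((len(tokenize(k)) for k in lexicon.exact_index), default=1)
    return longest + margin


def tag_dictionary(
    document: Document,
    lexicon: Lexicon,
    mode: str = "exact",
    max_span_tokens: int | None = None,
    allow_short_keys: bool = False,
) -> list[Mention]:
    """Tag every lexicon hit in a document, leftmost-longest, non-overlapping.

    All token windows up to ``max_span_tokens`` tokens are considered. A
    window matches if the exact document substring it covers is an exact
    key (``mode="exact"``) or if its canonical form is a canonical key
    (``mode="approximate"``). Match boundaries always coincide with token
    boundaries, so ``GOS-3`` is never found inside ``HGOS-3X``. Among
    overlapping candidates the leftmost match wins, ties broken by length
    (longest first).
    """
    if mode not in {"exact", "approximate"}:
        raise ValueError(f"unknown matching mode {mode!r}")
    tokens = tokenize(document.text)
    if max_span_tokens is None:
        max_span_tokens = max_key_tokens(lexicon)
    exact_keys = _eligible_keys(lexicon, allow_short_keys)
    canon_keys = {canonicalize(k) for k in exact_keys} - {""}

    candidates: list[tuple[int, int, int, int, frozenset[str]]] = []
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, min(i + 1 + max_span_tokens, n + 1)):
            start, end = tokens[i].start, tokens[j - 1].end
            surface = document.text[start:end]
            accs: set[str] = set()
            if mode == "exact":
                if surface in exact_keys:
                    accs = lexicon.exact_index[surface]
            else:
                # edge tokens must contribute to the canonical form, else a
                # smaller window with the same canonical form exists and the
                # extra punctuation would only bloat the mention boundary;
                # verbatim exact keys are always admitted
                edges_ok = bool(
                    canonicalize(tokens[i].surface) and canonicalize(tokens[j - 1].surface)
                )
                ck = canonicalize(surface)
                if (edges_ok or surface in exact_keys) and ck in canon_keys and ck in lexicon.canonical_index:
                    accs = lexicon.canonical_index[ck]
            if accs:
                candidates.append((i, j, start, end, frozenset(accs)))

    # leftmost-longest selection over token index spans
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[Mention] = []
    occupied_until = -1  # last claimed token index
    for i, j, start, end, accs in candidates:
        if i > occupied_until:
            mentions.append(
                Mention(
                    doc_id=document.doc_id,
                    start=start,
                    end=end,
                    surface=document.text[start:end],
                    label="CellLine",
                    accessions=accs,
                    match_level=mode if mode == "exact" else "approximate",
                )
            )
            occupied_until = j - 1
    return mentions


def dictionary_features(
    tokens: Sequence[LabeledToken],
    lexicon: Lexicon,
    text: str | None = None,
) -> list[str | None]:
    """Per-token lexicon flags from strict (exact, case-sensitive) matching.

    Tokens inside an exact dictionary match get ``"DICT-B"`` (first token)
    or ``"DICT-I"`` (continuation); all others ``None``. When ``text`` is
    omitted it is reconstructed from token offsets and surfaces.
    """
    if not tokens:
        return []
    if text is None:
        end = max(t.end for t in tokens)
        buf = [" "] * end
        for t in tokens:
            buf[t.start : t.end] = t.surface
        text = "".join(buf)
    doc = Document(doc_id="_feat", text=text)
    mentions = tag_dictionary(doc, lexicon, mode="exact")
    flags: list[str | None] = [None] * len(tokens)
    for m in mentions:
        inside = [
            i for i, t in enumerate(tokens) if max(t.start, m.start) < min(t.end, m.end)
        ]
        for rank, i in enumerate(inside):
            flags[i] = "DICT-B" if rank == 0 else "DICT-I"
    return flags
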