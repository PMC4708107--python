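# Methods

## Task and scope

The package targets *specific, established* cell line names — surface
strings that can be grounded to a cell line database accession
(`CVCL_…`). Generic category phrases ("T cell line", "cancer cell line")
are by definition not groundable and are treated as negatives throughout,
including in the synthetic gold standard. Only minimal name spans are
annotated (no premodifiers or head nouns such as "cells").

## Lexicon and matching criteria

The lexicon is parsed from Cellosaurus-style flat files (ID/AC/SY/DR/OX
records terminated by `//`). Every primary name, synonym and accession
becomes a key of the **exact index**; cross-reference identifiers are
admitted only when they are claimed by a single record, decided after the
full parse. A fixture-oriented `CC   Mutation data: yes` line sets a
boolean mutation-linkage flag on the record; no mutation lists are
carried. Duplicate AC lines within a block: first wins, with a warning.

Two matching criteria are exposed:

- **exact** — case-sensitive verbatim lookup;
- **approximate** — lookup of the *canonical form*: lowercased with all
  non-alphanumeric characters removed. "Alphanumeric" is decided by
  Unicode category (`str.isalnum`), so Greek letters and other non-ASCII
  symbols that occur in cell line names survive canonicalization.

The canonical index is derived from the exact index, unioning accession
sets over colliding canonical forms, so the exact result is always a
subset of the approximate result for the same string.

## Dictionary tagger

The tagger scans every token window up to a cap (longest lexicon key in
tokens + 2, recomputed per lexicon) and emits leftmost-longest,
non-overlapping matches whose boundaries coincide with token boundaries —
`GOS-3` is never found inside `HGOS-3X`. Tokenization is deterministic:
maximal alphanumeric runs, every other non-whitespace character a
single-character token.

Numerical/degenerate-input choices:

- Single-character and all-digit keys are excluded from matching by
  default (configurable); such symbols overlap massively with units,
  figure labels and gene symbols and would destroy precision.
- In approximate mode a window qualifies only if its first and last
  tokens contribute at least one alphanumeric character to the canonical
  form (verbatim exact keys are always admitted). Without this rule a
  window such as `. BZ-64` canonicalizes to the same form as `BZ-64` and
  the leftmost-longest selector would prefer the bloated boundary; with
  it, approximate-mode mentions are a superset of exact-mode mentions on
  token-separated text.
- Ties among overlapping candidates: leftmost first, then longest.

CRF dictionary features use **strict** matching only (exact,
case-sensitive): tokens inside a match get `DICT-B`/`DICT-I` flags.

## CRF tagger

A first-order linear-chain CRF over `{O, B, I}` with start/stop scores,
trained by penalized maximum conditional likelihood (L2, coefficient
`reg`) with L-BFGS from zero initialization — the objective is convex, so
training is reproducible given the input order. The forward–backward
recursions run vectorized over the whole padded corpus per optimizer
iteration; decoding is exact Viterbi (verified against exhaustive path
enumeration in the tests). Predicted sequences are repaired to IOB2
validity (orphan `I` → `B`).

Per-token features: surface, lowercased surface, prefixes/suffixes of
length 1–4, run-compressed character shape (uppercase→`A`, lowercase→`a`,
digit→`0`, other→`_`; `K562` → `A0`), has-digit / has-hyphen / all-caps /
initial-cap flags, dictionary flags, all projected over a ±2 window with
boundary sentinels. Lemma, POS and chunk features are not bundled (no
linguistic models ship with the package); the feature interface accepts
external per-token annotators so users can supply them.

**Label bias.** The recall/precision trade-off weight on non-O labels is
implemented, by default, as a scaling of non-O emission scores by the
bias during training *and* decoding: under L2 regularization this is
equivalent to relaxing the penalty on non-O emission weights by the
squared bias, letting the model express entity evidence more cheaply and
pushing recall up. A decode-only variant (`bias_mode="decode"`, an
additive `log(bias)` offset on non-O emissions at decoding) is available
when the trade-off must be adjusted without retraining. Defaults:
`reg` grid {0.01, 0.1, 1, 10}, bias grid {0.5, 1, 2, 4}, L2, seed 42.

Hyperparameters are selected by grid search on a development set scored
with the overlap criterion (ties: smaller `reg`, then smaller bias); the
final model is trained on the concatenation train + dev under the
selected configuration. Models serialize to a directory (JSON weights +
plain-text manifest carrying a feature-template hash, hyperparameters,
seed and corpus fingerprints); a template mismatch at load time is an
error, and reloaded models reproduce predictions exactly.

## Normalization

Grounding is stepwise and strict-first: exact lookup of the mention
surface; only if it fails, approximate lookup of the canonical form;
otherwise level `none`. Ambiguous surfaces return the full sorted
accession set — no disambiguation is attempted, downstream consumers
decide. An optional species post-filter (default off) restricts
candidates to records listing a given taxon. Corpus-level summaries
report counts and fractions per match level, the number of ambiguous
groundings and the fraction linked to mutation-flagged records.

## Evaluation

The overlap criterion counts a prediction as correct if it shares ≥ 1
character with a gold annotation of the same document
(`max(starts) < min(ends)`), accommodating span-extent differences
between annotation schemes. Matching is many-to-many: each side is
counted independently, so precision and recall may derive from different
match counts; no deduplication is applied. Percentages are rendered
half-up to 2 decimals. Corpus profile statistics: *annotation diversity*
= unique surfaces per mention; *dictionary coverage* = fraction of
mentions (per occurrence) whose surface matches the lexicon
approximately.

## Synthetic data

The generator emulates the mechanism-relevant structure of an annotated
cell line corpus, not its linguistic richness:

- lexicon records with template names (`LETTERS-DIGITS`, fused
  `LETTERSDIGITS`, CamelCase syllables) and 0–3 synonyms that are
  canonical-preserving variants (hyphen↔space↔fused, case flips), plus
  occasional truly distinct aliases; ~30% of records carry the
  mutation-data flag; generated canonical forms never collide with the
  carrier-sentence vocabulary, so distractor-free corpora contain no
  accidental dictionary hits;
- documents of template carrier sentences in two domains (general cell
  culture, cancer), one gold mention per mention sentence; mention counts
  per document are Poisson with mean 2.0; surface variants appear at rate
  0.3, generic phrases at 0.2, homonym distractors (lexicon symbols in
  gene/disease cue contexts, unlabeled) at 0.1 — chosen so that the four
  systems separate: exact matching loses recall to variants, approximate
  matching loses precision to homonyms, and context suffices to suppress
  distractors;
- 50/17/33% train/dev/test document splits, stratified by domain, with
  **disjoint name pools** per split so a tagger cannot score by
  memorizing training names.

What the generator does *not* emulate — and what passing tests therefore
do not show about real text: real lexical context diversity, nested or
discontinuous mentions, boundary ambiguity against premodifiers,
non-template sentence structure, OCR/tokenization noise, and the true
ambiguity distribution of cell line homonyms. Published benchmark scores
on manually annotated corpora are comparison points, not targets, and are
not reproduced here.

## Benchmark sizes and defaults

The end-to-end benchmark uses 60 lexicon records and 300 documents
(≈ 200 test-split mentions), a 2 × 2 grid (`reg` ∈ {0.1, 1}, bias ∈
{1, 2}) and an 80-iteration L-BFGS cap — sizes at which the full
pipeline (two grid searches, two final fits, four evaluations) completes
in about a minute on a single core while leaving every mechanism
exercised. The library defaults for user-driven training keep the full
4 × 4 grid.

## Known limitations

- The CRF feature template is a reconstruction of common NER practice,
  not a replica of any specific toolkit's template.
- Leftmost-longest dictionary matching cannot recover overlapping or
  nested gold mentions (the BIO encoder likewise keeps only the longer
  of two overlapping gold spans, logging the drop).
- Approximate matching is canonicalization-based only; no edit-distance
  or embedding similarity.
- The sentence splitter is a newline + period-whitespace heuristic;
  mentions crossing its boundaries are rejected at encode time.
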