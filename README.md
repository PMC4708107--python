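# cytolex

Recognition and normalization of **established cell line names** in
biomedical text.

Cell lines (K562, MCF-7, GOS-3, ...) are the workhorses of experimental
cancer biology, and mapping a name mentioned in a paper to its database
record — with its known somatic mutations — is the entry point for
literature-scale analyses such as mining synthetic-lethality evidence.
The obstacle is surface variation and ambiguity: the same line appears as
`GOS-3`, `GOS 3` or `gos3`, while symbols like `AGS` or `HK2` double as
disease or gene names. `cytolex` provides the full pipeline for this
task:

- a **lexicon** built from Cellosaurus-style flat files (names, synonyms,
  accessions, non-ambiguous cross-references), with two matching criteria:
  *exact* (case-sensitive, high precision) and *approximate* (high
  recall — strings match after lowercasing and stripping every
  non-alphanumeric character, so `gos3` matches both `GOS 3` and `Gos-3`);
- a **dictionary tagger** scanning token windows under either criterion
  (leftmost-longest, token-boundary-aligned);
- a **linear-chain CRF tagger** over BIO labels with orthographic
  features (surface, casing, affixes, compressed character shape) and
  strict-matching dictionary flags, with grid-searched L2 regularization
  and a *label bias* parameter trading precision for recall, trained
  finally on train+development data;
- stepwise **normalization** of recognized mentions to accessions
  (exact lookup first, approximate only as fallback);
- **overlap-criterion evaluation** (a prediction counts as correct if it
  shares at least one character with a gold annotation) plus corpus
  profile statistics (annotation diversity, dictionary coverage);
- a **synthetic corpus generator** producing a miniature lexicon and
  brat-format annotated documents with controlled surface variation,
  unlabeled generic phrases ("T cell line") and homonym distractors, so
  the whole pipeline is testable end to end without downloads.

## Worked example

Generate a 20-line lexicon and a 30-document annotated corpus, build the
dictionary, tag the held-out test split with approximate matching, and
score it:

```bash
cytolex --seed 7 simulate --n-records 20 --n-docs 30 --out sim
# 30 documents, 60 gold mentions -> sim
cytolex build-dict --cellosaurus sim/cellosaurus.txt --out dict
# 20 records, 80 exact keys -> dict
cytolex tag --mode approx --dict dict --in sim/test --out pred
# 20 mentions in 8 documents -> pred
cytolex evaluate --gold sim/test --pred pred
# system  precision  recall   f_score  n_pred  n_gold
# pred    95.00      100.00   97.44    20      19
cytolex normalize --dict dict --in pred --out mentions.tsv
# 20 mentions: 17 exact, 3 approximate, 0 unmatched (100.00% normalized)
```

The tagger recovered every gold mention (recall 100.00) and tagged one
spurious homonym (precision 95.00); all tagged surfaces could be grounded
to an accession, 17 verbatim and 3 only after canonicalization.

The end-to-end benchmark (default: 60 lexicon records, 300 documents,
30% surface-variant rate, 20% generic and 10% homonym distractor rates,
with test-split cell line names held out of the training text) trains the
CRF with and without dictionary features and compares all four systems:

```bash
cytolex --seed 42 benchmark
# system       precision  recall   f_score  n_pred  n_gold
# dict-exact   97.89      91.63    94.66    190     203
# dict-approx  98.07      100.00   99.02    207     203
# crf          99.51      100.00   99.75    204     203
# crf+dict     100.00     100.00   100.00   203     203
```

Exact dictionary matching misses surface variants (recall 91.63);
approximate matching recovers them but tags homonym distractors; the CRF
uses context to suppress the distractors, and dictionary features give it
the final edge — the same ordering the method is designed around.

`cytolex train` and `cytolex tag --mode crf` expose the same machinery
for user-supplied brat corpora; `cytolex stats` profiles a gold corpus
against a dictionary.

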