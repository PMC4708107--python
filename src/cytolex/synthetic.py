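"""Synthetic lexicon and corpus generation for controlled benchmarking.

The generator emulates the moving parts that make cell line recognition
hard, without any external downloads:

* a miniature Cellosaurus-style lexicon whose records carry synonyms that
  are surface variants of the primary name (hyphen/space/fused, case
  flips) plus occasional truly distinct aliases;
* documents in which lexicon names appear as gold-labeled mentions, with
  a controlled probability of canonical-form-preserving surface variation;
* *generic* phrases ("T cell line") that are deliberately not labeled,
  because they cannot be grounded to a database record;
* *homonym* distractors — lexicon symbols reused in gene/disease contexts
  and left unlabeled, mimicking symbols shared with other entity types.

Documents are split 50/17/33% into train/development/test sets, stratified
by template domain, and the cell line names used in the three splits are
disjoint, so a tagger cannot score by memorizing training-set names.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from io import StringIO

from cytolex.corpus import Document, Mention
from cytolex.dictionary import (
    CellLineRecord,
    Lexicon,
    build_lexicon,
    canonicalize,
    write_cellosaurus,
)

_CONSONANT_SYL = ["He", "La", "Ko", "Va", "Mu", "Re", "So", "Ti", "Du", "Pa", "Ne", "Gi"]

_CULTURE_TEMPLATES = [
    "We cultured {} cells in supplemented medium.",
    "The {} line was maintained under standard conditions.",
    "{} cells were transfected with the reporter construct.",
    "Lysates of {} cells were analysed by immunoblotting.",
    "Conditioned medium from {} cells was collected daily.",
]
_CANCER_TEMPLATES = [
    "Treatment markedly reduced viability of {} cells.",
    "The {} line was derived from a primary tumour biopsy.",
    "Apoptosis was induced in {} cells after drug exposure.",
    "Xenografts of {} cells were established in nude mice.",
    "Colony formation by {} cells was strongly suppressed.",
]
_GENERIC_PHRASES = [
    "T cell line",
    "human monocytic cell line",
    "cancer cell line",
    "endothelial cell line",
]
_GENERIC_TEMPLATES = [
    "A {} was used as an additional control.",
    "Results were compared with a {} in parallel.",
]
_HOMONYM_TEMPLATES = [
    "Expression of {} was markedly elevated in patients.",
    "The {} gene was silenced by promoter methylation.",
    "Germline mutations in {} were found in patients with the disease.",
]
_FILLER_SENTENCES = [
    "Samples were processed according to the standard protocol.",
    "Statistical significance was assessed with appropriate tests.",
    "All experiments were performed in biological triplicate.",
    "Antibodies were obtained from commercial suppliers.",
]

# canonical forms of every word the carrier templates can emit; generated
# names must avoid these so distractor-free corpora contain no accidental
# dictionary hits
_RESERVED_CANONICALS = {
    canonicalize(w)
    for sent in (
        _CULTURE_TEMPLATES + _CANCER_TEMPLATES + _GENERIC_TEMPLATES
        + _HOMONYM_TEMPLATES + _FILLER_SENTENCES + _GENERIC_PHRASES
    )
    for w in sent.replace("{}", " ").replace(".", " ").split()
}


def _gen_name(rng: random.Random) -> str:
    kind = rng.randrange(3)
    if kind == 0:  # LETTERS-DIGITS, e.g. MCF-7
        letters = "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ") for _ in range(rng.randint(2, 4)))
        digits = "".join(rng.choice("0123456789") for _ in range(rng.randint(1, 3)))
        return f"{letters}-{digits}"
    if kind == 1:  # fused LETTERSDIGITS, e.g. K562
        letters = "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ") for _ in range(rng.randint(1, 3)))
        digits = "".join(rng.choice("0123456789") for _ in range(rng.randint(2, 4)))
        return f"{letters}{digits}"
    # CamelCase words, e.g. HeLa-like
    return "".join(rng.choice(_CONSONANT_SYL) for _ in range(2))


def _surface_variants(name: str) -> list[str]:
    """Canonical-form-preserving rewritings of a name."""
    variants = {
        name.lower(),
        name.upper(),
        name.replace("-", " "),
        name.replace("-", ""),
        name.replace(" ", "-"),
    }
    # insert a hyphen at the first letter→digit boundary of a fused name
    for i in range(1, len(name)):
        if name[i - 1].isalpha() and name[i].isdigit():
            variants.add(name[:i] + "-" + name[i:])
            break
    variants.discard(name)
    return sorted(v for v in variants if canonicalize(v) == canonicalize(name))


def gen_records(
    n_records: int, seed: int, distinct_alias_rate: float = 0.15, mutation_rate: float = 0.3
) -> tuple[list[CellLineRecord], set[str]]:
    """Generate records and the set of aliases flagged as truly distinct
    (canonical form differing from the primary name's)."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = random.Random(seed)
    used_canon = set(_RESERVED_CANONICALS)
    records: list[CellLineRecord] = []
    distinct_aliases: set[str] = set()
    for i in range(n_records):
        while True:
            name = _gen_name(rng)
            if canonicalize(name) not in used_canon:
                break
        used_canon.add(canonicalize(name))
        synonyms = set(rng.sample(_surface_variants(name), k=min(rng.randint(0, 3), len(_surface_variants(name)))))
        if rng.random() < distinct_alias_rate:
            while True:
                alias = _gen_name(rng)
                if canonicalize(alias) not in used_canon:
                    break
            used_canon.add(canonicalize(alias))
            synonyms.add(alias)
            distinct_aliases.add(alias)
        xrefs = {}
        if rng.random() < 0.4:
            xrefs["CLDB"] = f"cl{rng.randint(1000, 9999)}"
        records.append(
            CellLineRecord(
                accession=f"CVCL_T{i:03d}",
                primary_name=name,
                synonyms=synonyms,
                xrefs=xrefs,
                species={"Homo sapiens"},
                has_mutation_data=rng.random() < mutation_rate,
            )
        )
    return records, distinct_aliases


def gen_lexicon(n_records: int, seed: int) -> str:
    """Generate a miniature Cellosaurus-format flat file (deterministic
    under ``seed``)."""
    records, _ = gen_records(n_records, seed)
    buf = StringIO()
    write_cellosaurus(records, buf)
    return buf.getvalue()


@dataclass
class SyntheticCorpus:
    """A generated brat-style corpus with gold mentions and split manifests."""

    documents: dict[str, Document]
    mentions: list[Mention]
    splits: dict[str, list[str]] = field(default_factory=dict)

    def mentions_of(self, doc_id: str) -> list[Mention]:
        return [m for m in self.mentions if m.doc_id == doc_id]

    def split_mentions(self, split: str) -> list[Mention]:
        ids = set(self.splits[split])
        return [m for m in self.mentions if m.doc_id in ids]


def _partition(items: list, fractions: tuple[float, ...]) -> list[list]:
    out, start = [], 0
    n = len(items)
    for i, frac in enumerate(fractions):
        end = n if i == len(fractions) - 1 else start + round(frac * n)
        out.append(items[start:end])
        start = end
    return out


def gen_corpus(
    lexicon: Lexicon | list[CellLineRecord],
    n_docs: int,
    seed: int,
    variant_rate: float = 0.3,
    generic_rate: float = 0.2,
    homonym_rate: float = 0.1,
    mentions_per_doc: float = 2.0,
) -> SyntheticCorpus:
    """Generate annotated documents with controlled distractors.

    Each document draws its mention count from a Poisson distribution with
    mean ``mentions_per_doc``; each mention's surface is, with probability
    ``variant_rate``, a canonical-preserving variant of the record's
    primary name instead of the verbatim name. A generic (unlabeled)
    phrase sentence is added with probability ``generic_rate`` and a
    homonym distractor sentence (a lexicon symbol in a gene/disease
    context, unlabeled) with probability ``homonym_rate``. Splits are
    50/17/33% train/dev/test, stratified over the two template domains,
    with disjoint name pools per split.
    """
    for name, rate in (
        ("variant_rate", variant_rate),
        ("generic_rate", generic_rate),
        ("homonym_rate", homonym_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    records = (
        sorted(lexicon.records.values(), key=lambda r: r.accession)
        if isinstance(lexicon, Lexicon)
        else list(lexicon)
    )
    if not records:
        raise ValueError("cannot generate a corpus from an empty lexicon")
    rng = random.Random(seed)

    shuffled = records[:]
    rng.shuffle(shuffled)
    pools = dict(zip(("train", "dev", "test"), _partition(shuffled, (0.50, 0.17, 0.33))))
    for split, pool in pools.items():
        if not pool:  # tiny lexicons: fall back to sharing the full pool
            pools[split] = records[:]

    # stratified 50/17/33 doc split within each domain
    domains = ["random" if i % 2 == 0 else "cancer" for i in range(n_docs)]
    splits: dict[str, list[str]] = {"train": [], "dev": [], "test": []}
    for domain in ("random", "cancer"):
        ids = [f"d{i:04d}" for i in range(n_docs) if domains[i] == domain]
        for split, part in zip(("train", "dev", "test"), _partition(ids, (0.50, 0.17, 0.33))):
            splits[split].extend(part)
    doc_split = {d: s for s, ds in splits.items() for d in ds}

    documents: dict[str, Document] = {}
    mentions: list[Mention] = []
    for i in range(n_docs):
        doc_id = f"d{i:04d}"
        domain = domains[i]
        pool = pools[doc_split[doc_id]]
        templates = _CULTURE_TEMPLATES if domain == "random" else _CANCER_TEMPLATES

        sentences: list[tuple[str, str | None]] = []  # (template, surface or None)
        n_mentions = _poisson(rng, mentions_per_doc)
        for _ in range(n_mentions):
            rec = rng.choice(pool)
            surface = rec.primary_name
            if rng.random() < variant_rate:
                variants = _surface_variants(rec.primary_name)
                if variants:
                    surface = rng.choice(variants)
            sentences.append((rng.choice(templates), surface))
        if rng.random() < generic_rate:
            sentences.append((rng.choice(_GENERIC_TEMPLATES), rng.choice(_GENERIC_PHRASES)))
        if rng.random() < homonym_rate:
            sentences.append((rng.choice(_HOMONYM_TEMPLATES), rng.choice(records).primary_name))
        for _ in range(rng.randint(1, 2)):
            sentences.append((rng.choice(_FILLER_SENTENCES), None))
        rng.shuffle(sentences)

        parts: list[str] = []
        offset = 0
        for template, fill in sentences:
            if fill is None:
                sent = template
                slot = -1
            else:
                slot = template.index("{}")
                sent = template.replace("{}", fill)
            if fill is not None and template in _CULTURE_TEMPLATES + _CANCER_TEMPLATES:
                start = offset + slot
                mentions.append(
                    Mention(
                        doc_id=doc_id,
                        start=start,
                        end=start + len(fill),
                        surface=fill,
                        label="CellLine",
                    )
                )
            parts.append(sent)
            offset += len(sent) + 1  # single-space joiner
        documents[doc_id] = Document(doc_id=doc_id, text=" ".join(parts))

    for m in mentions:  # offsets must be exact by construction
        assert documents[m.doc_id].text[m.start : m.end] == m.surface
    return SyntheticCorpus(documents=documents, mentions=mentions, splits=splits)


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth sampling; lam is small here."""
    import math

    l_exp = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= l_exp:
            return k
        k += 1


# ---------------------------------------------------------------------------
# end-to-end benchmark


@dataclass
class BenchmarkResult:
    """Evaluation of four systems on the synthetic test split."""

    results: dict[str, "object"]  # name -> EvalResult
    grid_plain: "object"
    grid_dict: "object"
    normalization: "object"  # NormalizationSummary of test gold mentions
    corpus: SyntheticCorpus
    lexicon: Lexicon

    def report(self) -> str:
        from cytolex.evaluation import report as render

        return render(self.results)


def corpus_to_sentences(corpus: SyntheticCorpus, split: str):
    """Tokenized, BIO-labeled sentences (doc-level offsets) for one split."""
    from cytolex.corpus import encode_bio, tokenize_sentences

    out = []
    for doc_id in corpus.splits[split]:
        doc = corpus.documents[doc_id]
        doc_mentions = corpus.mentions_of(doc_id)
        for sent in tokenize_sentences(doc.text):
            s, e = sent[0].start, sent[-1].end
            in_sent = [m for m in doc_mentions if m.start >= s and m.end <= e]
            labels = encode_bio(sent, in_sent)
            for t, lab in zip(sent, labels):
                t.bio_label = lab
            out.append((doc_id, doc.text, sent))
    return out


def benchmark(
    seed: int = 42,
    n_records: int = 60,
    n_docs: int = 300,
    variant_rate: float = 0.3,
    generic_rate: float = 0.2,
    homonym_rate: float = 0.1,
    mentions_per_doc: float = 2.0,
    reg_values=(0.1, 1.0),
    bias_values=(1.0, 2.0),
    max_iter: int = 80,
) -> BenchmarkResult:
    """Generate lexicon + corpus, train the CRF (with and without lexicon
    features) via grid search + final train/dev fit, and evaluate four
    systems on the test split: dictionary-exact, dictionary-approximate,
    CRF, CRF+dict."""
    from cytolex import tagger as tg
    from cytolex.evaluation import evaluate_overlap
    from cytolex.matcher import tag_dictionary
    from cytolex.normalize import normalize_corpus

    records, _ = gen_records(n_records, seed)
    lexicon = build_lexicon(records)
    corpus = gen_corpus(
        lexicon,
        n_docs,
        seed + 1,
        variant_rate=variant_rate,
        generic_rate=generic_rate,
        homonym_rate=homonym_rate,
        mentions_per_doc=mentions_per_doc,
    )

    gold_test = corpus.split_mentions("test")
    test_docs = [corpus.documents[d] for d in corpus.splits["test"]]

    results = {}
    for mode, name in (("exact", "dict-exact"), ("approximate", "dict-approx")):
        pred = [m for doc in test_docs for m in tag_dictionary(doc, lexicon, mode)]
        results[name] = evaluate_overlap(pred, gold_test)

    train_sents = [s for _, _, s in corpus_to_sentences(corpus, "train")]
    dev_sents = [s for _, _, s in corpus_to_sentences(corpus, "dev")]
    test_sents = corpus_to_sentences(corpus, "test")

    grids = {}
    for use_dict, name in ((False, "crf"), (True, "crf+dict")):
        lex = lexicon if use_dict else None
        grid = tg.grid_search(
            train_sents, dev_sents, lex,
            reg_values=reg_values, bias_values=bias_values,
            max_iter=max_iter, seed=seed,
        )
        model = tg.finalize(
            train_sents, dev_sents, grid.selected, lex, max_iter=max_iter, seed=seed
        )
        pred = []
        for doc_id, text, sent in test_sents:
            labels = tg.predict(model, sent, lex)
            from cytolex.corpus import decode_mentions

            pred.extend(decode_mentions(sent, labels, doc_id=doc_id, text=text))
        results[name] = evaluate_overlap(pred, gold_test)
        grids[name] = grid

    _, norm_summary = normalize_corpus(gold_test, lexicon)
    return BenchmarkResult(
        results=results,
        grid_plain=grids["crf"],
        grid_dict=grids["crf+dict"],
        normalization=norm_summary,
        corpus=corpus,
        lexicon=lexicon,
    )
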