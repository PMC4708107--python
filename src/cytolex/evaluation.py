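"""Overlap-criterion scoring and corpus profile statistics.

The overlap criterion counts a predicted mention as correct if it shares at
least one character with a gold annotation in the same document. This
accommodates minor span-extent differences between annotation schemes
(e.g. whether head nouns are included). Matching is many-to-many: each
predicted mention is matched if it overlaps any gold mention and each gold
mention is matched if any prediction overlaps it, so precision and recall
can derive from different match counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Mapping, Sequence

from cytolex.corpus import Mention
from cytolex.dictionary import Lexicon, lookup


@dataclass(frozen=True)
class EvalResult:
    """Overlap-criterion counts with derived precision/recall/F-score."""

    n_pred: int
    n_gold: int
    n_pred_matched: int
    n_gold_matched: int

    @property
    def precision(self) -> float:
        return self.n_pred_matched / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.n_gold_matched / self.n_gold if self.n_gold else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def evaluate_overlap(pred: Iterable[Mention], gold: Iterable[Mention]) -> EvalResult:
    """Score predictions against gold under the any-overlap criterion.

    Two spans overlap iff they share a document and
    ``max(starts) < min(ends)``. Document grouping prevents cross-document
    matches.
    """
    pred = list(pred)
    gold = list(gold)
    gold_by_doc: dict[str, list[Mention]] = defaultdict(list)
    for g in gold:
        gold_by_doc[g.doc_id].append(g)
    pred_by_doc: dict[str, list[Mention]] = defaultdict(list)
    for p in pred:
        pred_by_doc[p.doc_id].append(p)

    n_pred_matched = sum(
        1 for p in pred if any(p.overlaps(g) for g in gold_by_doc.get(p.doc_id, ()))
    )
    n_gold_matched = sum(
        1 for g in gold if any(g.overlaps(p) for p in pred_by_doc.get(g.doc_id, ()))
    )
    return EvalResult(
        n_pred=len(pred),
        n_gold=len(gold),
        n_pred_matched=n_pred_matched,
        n_gold_matched=n_gold_matched,
    )


@dataclass(frozen=True)
class CorpusStats:
    """Annotation diversity and dictionary coverage of a gold corpus.

    ``diversity_pct`` is unique strings per mention (how varied the
    annotations are); ``normalized_pct`` is the fraction of mentions whose
    string matches the lexicon under the approximate criterion (how
    specific / groundable they are).
    """

    n_mentions: int
    n_unique_strings: int
    n_dict_matched: int

    @property
    def diversity_pct(self) -> float:
        return 100.0 * self.n_unique_strings / self.n_mentions

    @property
    def normalized_pct(self) -> float:
        return 100.0 * self.n_dict_matched / self.n_mentions


def corpus_stats(gold: Sequence[Mention], lexicon: Lexicon) -> CorpusStats:
    """Profile a gold corpus: mention count, unique verbatim surfaces, and
    mentions matching the lexicon approximately (counted per occurrence)."""
    if not gold:
        raise ValueError("corpus_stats undefined for an empty corpus")
    surfaces = [m.surface for m in gold]
    n_matched = sum(1 for s in surfaces if lookup(lexicon, s, "approximate"))
    return CorpusStats(
        n_mentions=len(surfaces),
        n_unique_strings=len(set(surfaces)),
        n_dict_matched=n_matched,
    )


def pct(x: float, digits: int = 2) -> str:
    """Format a [0, 1] fraction as a percentage, half-up to ``digits``."""
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(100 * x)).quantize(q, rounding=ROUND_HALF_UP))


def report(
    results: Mapping[str, EvalResult | CorpusStats], stream: IO[str] | None = None
) -> str:
    """Render named results as a deterministic TSV table.

    EvalResult rows show P/R/F as percentages to 2 decimals (half-up);
    CorpusStats rows show diversity and normalized percentages.
    """
    lines = []
    eval_rows = {k: v for k, v in results.items() if isinstance(v, EvalResult)}
    stat_rows = {k: v for k, v in results.items() if isinstance(v, CorpusStats)}
    if eval_rows:
        lines.append("system\tprecision\trecall\tf_score\tn_pred\tn_gold")
        for name, r in eval_rows.items():
            lines.append(
                f"{name}\t{pct(r.precision)}\t{pct(r.recall)}\t{pct(r.f_score)}"
                f"\t{r.n_pred}\t{r.n_gold}"
            )
    if stat_rows:
        lines.append("corpus\tn_mentions\tn_unique\tdiversity_pct\tnormalized_pct")
        for name, s in stat_rows.items():
            lines.append(
                f"{name}\t{s.n_mentions}\t{s.n_unique_strings}"
                f"\t{pct(s.diversity_pct / 100)}\t{pct(s.normalized_pct / 100)}"
            )
    if not eval_rows and not stat_rows:
        lines.append("system\tprecision\trecall\tf_score\tn_pred\tn_gold")
    out = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(out)
    return out
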