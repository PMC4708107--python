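"""Stepwise normalization of recognized mentions to lexicon accessions.

Grounding proceeds in two steps, strict first: a mention surface is first
looked up verbatim (exact criterion); only if that fails is the canonical
form looked up (approximate criterion: case-lowered, punctuation-stripped).
A mention matching neither is reported unnormalized. Ambiguous surfaces
return the full accession set — no disambiguation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from cytolex.corpus import Mention
from cytolex.dictionary import Lexicon, lookup


def normalize_mention(
    surface: str, lexicon: Lexicon, species: str | None = None
) -> tuple[tuple[str, ...], str]:
    """Ground one surface string: ``(sorted accessions, match_level)``.

    ``match_level`` is ``"exact"`` when the surface is a verbatim lexicon
    key, ``"approximate"`` when only its canonical form matches, ``"none"``
    otherwise. Exact always takes precedence. The optional ``species``
    post-filter keeps only accessions whose record lists that taxon (off by
    default).
    """
    accs = lookup(lexicon, surface, "exact")
    level = "exact"
    if not accs:
        accs = lookup(lexicon, surface, "approximate")
        level = "approximate"
    if not accs:
        return (), "none"
    if species is not None:
        accs = {a for a in accs if species in lexicon.records[a].species} or accs
    return tuple(sorted(accs)), level


@dataclass(frozen=True)
class NormalizationSummary:
    n_mentions: int
    n_exact: int
    n_approximate: int
    n_none: int
    n_ambiguous: int
    n_mutation_linked: int

    @property
    def normalized_fraction(self) -> float:
        if not self.n_mentions:
            return 0.0
        return (self.n_exact + self.n_approximate) / self.n_mentions

    @property
    def mutation_linked_fraction(self) -> float:
        if not self.n_mentions:
            return 0.0
        return self.n_mutation_linked / self.n_mentions


def normalize_corpus(
    mentions: Iterable[Mention], lexicon: Lexicon, species: str | None = None
) -> tuple[list[Mention], NormalizationSummary]:
    """Normalize every mention and summarize match levels.

    Returns the mentions annotated with accessions and match level, plus
    counts and fractions per level, the number of ambiguous groundings
    (more than one candidate accession) and the number linked to at least
    one record carrying mutation data.
    """
    out: list[Mention] = []
    n_exact = n_approx = n_none = n_amb = n_mut = 0
    for m in mentions:
        accs, level = normalize_mention(m.surface, lexicon, species=species)
        if level == "exact":
            n_exact += 1
        elif level == "approximate":
            n_approx += 1
        else:
            n_none += 1
        if len(accs) > 1:
            n_amb += 1
        if any(lexicon.records[a].has_mutation_data for a in accs):
            n_mut += 1
        out.append(replace(m, accessions=frozenset(accs) if accs else None, match_level=level))
    summary = NormalizationSummary(
        n_mentions=len(out),
        n_exact=n_exact,
        n_approximate=n_approx,
        n_none=n_none,
        n_ambiguous=n_amb,
        n_mutation_linked=n_mut,
    )
    return out, summary
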