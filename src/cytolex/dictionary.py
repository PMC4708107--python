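"""Cell line lexicon: Cellosaurus flat-file parsing and lookup indices.

A Cellosaurus-style flat file is a sequence of records, each a block of
two-letter-coded lines terminated by ``//``::

    ID   GOS-3
    AC   CVCL_2050
    SY   GOS3
    DR   CLDB; cl5278
    OX   NCBI_TaxID=9606; ! Homo sapiens
    //

The lexicon built from such records supports two matching criteria:

* **exact** — case-sensitive lookup of the verbatim surface string;
* **approximate** — lookup of the *canonical form*: the string lowercased
  with every non-alphanumeric character removed, so that ``gos3`` matches
  both ``GOS 3`` and ``Gos-3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)


class EmptyLexiconError(ValueError):
    """Raised when a lexicon source yields no parsable records."""


@dataclass
class CellLineRecord:
    """One cell line entry: accession, names, cross-references, species.

    Parameters
    ----------
    accession:
        Database accession, e.g. ``CVCL_2050``.
    primary_name:
        The record's main name, e.g. ``GOS-3``.
    synonyms:
        Alternative surface forms, e.g. ``{"GOS3"}``; never contains
        ``primary_name``.
    xrefs:
        Mapping from external source name to identifier, e.g.
        ``{"CLDB": "cl5278"}``.
    species:
        Taxon labels from OX lines.
    has_mutation_data:
        Whether the line is linked to known somatic mutation data
        (an input flag; no mutation lists are carried).
    """

    accession: str
    primary_name: str
    synonyms: set[str] = field(default_factory=set)
    xrefs: dict[str, str] = field(default_factory=dict)
    species: set[str] = field(default_factory=set)
    has_mutation_data: bool = False

    def __post_init__(self) -> None:
        self.accession = self.accession.strip()
        self.primary_name = self.primary_name.strip()
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.primary_name:
            raise ValueError("primary_name must be non-empty")
        self.synonyms = {s.strip() for s in self.synonyms if s.strip()}
        self.synonyms.discard(self.primary_name)

    def surface_forms(self) -> set[str]:
        """All strings under which this record can be found exactly."""
        return {self.primary_name, self.accession} | self.synonyms


def canonicalize(s: str) -> str:
    """Map a string to its canonical form for approximate matching.

    Lowercases and drops every character that is not a (Unicode) letter or
    digit, so hyphenation, spacing and case differences are ignored:
    ``canonicalize("GOS 3") == canonicalize("Gos-3") == "gos3"``.
    Idempotent; the empty string maps to itself.
    """
    return "".join(ch for ch in s.lower() if ch.isalnum())


def _iter_blocks(lines: Iterable[str]) -> Iterator[list[tuple[str, str]]]:
    """Yield lists of (code, value) pairs, one list per ``//`` block."""
    block: list[tuple[str, str]] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if line.strip() == "//":
            if block:
                yield block
            block = []
            continue
        if len(line) < 2 or line[:2].strip() == "":
            continue
        code = line[:2]
        value = line[2:].strip()
        block.append((code, value))
    # trailing block without terminator is ignored (malformed tail)


def parse_cellosaurus(stream: IO[str] | Iterable[str]) -> list[CellLineRecord]:
    """Parse a Cellosaurus-format flat file into cell line records.

    Recognized line codes are ``ID`` (primary name), ``AC`` (accession),
    ``SY`` (``"; "``-separated synonyms), ``DR`` (``Source; Identifier``
    cross-references) and ``OX`` (species); all other codes are skipped.
    Blocks lacking either an ID or an AC line are skipped and counted in a
    warning. An extra ``CC`` convention is honoured for fixtures:
    ``CC   Mutation data: yes`` sets :attr:`CellLineRecord.has_mutation_data`.

    Raises
    ------
    EmptyLexiconError
        If no block yields a valid record.
    """
    records: list[CellLineRecord] = []
    n_skipped = 0
    for block in _iter_blocks(stream):
        name: str | None = None
        accession: str | None = None
        synonyms: set[str] = set()
        xrefs: dict[str, str] = {}
        species: set[str] = set()
        has_mut = False
        for code, value in block:
            if code == "ID" and name is None:
                name = value
            elif code == "AC":
                if accession is None:
                    accession = value
                else:
                    logger.warning("duplicate AC line %r ignored (first wins)", value)
            elif code == "SY":
                synonyms.update(v.strip() for v in value.split("; ") if v.strip())
            elif code == "DR":
                parts = value.split(";", 1)
                if len(parts) == 2 and parts[0].strip() and parts[1].strip():
                    xrefs[parts[0].strip()] = parts[1].strip()
            elif code == "OX":
                # e.g. "NCBI_TaxID=9606; ! Homo sapiens"
                label = value.split("!", 1)[-1].strip() if "!" in value else value.strip()
                if label:
                    species.add(label)
            elif code == "CC" and value.lower().startswith("mutation data:"):
                has_mut = value.split(":", 1)[1].strip().lower() in {"yes", "true", "1"}
        if name is None or accession is None:
            n_skipped += 1
            continue
        records.append(
            CellLineRecord(
                accession=accession,
                primary_name=name,
                synonyms=synonyms,
                xrefs=xrefs,
                species=species,
                has_mutation_data=has_mut,
            )
        )
    if n_skipped:
        logger.warning("skipped %d blocks missing ID or AC", n_skipped)
    if not records:
        raise EmptyLexiconError("no parsable cell line records in input")
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


@dataclass
class Lexicon:
    """Dual-index lexicon over cell line records.

    ``exact_index`` maps verbatim surface strings to accession sets;
    ``canonical_index`` maps canonical forms to accession sets and is a
    superset view of the exact index (every exact key contributes its
    canonical form).
    """

    exact_index: dict[str, set[str]]
    canonical_index: dict[str, set[str]]
    records: dict[str, CellLineRecord]

    def __len__(self) -> int:
        return len(self.records)


def build_lexicon(
    records: Iterable[CellLineRecord],
    min_name_len: int = 1,
) -> Lexicon:
    """Build exact and canonical lookup indices from parsed records.

    Every primary name, synonym and accession becomes an exact key.
    Cross-reference identifiers are admitted only when non-ambiguous, i.e.
    the identifier string is claimed by a single record (checked after the
    full pass). Keys shorter than ``min_name_len`` are dropped; keys whose
    canonical form is empty contribute nothing to the canonical index.
    """
    records = list(records)
    if not records:
        raise EmptyLexiconError("cannot build a lexicon from zero records")

    exact: dict[str, set[str]] = {}
    xref_claims: dict[str, set[str]] = {}
    by_acc: dict[str, CellLineRecord] = {}
    for rec in records:
        by_acc[rec.accession] = rec
        for form in rec.surface_forms():
            if len(form) >= min_name_len:
                exact.setdefault(form, set()).add(rec.accession)
        for ident in rec.xrefs.values():
            xref_claims.setdefault(ident, set()).add(rec.accession)
    for ident, accs in xref_claims.items():
        if len(accs) == 1 and len(ident) >= min_name_len:
            exact.setdefault(ident, set()).update(accs)
        elif len(accs) > 1:
            logger.info("ambiguous xref identifier %r dropped", ident)

    canonical: dict[str, set[str]] = {}
    for key, accs in exact.items():
        ck = canonicalize(key)
        if ck:
            canonical.setdefault(ck, set()).update(accs)
    return Lexicon(exact_index=exact, canonical_index=canonical, records=by_acc)


def lookup(lexicon: Lexicon, s: str, mode: str = "exact") -> set[str]:
    """Look up a surface string, returning the matching accession set.

    ``mode="exact"`` is case-sensitive verbatim lookup; ``mode="approximate"``
    looks up the canonical form, so the exact result is always a subset of
    the approximate one for the same string.
    """
    if mode == "exact":
        return set(lexicon.exact_index.get(s, set()))
    if mode == "approximate":
        return set(lexicon.canonical_index.get(canonicalize(s), set()))
    raise ValueError(f"unknown lookup mode {mode!r}")


def write_lexicon_tsv(lexicon: Lexicon, stream: IO[str]) -> None:
    """Dump a lexicon as TSV: accession, primary name, synonyms, canonicals."""
    stream.write("accession\tprimary_name\tsynonyms\tcanonical_forms\n")
    for acc in sorted(lexicon.records):
        rec = lexicon.records[acc]
        canon = sorted({canonicalize(f) for f in rec.surface_forms()} - {""})
        stream.write(
            f"{acc}\t{rec.primary_name}\t{'|'.join(sorted(rec.synonyms))}\t{'|'.join(canon)}\n"
        )


def write_cellosaurus(records: Iterable[CellLineRecord], stream: IO[str]) -> None:
    """Write records back in the Cellosaurus flat-file dialect read by
    :func:`parse_cellosaurus` (round-trip partner, used by the fixture
    generator)."""
    for rec in records:
        stream.write(f"ID   {rec.primary_name}\n")
        stream.write(f"AC   {rec.accession}\n")
        if rec.synonyms:
            stream.write(f"SY   {'; '.join(sorted(rec.synonyms))}\n")
        for src in sorted(rec.xrefs):
            stream.write(f"DR   {src}; {rec.xrefs[src]}\n")
        for sp in sorted(rec.species):
            stream.write(f"OX   NCBI_TaxID=0000; ! {sp}\n")
        if rec.has_mutation_data:
            stream.write("CC   Mutation data: yes\n")
        stream.write("//\n")
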