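"""Annotated literature corpora in MEDLINE flat-file format.

Articles carry their PubMed identifier, free-text fields, MeSH headings as
indexed (major-topic asterisks and ``/qualifier`` suffixes preserved — it is
the consumers that normalize them away), and author keywords.  Reading goes
through Biopython's MEDLINE parser; writing emits the same tag grammar
(4-character tag, ``- ``, value; continuation lines indented six spaces;
records separated by blank lines) so that read -> write -> read is the
identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
from Bio import Medline

from .errors import IntegrityError, ParseError
from .mesh import normalize_heading, normalize_term

__all__ = ["Article", "Corpus", "read_medline", "write_medline", "sample_articles"]

_NEWLINES = re.compile(r"[\r\n]+")


@dataclass
class Article:
    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_headings: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    journal: str = ""
    pub_date: str = ""

    def heading_keys(self) -> frozenset[str]:
        """Normalized lookup keys of the MeSH headings: asterisk and
        qualifier stripped, whitespace collapsed, case-folded, deduplicated."""
        return frozenset(
            normalize_term(normalize_heading(h))
            for h in self.mesh_headings
            if normalize_heading(h)
        )

    def text_fields(self) -> str:
        return "\n".join([self.title, self.abstract, *self.keywords])


@dataclass
class Corpus:
    articles: list[Article] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, a in enumerate(self.articles):
            if not a.pmid:
                raise IntegrityError(f"article at position {i} has an empty PMID")
            if a.pmid in seen:
                raise IntegrityError(
                    f"duplicate PMID {a.pmid} (positions {seen[a.pmid]} and {i})"
                )
            seen[a.pmid] = i
        self._by_pmid = {a.pmid: a for a in self.articles}

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.articles == other.articles

    @property
    def pmids(self) -> list[str]:
        return [a.pmid for a in self.articles]

    def get(self, pmid: str) -> Article:
        return self._by_pmid[pmid]


def read_medline(source: str | Path | IO[str]) -> Corpus:
    """Parse a MEDLINE flat file into a Corpus.

    Continuation lines are joined with a single space (Biopython's rule);
    MH and OT fields accumulate in order.  A record without a PMID is a
    parse error naming the record index; duplicate PMIDs are an integrity
    error.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_medline(handle)
    articles: list[Article] = []
    for idx, rec in enumerate(Medline.parse(source)):
        pmid = rec.get("PMID", "").strip()
        if not pmid:
            raise ParseError(f"record {idx}: no PMID field")
        articles.append(
            Article(
                pmid=pmid,
                title=rec.get("TI", ""),
                abstract=rec.get("AB", ""),
                mesh_headings=list(rec.get("MH", [])),
                keywords=list(rec.get("OT", [])),
                journal=rec.get("JT", ""),
                pub_date=rec.get("DP", ""),
            )
        )
    return Corpus(articles)


def _emit(sink: IO[str], tag: str, value: str) -> None:
    sink.write(f"{tag:<4}- {_NEWLINES.sub(' ', value)}\n")


def write_medline(corpus: Corpus, sink: IO[str]) -> None:
    """Serialize in a fixed tag order (PMID, TI, AB, JT, DP, MH*, OT*).

    Empty optional fields are omitted; newlines inside values are collapsed
    to spaces (the flat format cannot represent them).
    """
    for i, a in enumerate(corpus):
        if i:
            sink.write("\n")
        _emit(sink, "PMID", a.pmid)
        if a.title:
            _emit(sink, "TI", a.title)
        if a.abstract:
            _emit(sink, "AB", a.abstract)
        if a.journal:
            _emit(sink, "JT", a.journal)
        if a.pub_date:
            _emit(sink, "DP", a.pub_date)
        for mh in a.mesh_headings:
            _emit(sink, "MH", mh)
        for kw in a.keywords:
            _emit(sink, "OT", kw)


def sample_articles(corpus: Corpus, n: int, seed: int) -> Corpus:
    """Uniform sample of ``n`` articles without replacement, seeded.

    The survivors keep their original corpus order, so identical
    ``(corpus, n, seed)`` always yields the identical sub-corpus.
    """
    if n < 0 or n > len(corpus):
        raise ValueError(f"sample size {n} outside [0, {len(corpus)}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(corpus), size=n, replace=False))
    return Corpus([corpus.articles[i] for i in idx], provenance=corpus.provenance)
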