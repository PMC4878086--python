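"""MeSH term frequency statistics, cutoffs, and exclusion filtering.

Frequencies are *document* frequencies: a term counts once per article whose
(normalized, deduplicated) heading set contains it, regardless of how many
qualifier variants of the heading the article lists.  Headings that do not
resolve in the vocabulary are still counted — under their normalized literal
string — and reported separately, since unindexed or retired headings are a
fact of real corpora.

A frequency cutoff keeps terms seen at least ``min_count`` times; the
coverage of the kept subset is the fraction of total occurrences it
accounts for.  Exclusion filtering removes overly general "check tags"
(Humans, Animals, Cell Line...) and any further curated name lists; which
terms are too general is expert judgment, so the lists are declarative
config, not computed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

from .corpus import Corpus
from .mesh import MeshTree, normalize_heading, normalize_term

__all__ = [
    "TermFrequencyTable",
    "term_frequencies",
    "coverage_cutoff",
    "apply_exclusions",
    "load_exclusion_list",
    "packaged_exclusion_list",
    "write_frequency_tsv",
]


@dataclass(frozen=True)
class TermFrequencyTable:
    """Document frequencies, sorted by count descending then term ascending."""

    entries: tuple[tuple[str, int], ...]
    total_occurrences: int
    unresolved: frozenset[str] = frozenset()

    def counts(self) -> dict[str, int]:
        return dict(self.entries)


def term_frequencies(corpus: Corpus, tree: MeshTree) -> TermFrequencyTable:
    """Count, per term, the number of articles indexed with it.

    Headings are normalized (asterisk/qualifier stripped) and deduplicated
    within each article; headings resolving in ``tree`` (including via entry
    terms) are counted under the descriptor's preferred name, the rest under
    their normalized literal string and flagged in ``unresolved``.
    """
    counter: Counter[str] = Counter()
    unresolved: set[str] = set()
    for article in corpus:
        seen: set[str] = set()
        for heading in article.mesh_headings:
            literal = normalize_heading(heading)
            if not literal:
                continue
            resolved = tree.resolve(literal)
            if resolved is None:
                unresolved.add(literal)
                seen.add(literal)
            else:
                seen.add(resolved)
        counter.update(seen)
    entries = tuple(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    return TermFrequencyTable(
        entries=entries,
        total_occurrences=sum(counter.values()),
        unresolved=frozenset(unresolved),
    )


def coverage_cutoff(
    table: TermFrequencyTable, min_count: int
) -> tuple[set[str], float]:
    """Terms with count >= min_count, and the occurrence fraction they cover.

    Coverage is 1.0 at min_count=1 by construction, and defined as 1.0 on an
    empty table (vacuously everything is covered).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if not table.entries:
        return set(), 1.0
    kept = {term for term, count in table.entries if count >= min_count}
    covered = sum(count for term, count in table.entries if count >= min_count)
    return kept, covered / table.total_occurrences


def apply_exclusions(
    terms: Iterable[str],
    exclusion_list: Iterable[str] = (),
    pattern_rules: Iterable[Iterable[str]] = (),
) -> set[str]:
    """Remove exact exclusion matches and members of any curated name list.

    Matching is case-insensitive/whitespace-normalized on both sides.  Each
    pattern rule is itself a literal name list (e.g. a "general check tags"
    list and a "molecular entities" list shipped as package data).
    """
    banned = {normalize_term(t) for t in exclusion_list}
    for rule in pattern_rules:
        banned.update(normalize_term(t) for t in rule)
    return {t for t in terms if normalize_term(t) not in banned}


def load_exclusion_list(source: str | Path | IO[str]) -> set[str]:
    """Plain list file: one term per line, ``#`` comments and blanks ignored."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_exclusion_list(handle)
    out: set[str] = set()
    for line in source:
        term = line.split("#", 1)[0].strip()
        if term:
            out.add(term)
    return out


def packaged_exclusion_list(name: str) -> set[str]:
    """A curated exclusion list shipped with the package.

    Available: ``general_terms`` (check tags too general to discriminate) and
    ``molecular_entities`` (substance-level headings excluded as hard to
    classify).
    """
    text = resources.files("meshkos.data").joinpath(f"{name}.txt").read_text("utf-8")
    return load_exclusion_list(iter(text.splitlines(keepends=True)))


def write_frequency_tsv(table: TermFrequencyTable, sink: IO[str]) -> None:
    """Export as TSV: term, count, rank, cumulative coverage."""
    sink.write("term\tcount\trank\tcumulative_coverage\n")
    running = 0
    for rank, (term, count) in enumerate(table.entries, start=1):
        running += count
        cov = running / table.total_occurrences if table.total_occurrences else 1.0
        sink.write(f"{term}\t{count}\t{rank}\t{cov:.6f}\n")
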