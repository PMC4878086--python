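"""Classified thesaurus: bucketing literature by category-keyed term sets.

A *classified thesaurus* maps analysis categories (anatomical systems,
disease groups, cell types...) to lists of vocabulary terms.  An article
belongs to a category when any of its headings falls inside the hyponym
explosion of any of the category's terms; categories may overlap ("crossed"
categories), so membership is a set.  The upper-node rule — when a term is
in a category, consider adding its ancestors too — is emitted as curation
*suggestions* only: whether a broader ancestor still belongs is expert
judgment (auto-merging would eventually pull in wildly general nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import yaml

from .corpus import Article
from .errors import IntegrityError, UnknownTermError
from .mesh import MeshTree, normalize_term
from .query import BooleanQuery

__all__ = [
    "Category",
    "ClassifiedThesaurus",
    "load_categories",
    "classify_article",
    "suggest_upper_nodes",
    "category_queries",
]


@dataclass(frozen=True)
class Category:
    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise IntegrityError(f"category {self.name!r} has no terms")
        keys = [normalize_term(t) for t in self.terms]
        if len(set(keys)) != len(keys):
            raise IntegrityError(f"category {self.name!r} lists a term twice")


@dataclass(frozen=True)
class ClassifiedThesaurus:
    categories: tuple[Category, ...]
    framework_note: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IntegrityError(f"duplicate category names: {dupes}")

    def __iter__(self):
        return iter(self.categories)

    def get(self, name: str) -> Category:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)


def load_categories(
    source: str | Path | IO[str] | Mapping,
    tree: MeshTree,
    strict: bool = True,
) -> ClassifiedThesaurus:
    """Read a category config (YAML) and validate against the vocabulary.

    Accepted shapes: a mapping ``{category name: [term, ...]}``, a list of
    ``{name: ..., terms: [...]}`` entries, or either nested under a
    ``categories`` key with an optional ``framework`` note.  In strict mode
    a term missing from the vocabulary is an error; in lenient mode it is
    kept (flagged to the caller by failing resolution later).
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_categories(handle, tree, strict=strict)
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        doc = yaml.safe_load(source) or {}
    note = ""
    if isinstance(doc, Mapping) and "categories" in doc:
        note = str(doc.get("framework", ""))
        doc = doc["categories"]
    if isinstance(doc, Mapping):
        items = [(str(k), v) for k, v in doc.items()]
    else:
        items = []
        for entry in doc or []:
            if not isinstance(entry, Mapping) or "name" not in entry or "terms" not in entry:
                raise IntegrityError(f"malformed category entry: {entry!r}")
            items.append((str(entry["name"]), entry["terms"]))
    categories = []
    for name, terms in items:
        if not isinstance(terms, (list, tuple)):
            raise IntegrityError(f"category {name!r}: terms must be a list")
        categories.append(Category(name=name, terms=tuple(str(t) for t in terms)))
    thesaurus = ClassifiedThesaurus(categories=tuple(categories), framework_note=note)
    if strict:
        missing = [
            (c.name, t) for c in thesaurus for t in c.terms if t not in tree
        ]
        if missing:
            listing = ", ".join(f"{t!r} (in {c!r})" for c, t in missing[:20])
            raise UnknownTermError(f"category terms not in vocabulary: {listing}")
    return thesaurus


def classify_article(
    article: Article,
    thesaurus: ClassifiedThesaurus,
    tree: MeshTree,
    explode: bool = True,
) -> set[str]:
    """Categories whose (exploded) term sets intersect the article's headings.

    With ``explode=False`` membership requires an exact heading match; the
    exploded membership is always a superset of the exact one.
    """
    headings = article.heading_keys()
    if not headings:
        return set()
    out: set[str] = set()
    for cat in thesaurus:
        for term in cat.terms:
            if term not in tree:
                continue
            names = tree.explode(term) if explode else {tree.resolve(term)}
            if headings & {normalize_term(n) for n in names}:
                out.add(cat.name)
                break
    return out


def suggest_upper_nodes(
    thesaurus: ClassifiedThesaurus, tree: MeshTree
) -> dict[str, set[str]]:
    """Per category, the strict ancestors of its terms not already members.

    Emitted as curation suggestions, never auto-merged.
    """
    out: dict[str, set[str]] = {}
    for cat in thesaurus:
        members = {normalize_term(t) for t in cat.terms}
        suggested: set[str] = set()
        for term in cat.terms:
            if term not in tree:
                continue
            suggested |= tree.ancestors(term)
        out[cat.name] = {s for s in suggested if normalize_term(s) not in members}
    return out


def category_queries(thesaurus: ClassifiedThesaurus) -> dict[str, BooleanQuery]:
    """One exploded OR-query per category, for recall/precision evaluation."""
    return {
        cat.name: BooleanQuery(include_mesh=cat.terms) for cat in thesaurus
    }
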