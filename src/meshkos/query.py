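"""Boolean retrieval queries: OR-set of vocabulary terms plus free-text
supplements, minus a NOT-set, serializable to PubMed-style syntax.

The plain dialect reproduces the printed shape used in the field::

    ("Stem Cells" OR "stem cell" ...) NOT ("K562 Cells" OR ...)

Term order is preserved, never sorted: a published query is an ordered
artifact and its serialization must be byte-reproducible.  NOT binds last:
the semantics are (union of include matches) minus (union of exclude
matches), matching PubMed's left-to-right reading of this shape.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ParseError
from .mesh import MeshTree, normalize_term

__all__ = ["BooleanQuery", "build_query", "serialize", "parse"]


@dataclass(frozen=True)
class BooleanQuery:
    include_mesh: tuple[str, ...] = ()
    include_freetext: tuple[str, ...] = ()
    exclude_mesh: tuple[str, ...] = ()
    explode_includes: bool = True
    explode_excludes: bool = True

    def __post_init__(self) -> None:
        for label, terms in (
            ("include_mesh", self.include_mesh),
            ("include_freetext", self.include_freetext),
            ("exclude_mesh", self.exclude_mesh),
        ):
            keys = [normalize_term(t) for t in terms]
            if len(set(keys)) != len(keys):
                raise ValueError(f"duplicate terms in {label}: {terms}")
        overlap = {normalize_term(t) for t in self.include_mesh} & {
            normalize_term(t) for t in self.exclude_mesh
        }
        if overlap:
            raise ValueError(f"terms both included and excluded: {sorted(overlap)}")

    @property
    def runnable(self) -> bool:
        return bool(self.include_mesh or self.include_freetext)


def build_query(
    roots: Sequence[str],
    freetext: Sequence[str] = (),
    exclusions: Sequence[str] = (),
    explode_includes: bool = True,
    explode_excludes: bool = True,
) -> BooleanQuery:
    """Assemble a query preserving the given term ordering."""
    return BooleanQuery(
        include_mesh=tuple(roots),
        include_freetext=tuple(freetext),
        exclude_mesh=tuple(exclusions),
        explode_includes=explode_includes,
        explode_excludes=explode_excludes,
    )


def serialize(query: BooleanQuery, dialect: str = "plain") -> str:
    """Render to a query string.

    ``plain``: every term double-quoted, OR-joined, includes first, then at
    most one NOT-group — byte-reproducible.  ``pubmed_tagged``: same shape
    with ``[MeSH Terms]`` / ``[All Fields]`` suffixes, for real PubMed use
    where untagged tokens would be auto-mapped.
    """
    if not query.runnable:
        raise ValueError("cannot serialize a query with no include terms")
    if dialect == "plain":
        mesh = [f'"{t}"' for t in query.include_mesh]
        free = [f'"{t}"' for t in query.include_freetext]
        excl = [f'"{t}"' for t in query.exclude_mesh]
    elif dialect == "pubmed_tagged":
        mesh = [f'"{t}"[MeSH Terms]' for t in query.include_mesh]
        free = [f'"{t}"[All Fields]' for t in query.include_freetext]
        excl = [f'"{t}"[MeSH Terms]' for t in query.exclude_mesh]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    text = "(" + " OR ".join(mesh + free) + ")"
    if excl:
        text += " NOT (" + " OR ".join(excl) + ")"
    return text


_TOKEN = re.compile(r'"([^"]*)"|(\bOR\b)|(\bNOT\b)|(\()|(\))|(\S)')


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    for m in _TOKEN.finditer(text):
        pos = m.start()
        if m.group(1) is not None:
            tokens.append(("TERM", m.group(1), pos))
        elif m.group(2):
            tokens.append(("OR", "OR", pos))
        elif m.group(3):
            tokens.append(("NOT", "NOT", pos))
        elif m.group(4):
            tokens.append(("LPAR", "(", pos))
        elif m.group(5):
            tokens.append(("RPAR", ")", pos))
        else:
            raise ParseError(f"position {pos}: unexpected character {m.group(6)!r}")
    return tokens


def parse(text: str, tree: MeshTree | None = None) -> BooleanQuery:
    """Parse the plain dialect back into a BooleanQuery.

    Grammar: ``query := group (NOT group)?``, ``group := '(' term (OR
    term)* ')'`` with double-quoted terms; a leading ``=`` (as sometimes
    printed before a query) is tolerated.  Include terms resolving in the
    supplied vocabulary go to ``include_mesh``, the rest to
    ``include_freetext``; with no vocabulary everything is free-text.
    NOT-group terms always land in ``exclude_mesh``.
    """
    stripped = text.strip()
    if stripped.startswith("="):
        stripped = stripped[1:]
    tokens = _tokenize(stripped)
    cursor = 0

    def expect(kind: str) -> tuple[str, str, int]:
        nonlocal cursor
        if cursor >= len(tokens):
            raise ParseError(f"position {len(stripped)}: unexpected end of query, wanted {kind}")
        tok = tokens[cursor]
        if tok[0] != kind:
            raise ParseError(f"position {tok[2]}: expected {kind}, found {tok[1]!r}")
        cursor += 1
        return tok

    def group() -> list[str]:
        expect("LPAR")
        terms = [expect("TERM")[1]]
        while cursor < len(tokens) and tokens[cursor][0] == "OR":
            expect("OR")
            terms.append(expect("TERM")[1])
        expect("RPAR")
        return terms

    includes = group()
    excludes: list[str] = []
    if cursor < len(tokens) and tokens[cursor][0] == "NOT":
        expect("NOT")
        excludes = group()
    if cursor < len(tokens):
        tok = tokens[cursor]
        raise ParseError(f"position {tok[2]}: trailing content {tok[1]!r}")

    mesh: list[str] = []
    free: list[str] = []
    for term in includes:
        if tree is not None and term in tree:
            mesh.append(term)
        else:
            free.append(term)
    return BooleanQuery(
        include_mesh=tuple(mesh),
        include_freetext=tuple(free),
        exclude_mesh=tuple(excludes),
    )
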