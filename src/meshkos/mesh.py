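"""MeSH vocabulary model and tree-number hierarchy traversal.

MeSH (Medical Subject Headings) is the controlled vocabulary used to index
PubMed.  Each *descriptor* carries a unique identifier, a preferred name,
optional entry terms (synonyms), and one or more *tree numbers* —
dot-separated path codes such as ``A11.872.700`` locating the descriptor in
a poly-hierarchy.  A descriptor may sit in several subtrees at once; this
multi-homing is exactly what makes some hyponyms "noisy" in exploded
searches (a cell line filed both under progenitor cells and under cultured
cell lines drags cell-line literature into a stem-cell query).

All hierarchy operations here — parents, explosion, ancestry — are defined
over tree-number prefixes, which is how PubMed itself resolves hyponym
expansion.
"""

from __future__ import annotations

import io
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from lxml import etree

from .errors import IntegrityError, ParseError, UnknownTermError

__all__ = [
    "MeshDescriptor",
    "MeshTree",
    "load_mesh",
    "dump_mesh_tsv",
    "parents",
    "explode",
    "is_ancestor",
    "normalize_term",
    "normalize_heading",
    "parent_tree_number",
]

_WS = re.compile(r"\s+")
_TREE_NUMBER = re.compile(r"^[A-Za-z][A-Za-z0-9]*(?:\.[A-Za-z0-9]+)*$")


def normalize_term(name: str) -> str:
    """Canonical lookup key for a term: whitespace-collapsed, case-folded."""
    return _WS.sub(" ", name).strip().casefold()


def normalize_heading(heading: str) -> str:
    """Strip MEDLINE MH decorations: leading ``*`` (major topic) and ``/qualifier``.

    Returns the bare descriptor name with original casing, e.g.
    ``"*Stem Cells/metabolism"`` -> ``"Stem Cells"``.
    """
    head = heading.lstrip("*").split("/", 1)[0]
    return _WS.sub(" ", head).strip()


def parent_tree_number(tn: str) -> str | None:
    """Tree number with the last dot-segment removed; None for top-level numbers."""
    if "." not in tn:
        return None
    return tn.rsplit(".", 1)[0]


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH descriptor: identifier, preferred name, hierarchy positions, synonyms."""

    ui: str
    name: str
    tree_numbers: frozenset[str]
    entry_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ui:
            raise IntegrityError("descriptor with empty UI")
        if not self.name.strip():
            raise IntegrityError(f"descriptor {self.ui}: empty name")
        if not self.tree_numbers:
            raise IntegrityError(f"descriptor {self.ui} ({self.name!r}): no tree numbers")
        for tn in self.tree_numbers:
            if not _TREE_NUMBER.match(tn):
                raise IntegrityError(
                    f"descriptor {self.ui} ({self.name!r}): malformed tree number {tn!r}"
                )


class MeshTree:
    """Indexed collection of descriptors supporting hierarchy queries.

    Lookup by name is case-insensitive and whitespace-normalized; entry terms
    resolve to their owning descriptor.  The tree-number -> descriptor map is
    a bijection onto the used tree numbers (duplicates are a hard error).
    """

    def __init__(self, descriptors: Iterable[MeshDescriptor] = ()):
        self._by_ui: dict[str, MeshDescriptor] = {}
        self._name_index: dict[str, str] = {}  # normalized preferred name -> ui
        self._entry_index: dict[str, str] = {}  # normalized entry term -> ui
        self._tn_owner: dict[str, str] = {}  # tree number -> ui
        self._children: dict[str, list[str]] = defaultdict(list)
        for d in descriptors:
            self._add(d)
        for kids in self._children.values():
            kids.sort()

    def _add(self, d: MeshDescriptor) -> None:
        if d.ui in self._by_ui:
            raise IntegrityError(f"duplicate descriptor UI {d.ui}")
        key = normalize_term(d.name)
        if key in self._name_index:
            other = self._by_ui[self._name_index[key]]
            raise IntegrityError(
                f"duplicate descriptor name {d.name!r}: {other.ui} vs {d.ui}"
            )
        for tn in d.tree_numbers:
            if tn in self._tn_owner:
                other = self._by_ui[self._tn_owner[tn]]
                raise IntegrityError(
                    f"tree number {tn} claimed by both {other.ui} ({other.name!r}) "
                    f"and {d.ui} ({d.name!r})"
                )
        self._by_ui[d.ui] = d
        self._name_index[key] = d.ui
        for tn in d.tree_numbers:
            self._tn_owner[tn] = d.ui
            parent = parent_tree_number(tn)
            if parent is not None:
                self._children[parent].append(tn)
        for term in d.entry_terms:
            ekey = normalize_term(term)
            if ekey and ekey not in self._name_index and ekey not in self._entry_index:
                self._entry_index[ekey] = d.ui
        # entry terms shadowed by preferred names or by earlier entries are
        # silently unusable for lookup; the descriptor still records them

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_ui)

    def __iter__(self) -> Iterator[MeshDescriptor]:
        return iter(self._by_ui.values())

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeshTree):
            return NotImplemented
        canon = lambda t: {
            (d.ui, d.name, d.tree_numbers, d.entry_terms) for d in t
        }
        return canon(self) == canon(other)

    # -- lookup -------------------------------------------------------------

    def get(self, term: str) -> MeshDescriptor:
        """Descriptor for a preferred name or entry term; raises UnknownTermError."""
        key = normalize_term(term)
        ui = self._name_index.get(key) or self._entry_index.get(key)
        if ui is None:
            raise UnknownTermError(f"unknown MeSH term: {term!r}")
        return self._by_ui[ui]

    def resolve(self, term: str) -> str | None:
        """Preferred descriptor name for a term, or None if unresolvable."""
        key = normalize_term(term)
        ui = self._name_index.get(key) or self._entry_index.get(key)
        return self._by_ui[ui].name if ui is not None else None

    def by_ui(self, ui: str) -> MeshDescriptor:
        return self._by_ui[ui]

    def owner_of(self, tree_number: str) -> MeshDescriptor | None:
        ui = self._tn_owner.get(tree_number)
        return self._by_ui[ui] if ui is not None else None

    @property
    def tree_numbers(self) -> frozenset[str]:
        return frozenset(self._tn_owner)

    # -- hierarchy ----------------------------------------------------------

    def parents(self, term: str) -> set[str]:
        """Names of descriptors owning the parent tree number of each of
        ``term``'s tree numbers.  Top-level numbers (and numbers whose parent
        is not used by any descriptor) contribute nothing; ``term`` itself is
        never returned."""
        d = self.get(term)
        out: set[str] = set()
        for tn in d.tree_numbers:
            p = parent_tree_number(tn)
            if p is not None:
                owner = self.owner_of(p)
                if owner is not None and owner.ui != d.ui:
                    out.add(owner.name)
        return out

    def explode(self, term: str) -> set[str]:
        """The term plus every hierarchical descendant ("hyponym explosion").

        A descriptor is included iff one of its tree numbers prefix-extends
        any of ``term``'s tree numbers; the closure runs over ALL the term's
        tree numbers, which is what PubMed does and what makes multi-homed
        descendants noisy.
        """
        d = self.get(term)
        names = {d.name}
        stack = list(d.tree_numbers)
        seen: set[str] = set(stack)
        while stack:
            tn = stack.pop()
            owner = self.owner_of(tn)
            if owner is not None:
                names.add(owner.name)
            for child in self._children.get(tn, ()):
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return names

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff some tree number of ``b`` strictly prefix-extends some
        tree number of ``a`` (strict: a term is never its own ancestor)."""
        da, db = self.get(a), self.get(b)
        for tb in db.tree_numbers:
            for ta in da.tree_numbers:
                if tb.startswith(ta + "."):
                    return True
        return False

    def ancestors(self, term: str) -> set[str]:
        """Names of all strict ancestors of ``term`` via any tree number."""
        d = self.get(term)
        out: set[str] = set()
        for tn in d.tree_numbers:
            p = parent_tree_number(tn)
            while p is not None:
                owner = self.owner_of(p)
                if owner is not None and owner.ui != d.ui:
                    out.add(owner.name)
                p = parent_tree_number(p)
        return out


# -- module-level operation surface -----------------------------------------


def parents(tree: MeshTree, term: str) -> set[str]:
    return tree.parents(term)


def explode(tree: MeshTree, term: str) -> set[str]:
    return tree.explode(term)


def is_ancestor(tree: MeshTree, a: str, b: str) -> bool:
    return tree.is_ancestor(a, b)


# -- readers / writers -------------------------------------------------------


def load_mesh(source: str | Path | IO, dialect: str = "tsv") -> MeshTree:
    """Read a vocabulary from the official descriptor XML or the TSV dialect.

    TSV dialect: ``ui<TAB>name<TAB>tree-numbers(';'-separated)<TAB>entry-terms
    ('|'-separated, optional column)``, UTF-8, ``#`` comment lines allowed.
    """
    if dialect == "tsv":
        return _load_tsv(source)
    if dialect == "xml":
        return _load_xml(source)
    raise ValueError(f"unknown MeSH dialect: {dialect!r}")


def _open_text(source: str | Path | IO):
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8"), True
    return source, False


def _load_tsv(source: str | Path | IO) -> MeshTree:
    handle, owned = _open_text(source)
    descriptors: list[MeshDescriptor] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"line {lineno}: expected at least 3 tab-separated columns, got {len(cols)}"
                )
            ui, name, tn_col = cols[0].strip(), cols[1].strip(), cols[2]
            entry_col = cols[3] if len(cols) > 3 else ""
            tns = frozenset(t.strip() for t in tn_col.split(";") if t.strip())
            entries = frozenset(e.strip() for e in entry_col.split("|") if e.strip())
            try:
                descriptors.append(
                    MeshDescriptor(ui=ui, name=name, tree_numbers=tns, entry_terms=entries)
                )
            except IntegrityError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if owned:
            handle.close()
    return MeshTree(descriptors)


def _load_xml(source: str | Path | IO) -> MeshTree:
    if isinstance(source, io.TextIOBase):
        source = io.BytesIO(source.read().encode("utf-8"))
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed descriptor XML: {exc}") from exc
    descriptors: list[MeshDescriptor] = []
    for rec in tree.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI", "").strip()
        name = rec.findtext("DescriptorName/String", "").strip()
        tns = frozenset(
            el.text.strip() for el in rec.findall("TreeNumberList/TreeNumber") if el.text
        )
        entries = frozenset(
            el.text.strip()
            for el in rec.findall("ConceptList/Concept/TermList/Term/String")
            if el.text and el.text.strip() and normalize_term(el.text) != normalize_term(name)
        )
        try:
            descriptors.append(
                MeshDescriptor(ui=ui, name=name, tree_numbers=tns, entry_terms=entries)
            )
        except IntegrityError as exc:
            raise ParseError(f"DescriptorRecord {ui or '<no UI>'}: {exc}") from exc
    return MeshTree(descriptors)


def dump_mesh_tsv(tree: MeshTree, sink: IO[str]) -> None:
    """Write the TSV dialect (rows sorted by UI; re-readable by load_mesh)."""
    for d in sorted(tree, key=lambda d: d.ui):
        sink.write(
            "\t".join(
                [
                    d.ui,
                    d.name,
                    ";".join(sorted(d.tree_numbers)),
                    "|".join(sorted(d.entry_terms)),
                ]
            )
            + "\n"
        )
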