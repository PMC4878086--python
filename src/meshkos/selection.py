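"""Coarse-grained term labels and the two structural selection rules.

Experts label candidate terms as *specific* (usable on their own to retrieve
the domain), *related* (useful for fine-grained classification), *other*, or
*excluded*.  Two mechanical rules then shape the retrieval thesaurus:

1. **Parent tracing.**  Each specific term is traced upward until its parent
   is no longer specific; the surviving terms are the *roots* of the
   thesaurus.  "No longer related to the domain" is expert judgment, so it
   is operationalized as "parent not labeled specific" — the judgment lives
   in the label file, the tracing is code.

2. **Noisy-hyponym detection.**  A descendant of a root that is *also* homed
   in a subtree reachable without passing through any root (a multi-homed
   cell line, say) drags foreign literature into exploded searches.  Such
   terms are emitted as NOT-exclusion *candidates*; confirming them is again
   an expert step, driven by retrieval experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .errors import IntegrityError, ParseError, UnknownTermError
from .mesh import MeshTree, normalize_term, parent_tree_number

__all__ = [
    "LABELS",
    "TermLabel",
    "LabeledTermSet",
    "load_labels",
    "derive_specific_roots",
    "find_noisy_hyponyms",
    "build_labeled_term_set",
]

LABELS = ("specific", "related", "other", "excluded")


@dataclass(frozen=True)
class TermLabel:
    term: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParseError(f"unknown label {self.label!r} for term {self.term!r}")


@dataclass(frozen=True)
class LabeledTermSet:
    """An expert-labeled term set with its derived structure.

    ``specific_roots`` are the top-most specific terms; ``noisy_hyponyms``
    the multi-homed descendants proposed for NOT-exclusion;
    ``freetext_supplements`` the non-vocabulary phrases added for recall.
    """

    labels: tuple[TermLabel, ...]
    specific_roots: frozenset[str]
    noisy_hyponyms: frozenset[str]
    freetext_supplements: tuple[str, ...] = ()

    def labeled(self, label: str) -> set[str]:
        return {tl.term for tl in self.labels if tl.label == label}


def load_labels(source: str | Path | IO[str]) -> list[TermLabel]:
    """Read ``term<TAB>label`` rows; duplicates must agree, labels are closed."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_labels(handle)
    seen: dict[str, tuple[str, int]] = {}
    out: list[TermLabel] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"line {lineno}: expected term<TAB>label, got {len(cols)} columns")
        term, label = cols[0].strip(), cols[1].strip().lower()
        if label not in LABELS:
            raise ParseError(
                f"line {lineno}: unknown label {label!r} (expected one of {', '.join(LABELS)})"
            )
        key = normalize_term(term)
        if key in seen:
            prev_label, prev_line = seen[key]
            if prev_label != label:
                raise IntegrityError(
                    f"line {lineno}: term {term!r} already labeled {prev_label!r} "
                    f"at line {prev_line}"
                )
            continue  # consistent duplicate, deduplicated silently
        seen[key] = (label, lineno)
        out.append(TermLabel(term=term, label=label))
    return out


def _resolve_all(tree: MeshTree, terms: Iterable[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for t in terms:
        name = tree.resolve(t)
        if name is None:
            missing.append(t)
        else:
            resolved[t] = name
    if missing:
        raise UnknownTermError(
            "terms not in the vocabulary: " + ", ".join(repr(m) for m in sorted(missing))
        )
    return resolved


def derive_specific_roots(tree: MeshTree, labels: Iterable[TermLabel]) -> set[str]:
    """Specific-labeled terms none of whose parents is also specific-labeled.

    Because parent tracing follows every tree number, a term multi-homed
    under both a specific parent and an unrelated subtree is still folded
    under the specific parent (one specific parent suffices to subsume it).
    Every specific-labeled term is descendant-or-self of some returned root.
    """
    specific = [tl.term for tl in labels if tl.label == "specific"]
    resolved = _resolve_all(tree, specific)
    specific_names = set(resolved.values())
    roots: set[str] = set()
    for name in specific_names:
        if not (tree.parents(name) & specific_names):
            roots.add(name)
    return roots


def find_noisy_hyponyms(
    tree: MeshTree, roots: Iterable[str], specific_terms: Iterable[str] = ()
) -> set[str]:
    """Descendants of the roots that are also reachable outside them.

    A candidate is any non-root, non-specific descendant of some root that
    owns at least one tree number whose root-to-node path passes through no
    root — i.e. the term is homed both inside and outside the selected
    subtrees.  Candidates are advisory: the final NOT-list is curated.
    """
    root_names = set(_resolve_all(tree, roots).values())
    specific_names = set(_resolve_all(tree, specific_terms).values()) if specific_terms else set()
    root_tns = {tn for r in root_names for tn in tree.get(r).tree_numbers}

    def path_escapes_roots(tn: str) -> bool:
        # True if no prefix of tn (including tn itself) is a root tree number
        probe: str | None = tn
        while probe is not None:
            if probe in root_tns:
                return False
            probe = parent_tree_number(probe)
        return True

    candidates: set[str] = set()
    for root in root_names:
        candidates |= tree.explode(root)
    candidates -= root_names
    candidates -= specific_names
    return {
        name
        for name in candidates
        if any(path_escapes_roots(tn) for tn in tree.get(name).tree_numbers)
    }


def build_labeled_term_set(
    tree: MeshTree,
    labels: Iterable[TermLabel],
    freetext_supplements: Iterable[str] = (),
) -> LabeledTermSet:
    """Derive roots and noise candidates from a label collection in one step."""
    labels = tuple(labels)
    roots = derive_specific_roots(tree, labels)
    specific = {tl.term for tl in labels if tl.label == "specific"}
    noisy = find_noisy_hyponyms(tree, roots, specific)
    return LabeledTermSet(
        labels=labels,
        specific_roots=frozenset(roots),
        noisy_hyponyms=frozenset(noisy),
        freetext_supplements=tuple(freetext_supplements),
    )
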