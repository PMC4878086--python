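"""Boolean retrieval over a local corpus and the sampling evaluation protocols.

``execute`` matches a query against every article: a vocabulary include term
matches an article iff the article's normalized heading set intersects the
term's hyponym explosion (PubMed's default behavior); a free-text term
matches iff it occurs, case-insensitively at token boundaries, in title,
abstract, or keywords.  The NOT-set is subtracted after the union of
includes, so adding an exclude term can only shrink the result and adding an
include term can only grow it.

Evaluation mirrors the field's manual protocols with the human judge
abstracted to an injected oracle:

* recall against a gold article set is exact (full enumeration, no
  sampling);
* precision is estimated by repeatedly drawing seeded random samples of the
  retrieval set and asking the oracle which members are relevant, reporting
  every replicate and their mean;
* per-category recall draws one seeded benchmark sample, has the oracle
  assign categories (multi-membership allowed), and scores each category's
  query against its benchmark members.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Iterable, Mapping

import numpy as np

from .corpus import Corpus, sample_articles
from .errors import UnknownTermError
from .mesh import MeshTree, normalize_term
from .query import BooleanQuery

__all__ = [
    "RetrievalResult",
    "EvalReport",
    "execute",
    "recall_vs_gold",
    "precision_by_sampling",
    "category_recall",
    "load_judgments",
    "load_category_judgments",
]

Judge = Callable[[str], bool] | Mapping[str, bool]
CategoryJudge = Callable[[str], set[str]] | Mapping[str, set[str]]


@dataclass(frozen=True)
class RetrievalResult:
    query: BooleanQuery
    retrieved_pmids: frozenset[str]
    corpus_size: int


@dataclass(frozen=True)
class EvalReport:
    metric: str
    replicate_values: tuple[float, ...]
    mean: float
    sample_size: int
    replicates: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "replicate_values": list(self.replicate_values),
            "mean": self.mean,
            "sample_size": self.sample_size,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


def _mesh_match_keys(
    tree: MeshTree, terms: Iterable[str], explode: bool, on_unresolved: str
) -> tuple[set[str], list[str]]:
    """Union of normalized heading keys matching any of the terms; also the
    terms demoted to free-text under the lenient policy."""
    keys: set[str] = set()
    demoted: list[str] = []
    for term in terms:
        if term not in tree:
            if on_unresolved == "lenient":
                demoted.append(term)
                continue
            raise UnknownTermError(f"include term not in vocabulary: {term!r}")
        names = tree.explode(term) if explode else {tree.resolve(term)}
        keys.update(normalize_term(n) for n in names)
    return keys, demoted


def _freetext_pattern(term: str) -> re.Pattern[str]:
    # token-boundary, case-insensitive: "ipsc" must not match inside a word
    return re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", re.IGNORECASE)


def execute(
    corpus: Corpus,
    tree: MeshTree,
    query: BooleanQuery,
    on_unresolved: str = "strict",
) -> RetrievalResult:
    """Run a boolean query; see the module docstring for matching semantics.

    ``on_unresolved``: ``"strict"`` raises on an include term missing from
    the vocabulary, ``"lenient"`` demotes it to a free-text term.  Exclude
    terms missing from the vocabulary exclude nothing under either policy.
    """
    if not query.runnable:
        raise ValueError("query has no include terms")
    if on_unresolved not in ("strict", "lenient"):
        raise ValueError(f"on_unresolved must be strict|lenient, got {on_unresolved!r}")

    include_keys, demoted = _mesh_match_keys(
        tree, query.include_mesh, query.explode_includes, on_unresolved
    )
    exclude_keys: set[str] = set()
    for term in query.exclude_mesh:
        if term in tree:
            names = tree.explode(term) if query.explode_excludes else {tree.resolve(term)}
            exclude_keys.update(normalize_term(n) for n in names)
    patterns = [_freetext_pattern(t) for t in (*query.include_freetext, *demoted)]

    retrieved: set[str] = set()
    for article in corpus:
        headings = article.heading_keys()
        if headings & exclude_keys:
            continue
        if headings & include_keys:
            retrieved.add(article.pmid)
            continue
        if patterns:
            text = article.text_fields()
            if any(p.search(text) for p in patterns):
                retrieved.add(article.pmid)
    return RetrievalResult(
        query=query, retrieved_pmids=frozenset(retrieved), corpus_size=len(corpus)
    )


def recall_vs_gold(result: RetrievalResult, gold: Iterable[str]) -> float:
    """Exact recall: fraction of the gold set retrieved (no sampling)."""
    gold = set(gold)
    if not gold:
        raise ValueError("gold set is empty")
    return len(result.retrieved_pmids & gold) / len(gold)


def _judge_lookup(judge: Judge, pmids: Iterable[str]) -> dict[str, bool]:
    if callable(judge):
        return {p: bool(judge(p)) for p in pmids}
    missing = [p for p in pmids if p not in judge]
    if missing:
        raise ValueError(
            "pmids missing from judgment file: " + ", ".join(sorted(missing)[:20])
        )
    return {p: bool(judge[p]) for p in pmids}


def precision_by_sampling(
    result: RetrievalResult,
    judge: Judge,
    sample_size: int = 100,
    replicates: int = 3,
    seed: int = 0,
) -> EvalReport:
    """Relevant fraction in repeated seeded samples of the retrieval set.

    Each replicate draws a fresh sample without replacement from an
    independently seeded stream derived from ``(seed, replicate index)``, so
    any single replicate is reproducible on its own.
    """
    retrieved = sorted(result.retrieved_pmids)
    if sample_size > len(retrieved):
        raise ValueError(
            f"sample_size {sample_size} exceeds retrieval set size {len(retrieved)}"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    relevance = _judge_lookup(judge, retrieved)
    values: list[float] = []
    for i in range(replicates):
        rng = np.random.default_rng([seed, i])
        picks = rng.choice(len(retrieved), size=sample_size, replace=False)
        values.append(sum(relevance[retrieved[j]] for j in picks) / sample_size)
    return EvalReport(
        metric="precision",
        replicate_values=tuple(values),
        mean=float(np.mean(values)),
        sample_size=sample_size,
        replicates=replicates,
        seed=seed,
    )


def category_recall(
    corpus: Corpus,
    tree: MeshTree,
    category_queries: Mapping[str, BooleanQuery],
    bench_judge: CategoryJudge,
    bench_size: int = 300,
    seed: int = 0,
) -> dict[str, float | None]:
    """Per-category recall against one seeded benchmark sample.

    The oracle assigns each sampled article its category set; recall for a
    category is the fraction of its benchmark members retrieved by that
    category's query.  A category with no benchmark members is reported as
    ``None`` (undefined, distinct from 0.0).
    """
    bench = sample_articles(corpus, bench_size, seed)
    if callable(bench_judge):
        assigned = {a.pmid: set(bench_judge(a.pmid)) for a in bench}
    else:
        missing = [a.pmid for a in bench if a.pmid not in bench_judge]
        if missing:
            raise ValueError(
                "pmids missing from category judgments: " + ", ".join(sorted(missing)[:20])
            )
        assigned = {a.pmid: set(bench_judge[a.pmid]) for a in bench}
    out: dict[str, float | None] = {}
    for name, q in category_queries.items():
        members = {p for p, cats in assigned.items() if name in cats}
        if not members:
            out[name] = None
            continue
        retrieved = execute(corpus, tree, q).retrieved_pmids
        out[name] = len(members & retrieved) / len(members)
    return out


def load_judgments(source: str | Path | IO[str]) -> dict[str, bool]:
    """Binary relevance TSV: ``pmid<TAB>0|1``."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_judgments(handle)
    out: dict[str, bool] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2 or cols[1] not in ("0", "1"):
            raise ValueError(f"line {lineno}: expected pmid<TAB>0|1, got {line!r}")
        out[cols[0]] = cols[1] == "1"
    return out


def load_category_judgments(source: str | Path | IO[str]) -> dict[str, set[str]]:
    """Category assignment TSV: ``pmid<TAB>category[,category...]`` (empty
    second column = no categories)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_category_judgments(handle)
    out: dict[str, set[str]] = {}
    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        pmid, _, cats = line.partition("\t")
        out[pmid.strip()] = {c.strip() for c in cats.split(",") if c.strip()}
    return out
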