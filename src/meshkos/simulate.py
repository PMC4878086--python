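"""Synthetic vocabularies and corpora with planted topical structure.

The generator builds a miniature MeSH-like poly-hierarchy and a MEDLINE
corpus in which *relevant* articles draw their headings preferentially from
a designated "specific" subtree, with known ground-truth relevance — so
every pipeline stage (harvesting, selection, query building, retrieval
evaluation, coherence, classification) can be exercised end to end with no
download and an exact answer key.

What is emulated, and how:

* **Poly-hierarchy with noise.**  Two top-level subtrees are grown at
  random: the specific subtree (rooted at ``specific_subtree_root``) and a
  background subtree.  ``n_multihomed`` descriptors inside the specific
  subtree receive a second tree number under the background subtree —
  planted analogues of the multi-homed cell lines (K562 and friends) that
  make exploded searches noisy.
* **Indexing depth.**  Each indexed article carries 7–8 headings by
  default, the typical indexing depth of a research article.
* **Relevance signal.**  A relevant article draws each heading from the
  specific subtree with probability ``p_topic_term`` (else from the
  background).  Relevant articles avoid the planted multi-homed terms: in
  the real vocabulary those index cell-line literature, not the domain's —
  which is precisely why excluding them costs almost no recall.
* **Noise channel.**  An irrelevant article draws from the background only,
  except that with probability ``p_noise_overlap`` one heading is a planted
  multi-homed term; these are the articles an exploded search wrongly pulls
  in and a NOT-exclusion removes.
* **Unindexed articles.**  With probability ``p_heading_free`` a relevant
  article has no headings at all but embeds ``marker_phrase`` in its title
  and abstract — modeling recent articles that only free-text supplements
  can rescue.
* **Heading decoration.**  Emitted MH lines carry ``/qualifier`` suffixes
  and leading ``*`` major-topic markers at the stated rates, so consumers
  must normalize exactly as with real MEDLINE exports.

Ground truth records the relevant PMIDs and a category assignment derived
from the immediate children of the specific root (one category per child;
an article belongs to every child subtree it draws a heading from).
Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .corpus import Article, Corpus
from .mesh import MeshDescriptor, MeshTree

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "generate_tree",
    "generate_corpus",
    "planted_noise_terms",
    "expected_query_rates",
]

_QUALIFIERS = ("metabolism", "genetics", "cytology", "physiology")


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n_descriptors: int = 120
    max_depth: int = 5
    branching: tuple[int, int] = (2, 4)
    n_articles: int = 500
    relevant_fraction: float = 0.4
    specific_subtree_root: str = "Stem Cells"
    headings_per_article: tuple[int, int] = (7, 8)
    p_topic_term: float = 0.9
    p_noise_overlap: float = 0.1
    n_multihomed: int = 3
    p_heading_free: float = 0.0
    marker_phrase: str = "stemness"
    p_qualifier: float = 0.2
    p_major_topic: float = 0.1

    def __post_init__(self) -> None:
        for name in ("relevant_fraction", "p_topic_term", "p_noise_overlap",
                     "p_heading_free", "p_qualifier", "p_major_topic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.headings_per_article[0] < 1:
            raise ValueError("headings_per_article must be >= 1")
        if self.n_descriptors < 2:
            raise ValueError("need at least 2 descriptors (two subtree roots)")
        if self.branching[0] < 1 or self.branching[1] < self.branching[0]:
            raise ValueError(f"bad branching range {self.branching}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    relevant_pmids: frozenset[str]
    category_assignments: dict[str, frozenset[str]]


BACKGROUND_ROOT = "General Concepts"


def generate_tree(spec: GeneratorSpec) -> MeshTree:
    """Random rooted poly-hierarchy with planted multi-homed noise terms.

    Node capacities are drawn from the branching range and depth is capped,
    so infeasible (n_descriptors, max_depth, branching) combinations raise
    instead of looping.  Deterministic under ``spec.seed``.
    """
    rng = random.Random(f"{spec.seed}-tree")
    bmin, bmax = spec.branching
    # generous feasibility bound: every node at full fan-out
    capacity = 2 * sum(bmax**d for d in range(spec.max_depth + 1))
    if spec.n_descriptors > capacity:
        raise ValueError(
            f"cannot place {spec.n_descriptors} descriptors with branching "
            f"<= {bmax} and max_depth {spec.max_depth}"
        )

    # node bookkeeping: tree number -> (depth, remaining child slots, next child seg)
    nodes: list[dict] = []

    def new_node(name: str, tn: str, depth: int) -> dict:
        node = {
            "name": name,
            "tns": [tn],
            "depth": depth,
            "slots": rng.randint(bmin, bmax),
            "next_child": 100,
        }
        nodes.append(node)
        return node

    def child_tn(parent: dict) -> str:
        seg = parent["next_child"]
        parent["next_child"] += 10
        parent["slots"] -= 1
        return f"{parent['tns'][0]}.{seg}"

    specific_root = new_node(spec.specific_subtree_root, "A11", 0)
    background_root = new_node(BACKGROUND_ROOT, "B01", 0)
    in_specific = {id(specific_root)}

    for i in range(2, spec.n_descriptors):
        eligible = [
            n for n in nodes if n["slots"] > 0 and n["depth"] < spec.max_depth
        ]
        if not eligible:
            # drawn fan-outs exhausted: allow any node still under the hard
            # branching cap, so feasible specs always complete
            eligible = [
                n
                for n in nodes
                if n["depth"] < spec.max_depth
                and (n["next_child"] - 100) // 10 < bmax
            ]
            for n in eligible:
                n["slots"] = max(n["slots"], 1)
        if not eligible:
            raise ValueError(
                f"ran out of attachment points after {i} descriptors "
                f"(branching {spec.branching}, max_depth {spec.max_depth})"
            )
        # grow the two subtrees evenly so both hold a usable share of the
        # vocabulary regardless of how early fan-out falls
        side = rng.random() < 0.5
        pool = [n for n in eligible if (id(n) in in_specific) == side] or eligible
        parent = rng.choice(pool)
        node = new_node(f"Concept {i:04d}", child_tn(parent), parent["depth"] + 1)
        if id(parent) in in_specific:
            in_specific.add(id(node))

    # multi-home *leaves* only: the real noisy hyponyms (cultured cell
    # lines) are terminal nodes, so NOT-excluding them never explodes away
    # legitimate descendants
    parent_tns = {n["tns"][0].rsplit(".", 1)[0] for n in nodes if "." in n["tns"][0]}
    specific_leaves = [
        n
        for n in nodes
        if id(n) in in_specific
        and n is not specific_root
        and n["tns"][0] not in parent_tns
    ]
    if spec.n_multihomed > len(specific_leaves):
        raise ValueError(
            f"n_multihomed={spec.n_multihomed} but the specific subtree has only "
            f"{len(specific_leaves)} leaf descriptors"
        )
    outside = [n for n in nodes if id(n) not in in_specific]
    for node in rng.sample(specific_leaves, spec.n_multihomed):
        host = rng.choice(outside)
        node["tns"].append(child_tn(host))

    descriptors = [
        MeshDescriptor(
            ui=f"D{i:06d}",
            name=n["name"],
            tree_numbers=frozenset(n["tns"]),
        )
        for i, n in enumerate(nodes, start=1)
    ]
    return MeshTree(descriptors)


def planted_noise_terms(tree: MeshTree, spec: GeneratorSpec) -> set[str]:
    """Names of the multi-homed descriptors: inside the specific subtree by
    one tree number, outside it by another."""
    root_tns = tree.get(spec.specific_subtree_root).tree_numbers
    inside = lambda tn: any(tn == r or tn.startswith(r + ".") for r in root_tns)
    return {
        d.name
        for d in tree
        if any(inside(tn) for tn in d.tree_numbers)
        and any(not inside(tn) for tn in d.tree_numbers)
    }


def _decorate(rng: random.Random, heading: str, spec: GeneratorSpec) -> str:
    if rng.random() < spec.p_qualifier:
        heading = f"{heading}/{rng.choice(_QUALIFIERS)}"
    if rng.random() < spec.p_major_topic:
        heading = f"*{heading}"
    return heading


def generate_corpus(spec: GeneratorSpec, tree: MeshTree) -> tuple[Corpus, GroundTruth]:
    """Generate ``n_articles`` with planted relevance; see module docstring."""
    rng = random.Random(f"{spec.seed}-corpus")
    root = tree.resolve(spec.specific_subtree_root)
    if root is None:
        raise ValueError(
            f"specific subtree root {spec.specific_subtree_root!r} not in tree"
        )
    subtree = sorted(tree.explode(root))
    noise = sorted(planted_noise_terms(tree, spec))
    all_names = sorted(d.name for d in tree)
    # relevant articles never draw the planted noise terms: in the real
    # vocabulary those index foreign (cell-line) literature, which is why
    # NOT-excluding them costs essentially no recall
    topic_pool = sorted(set(subtree) - set(noise))
    background_pool = sorted(set(all_names) - set(subtree))
    if not topic_pool:
        raise ValueError("specific subtree is empty after removing noise terms")
    if len(background_pool) < spec.headings_per_article[1]:
        raise ValueError("background subtree too small for the indexing depth")

    n_rel = math.floor(spec.relevant_fraction * spec.n_articles)
    relevant_idx = set(rng.sample(range(spec.n_articles), n_rel))

    # categories: immediate children of the specific root
    child_names = sorted({d.name for d in tree if root in tree.parents(d.name)})
    child_explodes = {c: {n.casefold() for n in tree.explode(c)} for c in child_names}

    articles: list[Article] = []
    relevant_pmids: set[str] = set()
    assignments: dict[str, frozenset[str]] = {}
    kmin, kmax = spec.headings_per_article
    for i in range(spec.n_articles):
        pmid = str(1_000_000 + i)
        is_rel = i in relevant_idx
        headings: list[str] = []
        if is_rel:
            relevant_pmids.add(pmid)
            if rng.random() < spec.p_heading_free:
                articles.append(
                    Article(
                        pmid=pmid,
                        title=f"Recent advances in {spec.marker_phrase} research",
                        abstract=(
                            f"We report new findings bearing on {spec.marker_phrase} "
                            "in an experimental model."
                        ),
                        journal="Synthetic Journal of Cell Biology",
                        pub_date="2011",
                    )
                )
                assignments[pmid] = frozenset()
                continue
            k = rng.randint(kmin, kmax)
            n_topic = sum(rng.random() < spec.p_topic_term for _ in range(k))
            n_topic = min(n_topic, len(topic_pool))
            n_back = min(k - n_topic, len(background_pool))
            headings = rng.sample(topic_pool, n_topic) + rng.sample(
                background_pool, n_back
            )
        else:
            k = rng.randint(kmin, kmax)
            headings = rng.sample(background_pool, k)
            if noise and rng.random() < spec.p_noise_overlap:
                headings[0] = rng.choice(noise)
        rng.shuffle(headings)
        keys = {h.casefold() for h in headings}
        cats = frozenset(
            c for c, names in child_explodes.items() if keys & names
        )
        assignments[pmid] = cats
        articles.append(
            Article(
                pmid=pmid,
                title=f"A study of {headings[0].lower()} and related factors",
                abstract=f"We examine {', '.join(h.lower() for h in headings[:3])}.",
                mesh_headings=[_decorate(rng, h, spec) for h in headings],
                journal="Synthetic Journal of Cell Biology",
                pub_date="2010",
            )
        )
    corpus = Corpus(
        articles,
        provenance=f"synthetic corpus (seed={spec.seed}, n={spec.n_articles})",
    )
    return corpus, GroundTruth(
        relevant_pmids=frozenset(relevant_pmids), category_assignments=assignments
    )


def expected_query_rates(spec: GeneratorSpec) -> tuple[float, float]:
    """Closed-form expected (recall, precision) of the plain exploded query
    on the specific root, without NOT-exclusion, under the generative model.

    A relevant indexed article is retrieved iff it draws >= 1 topic heading:
    P = 1 - (1 - p_topic_term)^k averaged over the indexing-depth range;
    heading-free relevant articles are never retrieved by a MeSH-only query.
    An irrelevant article is retrieved iff it received a planted noise
    heading: P = p_noise_overlap.  Valid while the topic pool is larger than
    the indexing depth (no clamping).
    """
    kmin, kmax = spec.headings_per_article
    p_hit = sum(
        1 - (1 - spec.p_topic_term) ** k for k in range(kmin, kmax + 1)
    ) / (kmax - kmin + 1)
    recall = (1 - spec.p_heading_free) * p_hit
    n_rel = math.floor(spec.relevant_fraction * spec.n_articles)
    n_irr = spec.n_articles - n_rel
    tp = n_rel * recall
    fp = n_irr * spec.p_noise_overlap
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return recall, precision
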