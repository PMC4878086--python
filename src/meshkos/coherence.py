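"""Topical coherence of a retrieval set via binary vector-space cosine.

Each article is represented as a 0/1 indicator vector over MeSH terms:
x(t) = 1 iff term t indexes the article.  For a pair of articles the
vocabulary is the sorted union of their heading sets, and their similarity
is the cosine

    cos(x, y) = sum_t x(t) y(t) / sqrt(sum_t x(t)^2 * sum_t y(t)^2),

which for binary vectors is |X ∩ Y| / sqrt(|X| |Y|), bounded in [0, 1].
The coherence of a retrieval set is the mean cosine over all unordered
pairs of a seeded random sample: a topically tighter set scores higher, so
two retrieval strategies can be compared by their means.

Conventions (fixed, documented): self-pairs are excluded (they would add a
constant 1 to every mean), and vocabularies are per-pair unions — cosine on
binary vectors is invariant to padding with shared zero columns, so this
equals the global-vocabulary value while staying O(pair) in memory.
Articles with no headings are excluded before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Article, Corpus
from .errors import DegenerateInputError

__all__ = [
    "BinaryTermVector",
    "CoherenceReport",
    "vectorize_pair",
    "cosine",
    "mean_pairwise_similarity",
]


@dataclass(frozen=True)
class BinaryTermVector:
    vocabulary: tuple[str, ...]
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(self.bits):
            raise ValueError("vocabulary and bits differ in length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")


@dataclass(frozen=True)
class CoherenceReport:
    sample_size: int
    seed: int
    mean_similarity: float
    pair_count: int
    excluded_no_heading: int = 0


def vectorize_pair(a: Article, b: Article) -> tuple[BinaryTermVector, BinaryTermVector]:
    """Indicator vectors for two articles over their shared union vocabulary."""
    ka, kb = a.heading_keys(), b.heading_keys()
    if not ka and not kb:
        raise DegenerateInputError(
            f"articles {a.pmid} and {b.pmid} both have no MeSH headings"
        )
    vocab = tuple(sorted(ka | kb))
    return (
        BinaryTermVector(vocab, tuple(int(t in ka) for t in vocab)),
        BinaryTermVector(vocab, tuple(int(t in kb) for t in vocab)),
    )


def cosine(x: BinaryTermVector, y: BinaryTermVector) -> float:
    """Cosine similarity of two indicator vectors over the same vocabulary."""
    if x.vocabulary != y.vocabulary:
        raise ValueError("vectors are over different vocabularies")
    xs, ys = sum(x.bits), sum(y.bits)
    if xs == 0 or ys == 0:
        raise DegenerateInputError("cosine undefined for a zero vector")
    dot = sum(xb * yb for xb, yb in zip(x.bits, y.bits))
    return dot / float(np.sqrt(xs * ys))


def mean_pairwise_similarity(corpus: Corpus, n: int, seed: int) -> CoherenceReport:
    """Mean pairwise cosine over a seeded sample of ``n`` indexed articles.

    Articles without headings are dropped first (their vectors would be
    undefined); the eligible list is put in canonical PMID order before
    sampling so the result does not depend on corpus ordering.  The mean
    runs over all n(n-1)/2 unordered pairs, computed with one Gram matrix —
    equal to the per-pair union-vocabulary construction because cosine
    ignores shared zero columns.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 articles, got {n}")
    eligible = sorted(
        (a for a in corpus if a.heading_keys()), key=lambda a: a.pmid
    )
    excluded = len(corpus) - len(eligible)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} articles with headings, cannot sample {n}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(eligible), size=n, replace=False)
    heading_sets = [eligible[i].heading_keys() for i in picks]

    vocab = sorted(set().union(*heading_sets))
    index = {t: j for j, t in enumerate(vocab)}
    X = np.zeros((n, len(vocab)))
    for i, keys in enumerate(heading_sets):
        for t in keys:
            X[i, index[t]] = 1.0
    norms = np.sqrt((X * X).sum(axis=1))
    gram = X @ X.T / np.outer(norms, norms)
    iu = np.triu_indices(n, k=1)
    mean = float(gram[iu].mean())
    return CoherenceReport(
        sample_size=n,
        seed=seed,
        mean_similarity=mean,
        pair_count=n * (n - 1) // 2,
        excluded_no_heading=excluded,
    )
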