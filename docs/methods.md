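# Methods

This note documents the models, conventions, and design choices behind
`meshkos`, in the spirit of a statistical package's methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## The vocabulary model

A MeSH descriptor is `(ui, name, tree_numbers, entry_terms)` with at least
one tree number. Tree numbers are dot-separated alphanumeric paths; the
parent of `A11.872.100` is `A11.872`, and a single-segment number has no
parent. The map tree-number → descriptor is a bijection onto the used
numbers (duplicates are integrity errors naming both descriptors), while a
descriptor may own several numbers — the poly-hierarchy that creates noisy
hyponyms.

All hierarchy operations reduce to prefix relations on tree numbers:

* `parents(t)` — owners of the parent number of each of t's numbers.
  A parent number not owned by any descriptor (possible in truncated
  fixture vocabularies) contributes nothing, as do top-level numbers.
* `explode(t)` — t plus every descriptor one of whose numbers prefix-extends
  *any* of t's numbers. Implemented as DFS over a child-number adjacency
  index; the test suite keeps an independent oracle that exhaustively scans
  every (descriptor, number) pair, and the two must agree exactly.
* `is_ancestor(a, b)` — strict: some number of b prefix-extends some number
  of a; `is_ancestor(x, x)` is false.

Name lookup is case-insensitive and whitespace-collapsed, and entry terms
(synonyms) resolve to their descriptor; entry terms shadowed by a preferred
name, or claimed by two descriptors, are kept on the descriptor but not
indexed for lookup (first-writer-wins would be order-dependent; dropping
ambiguous synonyms is not). MEDLINE heading strings are normalized by
stripping a leading `*` (major-topic marker) and everything from the first
`/` (qualifiers) before lookup: the workflow operates at descriptor level
and deliberately ignores qualifier and major-topic distinctions.

Two readers are provided: a subset of the official descriptor XML (UI,
name, tree numbers, entry terms; all other elements ignored, since nothing
else is used) and a TSV dialect
(`ui<TAB>name<TAB>tn;tn<TAB>entry|entry`) convenient for fixtures. Both
load to equal in-memory vocabularies for the same content.

## Corpus I/O

MEDLINE flat files are read through Biopython's `Medline` parser
(continuation lines joined with one space; MH/OT fields accumulate), with
validation on top: a record without PMID is a parse error naming the
record index; duplicate PMIDs are integrity errors. Writing emits a fixed
tag order (PMID, TI, AB, JT, DP, MH…, OT…) without line wrapping, so
read∘write is the identity on corpora whose field values are free of
newlines (newlines are collapsed to spaces on write — the flat format
cannot represent them). Sampling is uniform without replacement under a
`numpy` generator seeded by the caller, with survivor order preserved so a
`(corpus, n, seed)` triple always denotes the same sub-corpus.

## Term statistics

Counts are **document frequencies**: a term counts once per article whose
normalized, deduplicated heading set contains it. The alternative
(heading-token counting) would double-count qualifier variants of one
heading; per-article counting matches how indexing depth is usually quoted
(7–8 headings per article). Ranking ties break alphabetically for
determinism. Headings that fail to resolve are counted under their literal
normalized string and reported in `unresolved` rather than dropped.

`coverage_cutoff(table, m)` keeps terms with count ≥ m and reports the
fraction of total occurrences they carry; it is monotone in m, equals 1.0
at m = 1, and is defined as 1.0 on an empty table. Which terms are "too
general" is expert judgment, so exclusion is config-driven: a term list
file format plus two shipped example lists (check tags; molecular
entities). Automated detection of over-general terms is out of scope.

## Term selection

Expert labels live in TSV (`term<TAB>specific|related|other|excluded`);
conflicting duplicates are errors, consistent duplicates collapse. The two
structural rules:

* **Roots**: a specific-labeled term is a root iff none of its parents
  (via any tree number) is specific-labeled. "Parent no longer related to
  the domain" is judgment; encoding it as "parent not labeled specific"
  keeps the judgment in the label file and the tracing mechanical. The
  returned set is an antichain, and every specific term is
  descendant-or-self of some root (parent chains strictly shorten tree
  numbers, so tracing terminates).
* **Noisy hyponyms**: a non-root, non-specific descendant of a root is a
  candidate iff it owns a tree number none of whose prefixes is a root
  number — i.e. it is reachable outside the selected subtrees. Candidates
  are advisory; the final NOT-list is curated, because confirming that a
  multi-homed term really drags in foreign literature is a retrieval
  experiment, not a hierarchy fact.

## Queries and retrieval semantics

A `BooleanQuery` is ordered lists: vocabulary includes, free-text includes,
vocabulary excludes, plus explosion flags (default on for both). Includes
and excludes must be disjoint and duplicate-free. Serialization preserves
order and is byte-reproducible; the plain dialect is
`("T1" OR …) NOT ("X1" OR …)`, the tagged dialect adds `[MeSH Terms]` /
`[All Fields]`. The parser accepts the plain grammar (one optional
NOT-group) and classifies terms as vocabulary or free-text by lookup
against a supplied vocabulary; NOT binds last, i.e. semantics are
(∪ include matches) \ (∪ exclude matches).

`execute` matches a vocabulary term against an article iff the article's
normalized heading set intersects the term's explosion, and a free-text
term iff it occurs case-insensitively at token boundaries (`\w`
boundaries, no stemming) in title, abstract, or keywords. Token-boundary
matching is the simplest reproducible rule that stops a supplement like
"ipsc" from matching inside longer words; field scope is a parameter of
the corpus representation, defaulting to title+abstract+keywords.
Unresolvable include terms either raise (strict, default) or demote to
free-text (lenient). Consequences that are property-tested: retrieval is
monotone in includes, anti-monotone in excludes, NOT is exactly set
difference, and explosion equals manual expansion of the term lists.

## Evaluation protocols

Relevance and category judgments are *injected oracles* (TSV files or
callables), never computed — in the emulated workflow they are human
experts. Recall against a gold set is exact enumeration. Precision is
estimated the way manual review protocols do it: repeated seeded
100-article samples of the retrieval set, judged, averaged; each replicate
uses an independent stream derived from `(seed, replicate_index)` so any
single replicate is reproducible in isolation. Per-category recall draws
one seeded benchmark sample (default 300), assigns categories by oracle
(multi-membership allowed), and scores each category's query against its
benchmark members; a category with no members is `None` (undefined),
distinct from 0.

## Coherence statistic

Articles become 0/1 indicator vectors over MeSH terms; pair similarity is
the cosine, which for binary vectors is |X∩Y|/√(|X||Y|) ∈ [0, 1]. Set
coherence is the mean over all unordered pairs of a seeded n-article
sample. Fixed conventions: self-pairs are excluded (they would add a
constant to every mean); vocabularies are per-pair unions, which equals
the global-vocabulary value because cosine is invariant to shared zero
columns; articles without headings are excluded before sampling (their
vectors are undefined) and counted in the report; the eligible list is
sorted by PMID before sampling so corpus order is irrelevant. The fast
path computes one Gram matrix; tests require agreement with a naive
O(n²) double loop to 1e-12. The directional use — a single-topic set
should out-cohere a mixed set — is verified on the generator.

## Classified thesaurus

Categories are ordered term lists keyed by unique names; overlap across
categories is allowed and meaningful (an article may belong to several).
Membership: heading set intersects the union of exploded category terms;
with explosion off, exact match only (exploded membership ⊇ exact).
Upper-node propagation — "if a term is in a category, consider its
ancestors" — is emitted as suggestions only and never auto-merged: a few
steps up any MeSH chain sits something like "Anatomy", so the "if
possible" condition is inherently expert.

## The synthetic generator

The generator's defaults are the study conditions the package is tested
under, chosen once:

| parameter | default | meaning |
|---|---|---|
| `n_descriptors` | 120 | vocabulary size; two top-level subtrees grown evenly |
| `max_depth`, `branching` | 5, (2, 4) | hierarchy shape bounds (hard cap enforced) |
| `headings_per_article` | (7, 8) | indexing depth of research articles |
| `relevant_fraction` | 0.4 | fraction of articles about the planted topic |
| `p_topic_term` | 0.9 | per-heading probability a relevant article draws from the specific subtree |
| `p_noise_overlap` | 0.1 | probability an irrelevant article carries a planted multi-homed term |
| `n_multihomed` | 3 | planted noisy hyponyms (leaf descriptors given a second, outside tree number) |
| `p_heading_free` | 0.0 | fraction of relevant articles with no headings but a free-text marker |
| `p_qualifier`, `p_major_topic` | 0.2, 0.1 | MH-line decoration rates exercising normalization |

Design choices worth stating:

* **Noise terms are leaves, and relevant articles never draw them.** The
  real multi-homed offenders are terminal cell-line descriptors indexing
  routine laboratory literature; modeling them as leaves means exploding a
  NOT-term cannot swallow legitimate descendants, and keeping them out of
  the relevant topic pool reproduces the observed dynamic that exclusion
  buys precision at essentially zero recall cost. Both choices are about
  the *mechanism*, not about making any particular test pass: with
  mid-tree noise terms the NOT-exclusion semantics would be correct but
  the planted world would not resemble the phenomenon being modeled.
* **Relevant headings are drawn as a binomial split** (n_topic ~
  Binomial(k, p_topic_term), sampled without replacement from each pool),
  which gives the closed-form retrieval expectations implemented in
  `expected_query_rates`: recall of the exploded-root query is
  (1 − p_heading_free) · E_k[1 − (1 − p)^k], irrelevant pull-in is
  p_noise_overlap, and precision follows from the two. The form is valid
  while both pools exceed the indexing depth; the default sizes satisfy
  this comfortably, and the generator-level test checks observed rates
  against the closed form within 3 binomial standard errors.
* **Categories** are the immediate children of the specific root; ground
  truth assigns an article to every child subtree it draws a heading from.
* Everything is deterministic under `seed` (string-derived `random.Random`
  streams, separate for tree and corpus), and emitted corpora round-trip
  through the MEDLINE writer/reader unchanged.

What the generator does **not** emulate: natural-language titles and
abstracts (titles are templated, so free-text evaluation beyond the marker
phrase is out of reach), Zipfian heading popularity within a pool
(draws are uniform), indexing errors and inter-indexer inconsistency, and
citation or journal structure. Consequently, green tests demonstrate that
the machinery — hierarchy operations, query semantics, estimators,
statistics — is correct under a controlled generative model; they do not
certify retrieval quality on real PubMed corpora, which depends on
vocabulary curation and expert judgment the toolkit deliberately leaves
external.

## Problem sizes and numerical conventions

The test suite and acceptance script run at deliberately modest scale —
vocabularies of 40–300 descriptors, corpora of 200–2000 articles, 100-seed
oracle sweeps, 50-seed coherence comparisons — sizes at which every
statistic is checkable against full enumeration while the whole suite
stays fast. Comparisons of floating-point statistics use explicit
tolerances: 1e-12 where two exact computations must agree (Gram matrix vs
double loop), binomial 3σ bands where a sampled estimate approximates an
enumerated truth. Published headline figures from any specific real-world
corpus (overall recall/precision of a particular curated thesaurus, hit
counts on a live index, similarity means of particular retrieval sets) are
functions of that corpus, a live search index, and human judges, and are
therefore not reproduction targets for the offline toolkit; what is
reproduced is every in-text worked computation (the cosine example, the
query string) and the qualitative dynamics of the protocols.

## Known limitations

* The MEDLINE writer does not wrap long lines (readers accept this; byte
  identity with PubMed exports is not attempted).
* Supplementary concept records, the qualifier hierarchy, and MeSH
  year-over-year evolution are out of scope.
* The query grammar covers the published OR/NOT shape, not full PubMed
  syntax (no AND trees, date ranges, or proximity operators).
* Boolean retrieval only: no ranking, scoring, or relevance feedback.
* Entry-term resolution is available but optional in spirit: real label
  files may or may not have used synonym matching, so nothing in the
  selection logic depends on it.
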