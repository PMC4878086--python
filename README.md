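# meshkos

Reengineer MeSH (Medical Subject Headings) into a domain-specific retrieval
thesaurus — and measure how well it works.

PubMed indexes every article with MeSH descriptors arranged in a
poly-hierarchy of dot-separated *tree numbers* (`A11.872`, `A11.872.100`,
…). Searching a descriptor "explodes" it to all of its hyponyms, which is
both the power and the trap of MeSH retrieval: an interdisciplinary field
such as stem cell research is scattered across many subtrees, and some
hyponyms are *multi-homed* — a cell line like "K562 Cells" sits under
progenitor cells **and** under routine laboratory cell lines, dragging
irrelevant literature into every exploded stem-cell query.

`meshkos` implements the full workflow for building and validating a
curated retrieval thesaurus from an annotated corpus, aimed at information
specialists, librarians, and text-mining researchers:

1. **Harvest** — parse MEDLINE flat files, count per-article (document)
   frequencies of the indexed MeSH terms, apply a frequency cutoff and
   measure its occurrence coverage (`termstats`).
2. **Filter** — remove over-general check tags (Humans, Animals, Cell
   Line…) and substance-level headings via declarative exclusion lists
   (`termstats`, shipped example lists under `meshkos/data/`).
3. **Select** — ingest expert labels (specific / related / other /
   excluded), trace each specific term up the hierarchy until its parent is
   no longer specific to obtain the *root* terms, and detect multi-homed
   *noisy hyponyms* as NOT-exclusion candidates (`selection`).
4. **Query** — assemble boolean queries: OR-set of exploded roots plus
   free-text supplements, minus a NOT-set; byte-reproducible serialization
   to PubMed-style syntax and a parser for the same dialect (`query`).
5. **Evaluate** — execute queries against a local corpus (explosion +
   token-boundary free-text matching) and estimate recall exactly and
   precision by repeated seeded 100-article samples judged by an injected
   relevance oracle (`evaluate`).
6. **Validate** — compare retrieval strategies by topical coherence: the
   mean pairwise cosine of binary MeSH indicator vectors,

   cos(x, y) = Σₜ x(t)·y(t) / √(Σₜ x(t)² · Σₜ y(t)²),

   over a seeded sample of the retrieval set (`coherence`).
7. **Classify** — bucket retrieved literature with a category-keyed
   classified thesaurus (category → MeSH term list, exploded, crossed
   categories allowed), with upper-node curation suggestions (`classify`).
8. **Simulate** — generate miniature vocabularies and corpora with planted
   relevance, multi-homed noise, and unindexed articles, with exact ground
   truth (`simulate`), so every protocol above is testable offline.

## Worked example

Generate a synthetic world (120 descriptors, 400 articles, 40% relevant,
15% noise-overlap, 10% of relevant articles unindexed), then refine a query
in three steps:

```sh
meshkos simulate --seed 7 --n-articles 400 --p-noise-overlap 0.15 \
    --p-heading-free 0.1 --out-dir demo
meshkos evaluate --mesh demo/mesh.tsv --corpus demo/corpus.medline \
    --judgments demo/relevance.tsv --seed 0 --query '("Stem Cells")'
```

Running `evaluate` for the three refinement stages prints:

| query | retrieved | recall | precision (3×100 samples) |
|---|---|---|---|
| `("Stem Cells")` | 172 | 0.8625 | 0.79 |
| `("Stem Cells") NOT (…3 noisy terms…)` | 138 | 0.8625 | 1.00 |
| `("Stem Cells" OR "stemness") NOT (…)` | 160 | 1.0000 | 1.00 |

The NOT-exclusion of the three planted multi-homed terms removes the 34
irrelevant articles that only entered through them (precision 0.79 → 1.00)
while recall is untouched; the free-text supplement `"stemness"` rescues
the relevant articles that carry no MeSH indexing at all (recall 0.8625 →
1.00). This is exactly the dynamic the toolkit is built to measure on real
corpora.

Coherence comparison of the same world:

```sh
meshkos coherence --corpus demo/corpus.medline --n 100 --seed 0
# "mean_similarity": 0.0661  (mixed sample; the relevant-only subset scores ~0.15)
```

A topically tight retrieval set scores a higher mean pairwise cosine than a
mixed one, which is the statistic used to compare two search strategies.

The shipped example configuration
`meshkos/data/stem_cell_thesaurus.yaml` contains a published stem-cell
retrieval thesaurus (15 MeSH roots, 5 free-text supplements, 3 noisy-hyponym
exclusions); `build_query` + `serialize` reproduce its published query
string byte-for-byte, and `parse` round-trips it.

## Query dialects

`plain` (default): `("T1" OR "T2" …) NOT ("X1" OR …)` — every term
double-quoted, single spaces, includes before the single NOT-group, order
preserved. `pubmed_tagged`: same shape with `[MeSH Terms]` / `[All Fields]`
suffixes for real PubMed sessions. One query per line in query files.

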