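"""Query execution semantics and the sampling evaluation protocols."""

import io

import numpy as np
import pytest

from meshkos import (
    BooleanQuery,
    Corpus,
    GeneratorSpec,
    UnknownTermError,
    build_query,
    category_recall,
    execute,
    generate_corpus,
    generate_tree,
    load_judgments,
    precision_by_sampling,
    recall_vs_gold,
)

from conftest import make_article


@pytest.fixture(scope="module")
def synthetic():
    spec = GeneratorSpec(seed=11, n_descriptors=100, n_articles=600,
                         relevant_fraction=0.4, p_noise_overlap=0.1)
    tree = generate_tree(spec)
    corpus, truth = generate_corpus(spec, tree)
    return spec, tree, corpus, truth


class TestExecute:
    def test_hyponym_match_freetext_rescue_and_not_exclusion(
        self, tiny_tree, three_article_corpus
    ):
        q = build_query(["Stem Cells"], freetext=["ips cell"], exclusions=["K562 Cells"])
        got = execute(three_article_corpus, tiny_tree, q).retrieved_pmids
        assert got == {"a1", "a3"}

    def test_empty_corpus(self, tiny_tree):
        q = build_query(["Stem Cells"])
        assert execute(Corpus([]), tiny_tree, q).retrieved_pmids == frozenset()

    def test_freetext_is_token_boundary(self, tiny_tree):
        corpus = Corpus([
            make_article(1, abstract="an ipsc line"),
            make_article(2, abstract="eclipscope artifacts"),
        ])
        q = BooleanQuery(include_freetext=("ipsc",))
        assert execute(corpus, tiny_tree, q).retrieved_pmids == {"1"}

    def test_freetext_is_case_insensitive_over_title_abstract_keywords(self, tiny_tree):
        corpus = Corpus([
            make_article(1, title="IPSC derivation"),
            make_article(2, keywords=["iPSC"]),
            make_article(3, abstract="unrelated"),
        ])
        q = BooleanQuery(include_freetext=("ipsc",))
        assert execute(corpus, tiny_tree, q).retrieved_pmids == {"1", "2"}

    def test_not_is_set_difference(self, synthetic):
        spec, tree, corpus, _ = synthetic
        names = sorted(d.name for d in tree)
        inc, exc = names[:5], names[5:8]
        with_not = execute(corpus, tree, build_query(inc, exclusions=exc))
        plain = execute(corpus, tree, build_query(inc))
        as_includes = execute(corpus, tree, build_query(exc))
        assert with_not.retrieved_pmids == (
            plain.retrieved_pmids - as_includes.retrieved_pmids
        )

    def test_monotone_in_includes_antimonotone_in_excludes(self, synthetic):
        spec, tree, corpus, _ = synthetic
        names = sorted(d.name for d in tree)
        base = execute(corpus, tree, build_query(names[:3])).retrieved_pmids
        grown = execute(corpus, tree, build_query(names[:6])).retrieved_pmids
        assert base <= grown
        shrunk = execute(
            corpus, tree, build_query(names[:3], exclusions=names[10:13])
        ).retrieved_pmids
        assert shrunk <= base

    def test_explosion_equals_manual_expansion(self, synthetic):
        spec, tree, corpus, _ = synthetic
        root = spec.specific_subtree_root
        exploded = execute(corpus, tree, build_query([root]))
        manual = execute(
            corpus,
            tree,
            BooleanQuery(
                include_mesh=tuple(sorted(tree.explode(root))), explode_includes=False
            ),
        )
        assert exploded.retrieved_pmids == manual.retrieved_pmids

    def test_unresolvable_include_strict_raises_lenient_demotes(self, tiny_tree):
        corpus = Corpus([make_article(1, abstract="organoid data")])
        q = build_query(["organoid"])
        with pytest.raises(UnknownTermError):
            execute(corpus, tiny_tree, q)
        got = execute(corpus, tiny_tree, q, on_unresolved="lenient")
        assert got.retrieved_pmids == {"1"}


class TestRecall:
    def test_arithmetic(self, tiny_tree, three_article_corpus):
        res = execute(three_article_corpus, tiny_tree, build_query(["Stem Cells"]))
        assert recall_vs_gold(res, {"a1", "a2"}) == 1.0
        assert recall_vs_gold(res, {"a1", "a3"}) == 0.5
        assert recall_vs_gold(res, {"a3"}) == 0.0

    def test_empty_gold_rejected(self, tiny_tree, three_article_corpus):
        res = execute(three_article_corpus, tiny_tree, build_query(["Stem Cells"]))
        with pytest.raises(ValueError):
            recall_vs_gold(res, set())


class TestPrecisionSampling:
    def test_all_relevant_judge_gives_one(self, synthetic):
        spec, tree, corpus, _ = synthetic
        res = execute(corpus, tree, build_query([spec.specific_subtree_root]))
        rep = precision_by_sampling(res, lambda p: True, 50, 3, seed=0)
        assert rep.replicate_values == (1.0, 1.0, 1.0) and rep.mean == 1.0

    def test_replicates_reproducible_under_seed(self, synthetic):
        spec, tree, corpus, truth = synthetic
        res = execute(corpus, tree, build_query([spec.specific_subtree_root]))
        judge = {p: p in truth.relevant_pmids for p in res.retrieved_pmids}
        a = precision_by_sampling(res, judge, 50, 5, seed=7)
        b = precision_by_sampling(res, judge, 50, 5, seed=7)
        assert a == b
        c = precision_by_sampling(res, judge, 50, 5, seed=8)
        assert a.replicate_values != c.replicate_values

    def test_sample_mean_recovers_enumerated_precision(self, synthetic):
        """Mean over many 100-article replicates must sit within 3 binomial
        standard errors of the exact relevant fraction of the retrieval set."""
        spec, tree, corpus, truth = synthetic
        res = execute(corpus, tree, build_query([spec.specific_subtree_root]))
        exact = len(res.retrieved_pmids & truth.relevant_pmids) / len(res.retrieved_pmids)
        judge = {p: p in truth.relevant_pmids for p in res.retrieved_pmids}
        rep = precision_by_sampling(res, judge, sample_size=100, replicates=200, seed=3)
        se = np.sqrt(exact * (1 - exact) / (100 * 200))
        assert abs(rep.mean - exact) <= 3 * se

    def test_oversized_sample_and_missing_judgment_rejected(self, synthetic):
        spec, tree, corpus, _ = synthetic
        res = execute(corpus, tree, build_query([spec.specific_subtree_root]))
        with pytest.raises(ValueError):
            precision_by_sampling(res, lambda p: True, len(res.retrieved_pmids) + 1)
        with pytest.raises(ValueError, match="missing"):
            precision_by_sampling(res, {}, 10)


class TestCategoryRecall:
    def test_recall_per_category_against_benchmark(self, synthetic):
        spec, tree, corpus, truth = synthetic
        cats = sorted({c for cs in truth.category_assignments.values() for c in cs})
        queries = {c: build_query([c]) for c in cats}
        got = category_recall(
            corpus, tree, queries, truth.category_assignments, bench_size=300, seed=5
        )
        # independent enumeration of the same protocol
        from meshkos import sample_articles

        bench = sample_articles(corpus, 300, seed=5)
        for c in cats:
            members = {
                a.pmid for a in bench if c in truth.category_assignments[a.pmid]
            }
            if not members:
                assert got[c] is None
                continue
            retrieved = execute(corpus, tree, queries[c]).retrieved_pmids
            assert got[c] == pytest.approx(len(members & retrieved) / len(members))
            assert 0.0 <= got[c] <= 1.0

    def test_query_retrieving_everything_scores_one(self, tiny_tree):
        corpus = Corpus([make_article(i, headings=["Stem Cells"]) for i in range(10)])
        judge = {str(i): {"cat"} for i in range(10)}
        got = category_recall(
            corpus, tiny_tree, {"cat": build_query(["Stem Cells"])}, judge,
            bench_size=10, seed=0,
        )
        assert got == {"cat": 1.0}

    def test_category_absent_from_benchmark_is_undefined(self, tiny_tree):
        corpus = Corpus([make_article(i, headings=["Stem Cells"]) for i in range(10)])
        judge = {str(i): set() for i in range(10)}
        got = category_recall(
            corpus, tiny_tree, {"ghost": build_query(["Stem Cells"])}, judge,
            bench_size=10, seed=0,
        )
        assert got == {"ghost": None}


def test_judgment_tsv_round_trip(tmp_path):
    path = tmp_path / "judgments.tsv"
    path.write_text("1\t1\n2\t0\n# comment\n3\t1\n")
    assert load_judgments(path) == {"1": True, "2": False, "3": True}
    with pytest.raises(ValueError, match="line 1"):
        load_judgments(io.StringIO("1\tmaybe\n"))
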