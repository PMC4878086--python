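"""Shared fixtures: a hand-built vocabulary mirroring the multi-homed
cell-line situation, and helpers for constructing articles."""

import io

import pytest
from hypothesis import HealthCheck, settings

from meshkos import Article, Corpus, load_mesh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# A miniature vocabulary: "K562 Cells" sits both under the stem-cell subtree
# (A11.872) and under the cultured-cell-line subtree (A11.251) — the
# multi-homing that makes it a noisy hyponym of any exploded stem-cell
# search.  A second, disjoint branch (cardiovascular) supports the
# classification tests.
FIXTURE_TSV = """\
D000001\tStem Cells\tA11.872\tmother cells|colony-forming unit
D000002\tAdult Stem Cells\tA11.872.100
D000003\tK562 Cells\tA11.872.200;A11.251.210.500
D000004\tCell Lines\tA11.251
D000005\tTumor Cell Lines\tA11.251.210
D000006\tHematopoiesis\tG09.188
D000007\tCardiovascular System\tA07
D000008\tCardiovascular Diseases\tC14
D000009\tHeart Failure\tC14.280
D000010\tDiagnostic Techniques, Cardiovascular\tE01.370.370
D000011\tCardiovascular Physiological Phenomena\tG09.330
"""


@pytest.fixture(scope="session")
def tiny_tree():
    return load_mesh(io.StringIO(FIXTURE_TSV), dialect="tsv")


def make_article(pmid, headings=(), title="", abstract="", keywords=()):
    return Article(
        pmid=str(pmid),
        title=title,
        abstract=abstract,
        mesh_headings=list(headings),
        keywords=list(keywords),
    )


@pytest.fixture
def three_article_corpus():
    """The retrieval hand-example: one hyponym hit, one noisy-term article,
    one unindexed article rescued only by free text."""
    return Corpus(
        [
            make_article("a1", headings=["Adult Stem Cells"]),
            make_article("a2", headings=["K562 Cells"]),
            make_article("a3", abstract="Derived from an ips cell clone."),
        ]
    )
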