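"""Vocabulary model: loading, lookup normalization, and hierarchy traversal
checked against an independent brute-force prefix-reachability oracle."""

import io

import pytest

from meshkos import (
    GeneratorSpec,
    IntegrityError,
    MeshTree,
    ParseError,
    UnknownTermError,
    dump_mesh_tsv,
    generate_tree,
    load_mesh,
    normalize_heading,
)

from conftest import FIXTURE_TSV


def explode_oracle(tree, term):
    """Exhaustive prefix scan over every tree number of every descriptor."""
    d = tree.get(term)
    out = {d.name}
    for other in tree:
        for tn in other.tree_numbers:
            if any(tn == t or tn.startswith(t + ".") for t in d.tree_numbers):
                out.add(other.name)
    return out


def is_ancestor_oracle(tree, a, b):
    da, db = tree.get(a), tree.get(b)
    return any(
        tb.startswith(ta + ".") for tb in db.tree_numbers for ta in da.tree_numbers
    )


class TestLoading:
    def test_tsv_fixture_loads_descriptors_and_tree_numbers(self, tiny_tree):
        assert len(tiny_tree) == 11
        assert tiny_tree.get("Stem Cells").ui == "D000001"
        assert tiny_tree.get("K562 Cells").tree_numbers == {
            "A11.872.200",
            "A11.251.210.500",
        }

    def test_empty_stream_is_a_valid_empty_vocabulary(self):
        tree = load_mesh(io.StringIO(""), dialect="tsv")
        assert len(tree) == 0

    def test_duplicate_tree_number_names_both_descriptors(self):
        bad = "D1\tStem Cells\tA11.872\nD2\tOther Cells\tA11.872\n"
        with pytest.raises(IntegrityError, match="A11.872") as exc:
            load_mesh(io.StringIO(bad))
        assert "D1" in str(exc.value) and "D2" in str(exc.value)

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            load_mesh(io.StringIO("D1\tStem Cells\tA11.872\nonly-one-column\n"))

    def test_duplicate_name_rejected_case_insensitively(self):
        bad = "D1\tStem Cells\tA11.872\nD2\tSTEM  cells\tB01\n"
        with pytest.raises(IntegrityError, match="duplicate descriptor name"):
            load_mesh(io.StringIO(bad))

    def test_xml_and_tsv_encodings_load_equal_trees(self, tiny_tree):
        records = []
        for d in sorted(tiny_tree, key=lambda d: d.ui):
            tns = "".join(f"<TreeNumber>{t}</TreeNumber>" for t in sorted(d.tree_numbers))
            terms = "".join(
                f"<Term><String>{t}</String></Term>" for t in sorted(d.entry_terms)
            )
            records.append(
                f"<DescriptorRecord><DescriptorUI>{d.ui}</DescriptorUI>"
                f"<DescriptorName><String>{d.name}</String></DescriptorName>"
                f"<TreeNumberList>{tns}</TreeNumberList>"
                f"<ConceptList><Concept><TermList>"
                f"<Term><String>{d.name}</String></Term>{terms}"
                f"</TermList></Concept></ConceptList></DescriptorRecord>"
            )
        xml = "<DescriptorRecordSet>" + "".join(records) + "</DescriptorRecordSet>"
        assert load_mesh(io.StringIO(xml), dialect="xml") == tiny_tree

    def test_tsv_dump_round_trips(self, tiny_tree):
        buf = io.StringIO()
        dump_mesh_tsv(tiny_tree, buf)
        buf.seek(0)
        assert load_mesh(buf, dialect="tsv") == tiny_tree


class TestLookup:
    def test_name_lookup_is_case_and_whitespace_insensitive(self, tiny_tree):
        assert tiny_tree.get("  stem   CELLS ").ui == "D000001"

    def test_entry_terms_resolve_to_their_descriptor(self, tiny_tree):
        assert tiny_tree.resolve("Mother Cells") == "Stem Cells"

    def test_unknown_term_raises(self, tiny_tree):
        with pytest.raises(UnknownTermError):
            tiny_tree.get("Quantum Cells")

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("*Stem Cells/metabolism", "Stem Cells"),
            ("Stem Cells/metabolism/genetics", "Stem Cells"),
            ("Stem  Cells", "Stem Cells"),
        ],
    )
    def test_heading_normalization_strips_medline_decorations(self, raw, expected):
        assert normalize_heading(raw) == expected


class TestHierarchy:
    def test_parents_follow_every_tree_number(self, tiny_tree):
        assert tiny_tree.parents("Adult Stem Cells") == {"Stem Cells"}
        assert tiny_tree.parents("Stem Cells") == set()
        assert tiny_tree.parents("K562 Cells") == {"Stem Cells", "Tumor Cell Lines"}

    def test_explode_covers_all_subtrees_of_the_term(self, tiny_tree):
        assert tiny_tree.explode("Stem Cells") == {
            "Stem Cells",
            "Adult Stem Cells",
            "K562 Cells",
        }
        assert tiny_tree.explode("Cell Lines") == {
            "Cell Lines",
            "Tumor Cell Lines",
            "K562 Cells",
        }

    def test_explode_of_a_leaf_is_itself(self, tiny_tree):
        assert tiny_tree.explode("Heart Failure") == {"Heart Failure"}

    def test_ancestry_is_strict(self, tiny_tree):
        assert tiny_tree.is_ancestor("Stem Cells", "K562 Cells")
        assert tiny_tree.is_ancestor("Cell Lines", "K562 Cells")
        assert not tiny_tree.is_ancestor("K562 Cells", "K562 Cells")
        assert not tiny_tree.is_ancestor("K562 Cells", "Stem Cells")


class TestHierarchyProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_explode_matches_brute_force_oracle_on_random_trees(self, seed):
        tree = generate_tree(GeneratorSpec(seed=seed, n_descriptors=80, n_multihomed=4))
        for d in tree:
            assert tree.explode(d.name) == explode_oracle(tree, d.name)

    @pytest.mark.parametrize("seed", range(5))
    def test_ancestry_agrees_with_explosion(self, seed):
        tree = generate_tree(GeneratorSpec(seed=seed, n_descriptors=40, n_multihomed=2))
        names = [d.name for d in tree]
        for a in names:
            ex = tree.explode(a)
            for b in names:
                assert tree.is_ancestor(a, b) == (b in ex and b != a)
                assert tree.is_ancestor(a, b) == is_ancestor_oracle(tree, a, b)

    def test_explode_is_monotone(self):
        tree = generate_tree(GeneratorSpec(seed=7, n_descriptors=60, n_multihomed=3))
        for d in tree:
            ex = tree.explode(d.name)
            assert d.name in ex and len(ex) >= 1
            for b in ex:
                assert tree.explode(b) <= ex
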