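import string

import pytest
from hypothesis import given, settings, strategies as st

from sigpca.ontology import (
    GeneSetCollection,
    Ontology,
    OntologyError,
    OntologyTerm,
    build_gene_set_collection,
    collapse_identical_parents,
    filter_by_size,
    parse_gaf,
    parse_obo,
    propagate,
    read_gene_sets,
    related_terms,
    write_gene_sets,
)


class TestParseObo:
    def test_terms_edges_and_alt_ids(self, tiny_obo):
        onto = parse_obo(tiny_obo)
        assert "GO:0000001" in onto
        assert onto.terms["GO:0000001"].is_a_parents == ["GO:0000002"]
        assert onto.resolve("GO:0000099") == "GO:0000001"

    def test_obsolete_terms_excluded(self, tiny_obo):
        onto = parse_obo(tiny_obo)
        assert "GO:0000003" not in onto
        assert len(onto) == 6

    def test_single_term_minimal_file(self, tmp_path):
        p = tmp_path / "one.obo"
        p.write_text("format-version: 1.2\n\n[Term]\nid: GO:1\nname: only\n"
                     "namespace: biological_process\n")
        assert len(parse_obo(p)) == 1

    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            Ontology({
                "A": OntologyTerm("A", "a", "biological_process", ["B"]),
                "B": OntologyTerm("B", "b", "biological_process", ["A"]),
            })


class TestParseGaf:
    def test_evidence_qualifier_and_dedup(self, tiny_gaf):
        anns = parse_gaf(tiny_gaf)
        genes = [g for g, _, _ in anns]
        # duplicate HBB collapses; IEA and NOT rows dropped
        assert genes == ["HBB", "CA1", "RHAG"]

    def test_custom_evidence_filter(self, tiny_gaf):
        anns = parse_gaf(tiny_gaf, allowed_evidence={"IEA"})
        assert [g for g, _, _ in anns] == ["HBA1"]

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gaf"
        p.write_text("!gaf-version: 2.1\nUniProtKB\tP1\tHBB\tGO:1\n")
        with pytest.raises(OntologyError, match=r":2:"):
            parse_gaf(p)


class TestPropagate:
    def test_child_annotation_reaches_parent(self, chain_ontology):
        sets = propagate(chain_ontology, [("g1", "B", "IDA")])
        assert sets["A"] == {"g1"} and sets["B"] == {"g1"}

    def test_chain_transitivity(self, chain_ontology):
        sets = propagate(chain_ontology, [("g1", "C", "IDA")])
        assert sets["A"] == sets["B"] == sets["C"] == {"g1"}

    def test_part_of_only_in_cellular_component(self, tiny_obo):
        onto = parse_obo(tiny_obo)
        sets = propagate(onto, [
            ("gcc", "GO:0000010", "IDA"),  # CC: part_of propagates
            ("gbp", "GO:0000020", "IDA"),  # BP: part_of ignored
        ])
        assert sets["GO:0000011"] == {"gcc"}
        assert "GO:0000021" not in sets

    def test_unknown_term_skipped(self, chain_ontology):
        sets = propagate(chain_ontology, [("g1", "NOPE", "IDA"),
                                          ("g2", "A", "IDA")])
        assert sets == {"A": {"g2"}}

    def test_alt_id_resolution(self, tiny_obo):
        onto = parse_obo(tiny_obo)
        sets = propagate(onto, [("g1", "GO:0000099", "IDA")])
        assert sets["GO:0000001"] == {"g1"}

    def test_monotone_supersets(self, diamond_ontology):
        anns = [(f"g{i}", t, "IDA")
                for i, t in enumerate(["D", "D", "P1", "P2", "R"])]
        sets = propagate(diamond_ontology, anns)
        for term in sets:
            for desc in diamond_ontology.descendants(term):
                if desc in sets:
                    assert sets[term] >= sets[desc]


class TestFilterBySize:
    @pytest.mark.parametrize("size,kept", [(4, False), (5, True),
                                           (200, True), (201, False)])
    def test_inclusive_window(self, size, kept):
        sets = {"T": {f"g{i}" for i in range(size)}}
        out = filter_by_size(sets, {"T": ("t", "biological_process")}, 5, 200)
        assert ("T" in out.sets) == kept

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            filter_by_size({}, {}, 0, 10)


class TestCollapseIdenticalParents:
    def _collection(self, sets):
        return GeneSetCollection(
            sets={k: frozenset(v) for k, v in sets.items()},
            term_meta={k: (k, "biological_process") for k in sets},
        )

    def test_identical_direct_parent_removed(self, chain_ontology):
        genes = {f"g{i}" for i in range(15)}
        coll = self._collection({"B": genes, "C": genes})
        out = collapse_identical_parents(coll, chain_ontology)
        assert "B" not in out.sets and "C" in out.sets

    def test_differing_sets_both_kept(self, chain_ontology):
        coll = self._collection({"B": {"g1", "g2"}, "C": {"g1"}})
        out = collapse_identical_parents(coll, chain_ontology)
        assert set(out.sets) == {"B", "C"}

    def test_chain_equality_propagates_through_identical_intermediate(
        self, chain_ontology
    ):
        # A == B == C: B removed (child C identical), A removed (child B
        # identical).  The comparison is per direct edge, so equality
        # propagates up exactly when every intermediate matches.
        genes = frozenset({"g1", "g2", "g3"})
        coll = self._collection({"A": genes, "B": genes, "C": genes})
        out = collapse_identical_parents(coll, chain_ontology)
        assert set(out.sets) == {"C"}

    def test_grandparent_not_removed_without_identical_intermediate(
        self, chain_ontology
    ):
        genes = frozenset({"g1", "g2", "g3"})
        coll = self._collection({"A": genes, "B": genes | {"g4"}, "C": genes})
        out = collapse_identical_parents(coll, chain_ontology)
        # A equals C but is not its direct parent, and B (its direct child)
        # differs -> A stays
        assert set(out.sets) == {"A", "B", "C"}

    def test_surviving_sets_unchanged(self, chain_ontology):
        genes = frozenset({"g1", "g2"})
        coll = self._collection({"B": genes, "C": genes, "A": {"g1"}})
        out = collapse_identical_parents(coll, chain_ontology)
        for t in out.sets:
            assert out.sets[t] == coll.sets[t]


class TestRelatedTerms:
    def test_isolated_term_empty(self, chain_ontology):
        assert related_terms(chain_ontology, "X") == set()

    def test_chain_middle(self, chain_ontology):
        assert related_terms(chain_ontology, "B") == {"A", "C"}

    def test_diamond_counts_each_ancestor_once(self, diamond_ontology):
        assert related_terms(diamond_ontology, "D") == {"P1", "P2", "R"}

    def test_symmetry(self, diamond_ontology):
        for a in diamond_ontology.terms:
            for b in related_terms(diamond_ontology, a):
                assert a in related_terms(diamond_ontology, b)

    def test_unknown_term_errors(self, chain_ontology):
        with pytest.raises(KeyError):
            related_terms(chain_ontology, "NOPE")


class TestGeneSetFile:
    def test_empty_collection_round_trips(self, tmp_path):
        coll = GeneSetCollection(sets={}, term_meta={})
        path = tmp_path / "gs.tsv"
        write_gene_sets(coll, path)
        assert read_gene_sets(path).sets == {}

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"T1": frozenset({"a", "b"}), "T2": frozenset({"c"})},
            term_meta={"T1": ("one", "biological_process"),
                       "T2": ("two", "cellular_component")},
        )
        path = tmp_path / "gs.tsv"
        write_gene_sets(coll, path)
        back = read_gene_sets(path)
        assert back.sets == coll.sets and back.term_meta == coll.term_meta

    def test_hand_edited_custom_set_loads(self, tmp_path):
        path = tmp_path / "custom.tsv"
        path.write_text("id\tname\tnamespace\tgenes\n"
                        "MYSET1\tmy favourite genes\tcustom\tTP53,MYC,EGFR\n")
        coll = read_gene_sets(path)
        assert coll.sets["MYSET1"] == {"TP53", "MYC", "EGFR"}
        assert coll.term_meta["MYSET1"] == ("my favourite genes", "custom")

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\tname\tnamespace\tgenes\n"
                        "T\tx\tcustom\ta\nT\ty\tcustom\tb\n")
        with pytest.raises(OntologyError, match="duplicate"):
            read_gene_sets(path)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.dictionaries(
        st.text(alphabet=string.ascii_uppercase + string.digits,
                min_size=1, max_size=8),
        st.frozensets(st.text(alphabet=string.ascii_letters + string.digits,
                              min_size=1, max_size=6),
                      min_size=1, max_size=10),
        max_size=8,
    ))
    def test_round_trip_property(self, tmp_path_factory, sets):
        coll = GeneSetCollection(
            sets=sets, term_meta={t: (f"name {t}", "custom") for t in sets},
        )
        path = tmp_path_factory.mktemp("gs") / "gs.tsv"
        write_gene_sets(coll, path)
        back = read_gene_sets(path)
        assert back.sets == coll.sets and back.term_meta == coll.term_meta


def test_full_chain_obo_gaf_to_collection(tiny_obo, tiny_gaf):
    onto = parse_obo(tiny_obo)
    anns = parse_gaf(tiny_gaf)
    coll = build_gene_set_collection(onto, anns, min_genes=1, max_genes=200)
    # HBB and RHAG (via alt_id) on the child term, CA1 directly on the parent
    assert coll.sets["GO:0000001"] == {"HBB", "RHAG"}
    assert coll.sets["GO:0000002"] == {"HBB", "RHAG", "CA1"}
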