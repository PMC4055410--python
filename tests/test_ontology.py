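"""Ontology parsing, annotation I/O, propagation and matrix construction."""

from __future__ import annotations

import numpy as np
import pytest

from negsel.ontology import (
    AnnotationSet,
    OboParseError,
    OntologyStructureError,
    annotated_direct_descendants,
    build_matrix,
    parse_annotations,
    parse_obo,
    propagate,
    propagate_negatives_down,
    write_annotations,
)

from conftest import B1, B2, B3, B4, C1, M1, M2, R1, R2, R3, random_annotations, random_layered_dag

MINI_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child one
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: child two
namespace: biological_process
relationship: part_of GO:0000001 ! root
"""


class TestParseObo:
    def test_minimal_file_loads_terms_and_edges(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(MINI_OBO)
        ont = parse_obo(p)
        assert len(ont.terms) == 3
        assert len(ont.edges) == 2
        assert ont.roots == {"BP": "GO:0000001"}
        assert ont.parents("GO:0000003") == {"GO:0000001"}

    def test_obsolete_terms_are_dropped(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            MINI_OBO
            + "\n[Term]\nid: GO:0000004\nname: gone\nnamespace: biological_process\n"
            "is_a: GO:0000001\nis_obsolete: true\n"
        )
        ont = parse_obo(p)
        assert "GO:0000004" not in ont.terms

    def test_cycle_raises_structural_error(self, tmp_path):
        p = tmp_path / "cycle.obo"
        p.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nnamespace: biological_process\n"
            "is_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nnamespace: biological_process\n"
            "is_a: GO:0000001\n"
        )
        with pytest.raises(OntologyStructureError):
            parse_obo(p)

    def test_malformed_stanza_names_the_line(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text("format-version: 1.2\n\n[Term]\nid: GO:0000001\nnonsense line\n")
        with pytest.raises(OboParseError, match="line 5"):
            parse_obo(p)

    def test_unknown_relations_are_dropped(self, tmp_path):
        p = tmp_path / "reg.obo"
        p.write_text(
            MINI_OBO + "\n[Term]\nid: GO:0000005\nnamespace: biological_process\n"
            "is_a: GO:0000001\nrelationship: regulates GO:0000002 ! dropped\n"
        )
        ont = parse_obo(p)
        assert ont.parents("GO:0000005") == {"GO:0000001"}


class TestParseAnnotations:
    def test_tsv_duplicates_collapse(self, tmp_path, toy_ontology):
        p = tmp_path / "a.tsv"
        p.write_text(f"Ga\t{B3}\tEXP\nGa\t{B3}\tEXP\nGb\t{B4}\tIEA\n")
        ann = parse_annotations(p, toy_ontology, format="tsv")
        assert len(ann.records) == 2

    def test_gaf_not_qualifier_excluded_and_iea_preserved(self, tmp_path, toy_ontology):
        gaf = (
            "!gaf-version: 2.1\n"
            f"DB\tID1\tGa\t\t{B3}\tREF\tEXP\t\tP\t\t\tprotein\ttaxon:9606\t2020\tDB\n"
            f"DB\tID2\tGb\tNOT\t{B3}\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t2020\tDB\n"
            f"DB\tID3\tGc\t\t{B4}\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t2020\tDB\n"
        )
        p = tmp_path / "a.gaf"
        p.write_text(gaf)
        ann = parse_annotations(p, toy_ontology, format="gaf")
        assert ("Ga", B3, "EXP") in ann.records
        assert all(g != "Gb" for g, _, _ in ann.records)  # NOT row excluded
        assert ("Gc", B4, "IEA") in ann.records  # IEA kept, code verbatim

    def test_unknown_terms_skipped_with_warning(self, tmp_path, toy_ontology):
        p = tmp_path / "a.tsv"
        p.write_text(f"Ga\t{B3}\tEXP\nGb\tGO:9999999\tEXP\n")
        with pytest.warns(UserWarning, match="skipped 1"):
            ann = parse_annotations(p, toy_ontology)
        assert len(ann.records) == 1

    def test_tsv_round_trip_identity(self, tmp_path, toy_ontology, toy_annotations):
        p = tmp_path / "rt.tsv"
        write_annotations(toy_annotations, p)
        back = parse_annotations(p, toy_ontology, format="tsv")
        assert back.records == toy_annotations.records


class TestPropagate:
    def test_upward_closure_on_toy_dag(self, toy_ontology, toy_annotations):
        prop = propagate(toy_annotations, toy_ontology)
        # brute-force closure oracle
        expected_pairs = set()
        for g, t, _ in toy_annotations.records:
            expected_pairs.add((g, t))
            for anc in toy_ontology.ancestors(t):
                expected_pairs.add((g, anc))
        assert {(g, t) for g, t, _ in prop.records} == expected_pairs
        # Ga reaches the BP root through both B3 and B4
        assert ("Ga", R1) in {(g, t) for g, t, _ in prop.records}

    def test_root_only_annotation_is_fixpoint(self, toy_ontology):
        ann = AnnotationSet(frozenset({("Gx", R1, "EXP")}))
        assert propagate(ann, toy_ontology).records == ann.records

    def test_idempotence(self, toy_ontology, toy_annotations):
        once = propagate(toy_annotations, toy_ontology)
        assert propagate(once, toy_ontology).records == once.records

    def test_inferred_code_prefers_non_iea(self, toy_ontology):
        # B3 via EXP and B4 via IEA both imply B1: inherited code must be EXP
        ann = AnnotationSet(frozenset({("Ga", B3, "EXP"), ("Ga", B4, "IEA")}))
        prop = propagate(ann, toy_ontology)
        codes = {t: ev for g, t, ev in prop.records}
        assert codes[B1] == "EXP"
        # B2 is implied only by the IEA-evidenced B4
        assert codes[B2] == "IEA"

    def test_propagation_idempotent_and_monotone_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ont = random_layered_dag(rng, n_terms=15)
            ann = random_annotations(rng, ont, n_genes=10)
            prop = propagate(ann, ont)
            pairs0 = {(g, t) for g, t, _ in ann.records}
            pairs1 = {(g, t) for g, t, _ in prop.records}
            assert pairs0 <= pairs1  # monotone: only adds
            assert propagate(prop, ont).records == prop.records


class TestPropagateNegativesDown:
    def test_matches_brute_force_copying(self, toy_ontology):
        negs = {"Gx", "Gy", "Gz"}
        out = propagate_negatives_down(negs, B1, toy_ontology)
        assert set(out) == {B1, B3, B4}
        assert all(v == negs for v in out.values())

    def test_leaf_term_maps_only_itself(self, toy_ontology):
        out = propagate_negatives_down({"Gx"}, B3, toy_ontology)
        assert out == {B3: {"Gx"}}

    def test_empty_negative_set(self, toy_ontology):
        out = propagate_negatives_down(set(), R2, toy_ontology)
        assert set(out) == {R2, M1, M2}
        assert all(v == set() for v in out.values())

    def test_unknown_term_raises(self, toy_ontology):
        with pytest.raises(KeyError):
            propagate_negatives_down({"Gx"}, "GO:9999999", toy_ontology)

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ont = random_layered_dag(rng, n_terms=30)
            term = sorted(ont.terms)[int(rng.integers(len(ont.terms)))]
            negs = {"Gx", "Gy"}
            out = propagate_negatives_down(negs, term, ont)
            brute = {term: negs} | {d: negs for d in ont.descendants(term)}
            assert {k: set(v) for k, v in out.items()} == brute


class TestBuildMatrix:
    def test_toy_incidence_and_row_sums(self, toy_ontology, toy_annotations):
        A = build_matrix(toy_annotations, toy_ontology)
        assert A.genes == ("Ga", "Gb", "Gc")
        dense = A.A.toarray()
        col = A.col_index
        # Ga: B3, B4 plus ancestors B1, B2, R1
        assert dense[0, col[B3]] == 1 and dense[0, col[R1]] == 1
        assert A.W_diag[A.row_index["Ga"]] == 5
        assert A.W_diag[A.row_index["Gb"]] == 4  # B4, B1, B2, R1
        assert A.W_diag[A.row_index["Gc"]] == 3  # M2, M1, R2
        assert np.array_equal(np.asarray(A.A.sum(axis=1)).ravel(), A.W_diag)
        assert set(np.unique(dense)) <= {0, 1}

    def test_upward_closure_in_matrix(self, toy_ontology, toy_annotations):
        A = build_matrix(toy_annotations, toy_ontology)
        dense = A.A.toarray()
        col = A.col_index
        for i in range(dense.shape[0]):
            for t in A.terms:
                if dense[i, col[t]]:
                    for anc in toy_ontology.ancestors(t):
                        assert dense[i, col[anc]] == 1

    def test_iea_only_gene_dropped_without_iea(self, toy_ontology, toy_annotations):
        A = build_matrix(toy_annotations, toy_ontology, include_iea=False)
        assert "Gc" not in A.genes  # Gc only has an IEA record
        assert "Ga" in A.genes  # Ga retains its EXP record

    def test_root_only_annotations_leave_zero_columns(self, toy_ontology):
        ann = AnnotationSet(frozenset({("Gx", R1, "EXP"), ("Gy", R2, "EXP")}))
        A = build_matrix(ann, toy_ontology)
        dense = A.A.toarray()
        for t in (B1, B2, B3, B4, M1, M2, C1, R3):
            assert dense[:, A.col_index[t]].sum() == 0

    def test_empty_set_raises(self, toy_ontology):
        with pytest.raises(ValueError, match="no annotated genes"):
            build_matrix(AnnotationSet(frozenset()), toy_ontology)

    def test_upward_closure_on_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ont = random_layered_dag(rng, n_terms=20)
            ann = random_annotations(rng, ont, n_genes=15)
            A = build_matrix(ann, ont)
            dense = A.A.toarray()
            col = A.col_index
            rows, cols = np.nonzero(dense)
            for i, j in zip(rows, cols):
                for anc in ont.ancestors(A.terms[j]):
                    assert dense[i, col[anc]] == 1

    def test_mtx_round_trip(self, tmp_path, toy_ontology, toy_annotations):
        A = build_matrix(toy_annotations, toy_ontology)
        A.save(tmp_path / "cache")
        from negsel.ontology import AnnotationMatrix

        B = AnnotationMatrix.load(tmp_path / "cache")
        assert B.genes == A.genes and B.terms == A.terms
        assert (B.A != A.A).nnz == 0


class TestAnnotatedDirectDescendants:
    def test_toy_counts_per_branch(self, toy_ontology, toy_annotations):
        prop = propagate(toy_annotations, toy_ontology)
        counts = annotated_direct_descendants(toy_ontology, prop)
        # BP root children B1, B2 both annotated via propagation; MF child M1
        # annotated via Gc; CC has no annotations at all
        assert counts == {"BP": 2, "MF": 1, "CC": 0}

    def test_empty_branch_contributes_zero(self, toy_ontology):
        ann = propagate(
            AnnotationSet(frozenset({("Gx", M2, "EXP")})), toy_ontology
        )
        counts = annotated_direct_descendants(toy_ontology, ann)
        assert counts["BP"] == 0 and counts["CC"] == 0 and counts["MF"] == 1
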