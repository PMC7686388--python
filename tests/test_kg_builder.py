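"""Tests for TBox/ABox assembly, mapping attachment, and graph merging."""

import pytest
from rdflib import RDF, RDFS

from gutbrainkg.curation_io import (
    MappingTableRow,
    RelationshipTableRow,
    StatementTableRow,
)
from gutbrainkg.fixtures import seed_dataset
from gutbrainkg.kg_builder import (
    attach_mappings,
    build_abox,
    build_tbox,
    merge_graphs,
    tbox_class_names,
)
from gutbrainkg.schema_model import (
    Direction,
    EntityKind,
    EvidenceLevel,
    ExternalMappings,
    KnowledgeBase,
    SchemaError,
)
from gutbrainkg import vocab

from conftest import synthetic_kb


def _stmt(microbe, ntm, ref, pmid, level, direction=Direction.MODULATE):
    return StatementTableRow(microbe, ntm, direction, ref, pmid, EvidenceLevel(level))


class TestTBox:
    def test_seven_classes(self):
        assert len(tbox_class_names()) == 7
        assert set(tbox_class_names()) == {
            "GutMicrobiota",
            "Neurotransmitter",
            "MentalDisorder",
            "KEGGPathway",
            "Statement",
            "Relationship",
            "Reference",
        }

    def test_deterministic(self):
        assert set(build_tbox()) == set(build_tbox())

    def test_every_abox_type_is_a_tbox_class(self, seed_kb):
        tbox_classes = set(vocab.CLASSES.values())
        graph = vocab.kb_to_graph(seed_kb)
        for subj, _, cls in graph.triples((None, RDF.type, None)):
            if cls in (RDFS.Class, RDF.Property):
                continue
            assert cls in tbox_classes, f"{subj} typed outside the TBox"


class TestABox:
    def test_table1_rows_build_expected_nodes(self):
        rows = [
            _stmt("Bifidobacterium dentium", "GABA", "DeVadder 2018", 29866843, "B"),
            _stmt("Bifidobacterium dentium", "GABA", "Pokusaeve 2017", 27458085, "B"),
            _stmt("Bifidobacterium dentium", "GABA", "Barrett 2012", 22612585, "C"),
        ]
        kb = build_abox(rows, [])
        assert len(kb.entities_of_kind(EntityKind.GUT_MICROBIOTA)) == 1
        assert len(kb.entities_of_kind(EntityKind.NEUROTRANSMITTER)) == 1
        assert len(kb.references) == 3
        assert len(kb.statements) == 3

    def test_empty_inputs_empty_abox(self):
        kb = build_abox([], [])
        assert not kb.entities and not kb.statements and not kb.relationships

    def test_duplicate_rows_collapse(self):
        row = _stmt("Clostridium", "Dopamine", "Asano 2012", 23064760, "B")
        kb = build_abox([row, row], [])
        assert len(kb.statements) == 1

    def test_reference_dedup_by_pmid(self):
        rows = [
            _stmt("Clostridium", "Dopamine", "Asano 2012", 23064760, "B"),
            _stmt("Clostridium", "Norepinephrine", "Asano 2012", 23064760, "B"),
        ]
        kb = build_abox(rows, [])
        assert len(kb.references) == 1

    def test_conflicting_level_same_pmid_rejected(self):
        rows = [
            _stmt("Clostridium", "Dopamine", "Asano 2012", 23064760, "B"),
            _stmt("Clostridium", "Norepinephrine", "Asano 2012", 23064760, "C"),
        ]
        with pytest.raises(SchemaError, match="conflicting evidence levels"):
            build_abox(rows, [])

    def test_case_insensitive_entity_resolution(self):
        rows = [
            _stmt("Clostridium", "GABA", "A 2020", 101, "B"),
            _stmt("clostridium", "gaba", "B 2020", 102, "B"),
        ]
        kb = build_abox(rows, [])
        assert len(kb.entities_of_kind(EntityKind.GUT_MICROBIOTA)) == 1

    def test_reference_count_equals_distinct_pmids(self, random_kbs):
        seed = seed_dataset()
        kb = build_abox(seed.statement_rows, seed.relationship_rows, seed.entity_rows)
        pmids = {r.pmid for r in seed.statement_rows}
        for row in seed.relationship_rows:
            pmids.update(row.pmids)
        assert set(kb.references) == pmids


class TestAttachMappings:
    def test_mapping_attached(self, ):
        kb = build_abox([_stmt("Clostridium", "GABA", "A 2020", 101, "B")], [])
        report = attach_mappings(
            kb,
            [
                MappingTableRow(
                    EntityKind.NEUROTRANSMITTER,
                    "GABA",
                    ExternalMappings(kegg_compound="C00334"),
                )
            ],
        )
        assert report.attached == ["GABA"]
        entity = kb.find_entity(EntityKind.NEUROTRANSMITTER, "GABA")
        assert entity.mappings.kegg_compound == "C00334"
        kb.check_integrity()

    def test_unknown_label_warns_and_leaves_kb_unchanged(self):
        kb = build_abox([_stmt("Clostridium", "GABA", "A 2020", 101, "B")], [])
        before = dict(kb.entities)
        with pytest.warns(UserWarning, match="Foo"):
            report = attach_mappings(
                kb,
                [MappingTableRow(EntityKind.NEUROTRANSMITTER, "Foo", ExternalMappings(umls_cui="C0000001"))],
            )
        assert report.unresolved == ["Foo"]
        assert kb.entities == before

    def test_kegg_compound_on_microbe_rejected(self):
        kb = build_abox([_stmt("Clostridium", "GABA", "A 2020", 101, "B")], [])
        with pytest.raises(SchemaError, match="KEGG"):
            attach_mappings(
                kb,
                [
                    MappingTableRow(
                        EntityKind.GUT_MICROBIOTA,
                        "Clostridium",
                        ExternalMappings(kegg_compound="C00334"),
                    )
                ],
            )


class TestMerge:
    def test_empty_is_identity(self, seed_kb):
        assert merge_graphs(seed_kb, KnowledgeBase()) == seed_kb
        assert merge_graphs(KnowledgeBase(), seed_kb) == seed_kb

    def test_idempotent(self, seed_kb):
        assert merge_graphs(seed_kb, seed_kb) == seed_kb

    def test_split_seed_reassembles(self, seed_kb):
        seed = seed_dataset()
        statements_only = build_abox(seed.statement_rows, [], seed.entity_rows)
        relationships_only = build_abox([], seed.relationship_rows, seed.entity_rows)
        assert merge_graphs(statements_only, relationships_only) == seed_kb

    def test_commutative_and_associative_on_random_pairs(self, random_kbs):
        for i in range(0, 8, 2):
            a, b, c = random_kbs[i], random_kbs[i + 1], random_kbs[(i + 5) % 20]
            assert merge_graphs(a, b) == merge_graphs(b, a)
            assert merge_graphs(merge_graphs(a, b), c) == merge_graphs(a, merge_graphs(b, c))

    def test_level_conflict_rejected(self):
        kb1 = build_abox([_stmt("Clostridium", "GABA", "A 2020", 101, "B")], [])
        kb2 = build_abox([_stmt("Clostridium", "GABA", "A 2020", 101, "C")], [])
        with pytest.raises(SchemaError, match="conflicting evidence levels"):
            merge_graphs(kb1, kb2)
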