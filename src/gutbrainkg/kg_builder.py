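"""Assembly of the TBox/ABox knowledge base from validated curation rows,
external-identifier attachment, and graph merging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdflib import Graph

from . import vocab
from .curation_io import (
    EntityTableRow,
    MappingTableRow,
    RelationshipTableRow,
    StatementTableRow,
)
from .schema_model import (
    EntityKind,
    EntityRecord,
    KnowledgeBase,
    Reference,
    Relationship,
    SchemaError,
    Statement,
)

__all__ = ["build_tbox", "tbox_class_names", "build_abox", "attach_mappings", "merge_graphs", "MappingReport"]


def build_tbox() -> Graph:
    """The terminological box as an RDF graph: the four entity classes
    (gut microbiota, neurotransmitter, mental disorder, KEGG pathway),
    the three relation classes (statement, relationship, reference), and
    the edge/attribute properties. Deterministic: repeated calls yield
    graphs with identical triple sets."""
    return vocab.tbox_graph()


def tbox_class_names() -> tuple[str, ...]:
    return tuple(sorted(vocab.CLASSES))


def build_abox(
    statement_rows: Sequence[StatementTableRow],
    relationship_rows: Sequence[RelationshipTableRow],
    entity_rows: Sequence[EntityTableRow] = (),
) -> KnowledgeBase:
    """Instantiate the assertional box from validated curation rows.

    Entities are auto-created on first mention (and from the optional
    roster rows, which let edge-less entities exist in the graph);
    references are deduplicated globally by PMID. The same PMID curated
    with two different evidence levels is a hard error — evidence grading
    must stay auditable, so there is no last-write-wins.
    """
    kb = KnowledgeBase()
    for row in entity_rows:
        kb.add_entity(EntityRecord.from_label(row.kind, row.label))
    for row in statement_rows:
        microbe = _resolve_or_create(kb, EntityKind.GUT_MICROBIOTA, row.microbe_label)
        ntm = _resolve_or_create(kb, EntityKind.NEUROTRANSMITTER, row.ntm_label)
        ref = Reference(row.ref_label, row.pmid, row.level)
        kb.add_statement(Statement(microbe, ntm, row.direction, ref))
    for row in relationship_rows:
        ntm = _resolve_or_create(kb, EntityKind.NEUROTRANSMITTER, row.ntm_label)
        disorder = _resolve_or_create(kb, EntityKind.MENTAL_DISORDER, row.disorder_label)
        refs = tuple(
            Reference(lbl, pmid, lvl)
            for lbl, pmid, lvl in zip(row.ref_labels, row.pmids, row.levels)
        )
        kb.add_relationship(Relationship(ntm, disorder, refs))
    kb.check_integrity()
    return kb


def _resolve_or_create(kb: KnowledgeBase, kind: EntityKind, label: str) -> EntityRecord:
    existing = kb.find_entity(kind, label)
    if existing is not None:
        return existing
    return kb.add_entity(EntityRecord.from_label(kind, label))


@dataclass
class MappingReport:
    """Outcome of an attach_mappings pass."""

    attached: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)


def attach_mappings(
    kb: KnowledgeBase, mapping_rows: Iterable[MappingTableRow]
) -> MappingReport:
    """Attach external identifiers (UMLS CUI, MeSH ID, KEGG compound and
    pathway numbers) to existing entities, matched by exact
    case-insensitive English label.

    Unresolvable labels are reported as warnings, not errors: mappings
    are additive and the graph is fully functional without them. A KEGG
    mapping on a non-chemical entity kind is a schema error.
    """
    report = MappingReport()
    for row in mapping_rows:
        entity = kb.find_entity(row.kind, row.label)
        if entity is None:
            report.unresolved.append(row.label)
            warnings.warn(
                f"mapping target {row.label!r} ({row.kind.value}) not in graph; skipped",
                stacklevel=2,
            )
            continue
        kb.entities[entity.key] = entity.with_mappings(row.mappings)
        _rewire_edges(kb, entity, kb.entities[entity.key])
        report.attached.append(row.label)
    kb.check_integrity()
    return report


def _rewire_edges(kb: KnowledgeBase, old: EntityRecord, new: EntityRecord) -> None:
    """Replace an entity record inside every edge that embeds it."""
    if old == new:
        return
    for stmt in [s for s in kb.statements if old in (s.microbe, s.neurotransmitter)]:
        kb.statements.discard(stmt)
        kb.statements.add(
            Statement(
                new if stmt.microbe == old else stmt.microbe,
                new if stmt.neurotransmitter == old else stmt.neurotransmitter,
                stmt.direction,
                stmt.reference,
            )
        )
    for rel in [r for r in kb.relationships if old in (r.neurotransmitter, r.disorder)]:
        kb.relationships.discard(rel)
        kb.relationships.add(
            Relationship(
                new if rel.neurotransmitter == old else rel.neurotransmitter,
                new if rel.disorder == old else rel.disorder,
                rel.references,
            )
        )


def merge_graphs(kb1: KnowledgeBase, kb2: KnowledgeBase) -> KnowledgeBase:
    """Set-union merge of two knowledge bases.

    Entities merge by (kind, local_id), references by PMID, edges by
    value. The same PMID carrying two different evidence levels is a
    conflict error, mirroring build_abox. Merging is commutative and
    associative up to set equality, with the empty graph as identity.
    """
    merged = KnowledgeBase()
    for kb in (kb1, kb2):
        for entity in kb.entities.values():
            merged.add_entity(entity)
        for ref in kb.references.values():
            merged.add_reference(ref)
    for kb in (kb1, kb2):
        for stmt in kb.statements:
            merged.add_statement(stmt)
        for rel in kb.relationships:
            merged.add_relationship(rel)
    merged.check_integrity()
    return merged
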