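"""Ontology vocabulary, controlled value sets, URI minting, and the in-memory
knowledge-base model.

The knowledge base is a small description-logic-style store for the
microbiota-gut-brain axis: gut microbes modulate neurotransmitter levels
(reified ``Statement`` edges, each backed by exactly one literature
reference), and neurotransmitters are associated with mental disorders
(reified ``Relationship`` edges, each backed by one to five references).
Every reference carries an evidence level from A (strongest, randomized
controlled trials) to E (weakest).

All model types are immutable so that graphs can be compared by set
equality, which the Turtle round-trip and merge contracts rely on.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from rdflib import Namespace

__all__ = [
    "BASE_NAMESPACE",
    "VOCAB",
    "EntityKind",
    "EvidenceLevel",
    "Direction",
    "EntityRecord",
    "ExternalMappings",
    "Reference",
    "Statement",
    "Relationship",
    "KnowledgeBase",
    "SchemaError",
    "mint_uri",
    "slugify",
    "validate_level",
    "compare_levels",
    "PLACEHOLDER_PMID_FLOOR",
]

#: Project-owned base namespace for all minted URIs. The upstream resource
#: never published its URI scheme, so this is a deliberate local constant;
#: change it before minting if you need graphs under your own authority.
BASE_NAMESPACE = "http://gutbrainkg.example.org/"

#: Vocabulary (TBox) namespace.
VOCAB = Namespace(BASE_NAMESPACE + "vocab#")

#: References with a PMID at or above this sentinel are curation
#: placeholders (facts taken from narrative text without a printed PMID)
#: and are excluded from citable-reference counts.
PLACEHOLDER_PMID_FLOOR = 900_000_000


class SchemaError(ValueError):
    """A model invariant was violated."""


class EntityKind(str, enum.Enum):
    """The four entity classes of the knowledge graph."""

    GUT_MICROBIOTA = "gut_microbiota"
    NEUROTRANSMITTER = "neurotransmitter"
    MENTAL_DISORDER = "mental_disorder"
    KEGG_PATHWAY = "kegg_pathway"

    @property
    def uri_segment(self) -> str:
        return _KIND_SEGMENTS[self]

    @property
    def class_name(self) -> str:
        return _KIND_CLASSES[self]


_KIND_SEGMENTS = {
    EntityKind.GUT_MICROBIOTA: "gm",
    EntityKind.NEUROTRANSMITTER: "ntm",
    EntityKind.MENTAL_DISORDER: "md",
    EntityKind.KEGG_PATHWAY: "pw",
}

_KIND_CLASSES = {
    EntityKind.GUT_MICROBIOTA: "GutMicrobiota",
    EntityKind.NEUROTRANSMITTER: "Neurotransmitter",
    EntityKind.MENTAL_DISORDER: "MentalDisorder",
    EntityKind.KEGG_PATHWAY: "KEGGPathway",
}


class EvidenceLevel(str, enum.Enum):
    """Study-design strength grade of a reference; A is strongest."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    @property
    def rank(self) -> int:
        """0 for A (strongest) through 4 for E (weakest)."""
        return "ABCDE".index(self.value)


class Direction(str, enum.Enum):
    """How a microbe modulates a neurotransmitter level.

    ``MODULATE`` is the explicit "direction unknown/unspecified" value,
    not a missing field: curated sources frequently assert modulation
    without resolving its sign.
    """

    INCREASE = "increase"
    DECREASE = "decrease"
    MODULATE = "modulate"


_SLUG_RE = re.compile(r"^[a-z0-9_]+$")
_CUI_RE = re.compile(r"^C\d{7}$")
_MESH_RE = re.compile(r"^[DC]\d+$")
_KEGG_COMPOUND_RE = re.compile(r"^C\d{5}$")
_KEGG_PATHWAY_RE = re.compile(r"^map\d{5}$")


def slugify(label: str) -> str:
    """Lowercase a label and collapse non-alphanumeric runs to single
    underscores, trimming leading/trailing ones."""
    slug = re.sub(r"[^a-z0-9]+", "_", label.lower()).strip("_")
    return slug


def mint_uri(kind: EntityKind, label: str) -> str:
    """Deterministically mint an entity URI from its kind and label.

    Raises :class:`SchemaError` on an empty label or a label that slugs
    to nothing (e.g. pure punctuation).
    """
    if not label or not label.strip():
        raise SchemaError("cannot mint URI from empty label")
    slug = slugify(label)
    if not slug:
        raise SchemaError(f"label {label!r} contains no sluggable characters")
    return f"{BASE_NAMESPACE}{EntityKind(kind).uri_segment}/{slug}"


def validate_level(level: str, *, context: str = "") -> EvidenceLevel:
    """Normalize a level token to a canonical :class:`EvidenceLevel`.

    ``context`` is interpolated into the error message so curation
    readers can name the offending row.
    """
    if isinstance(level, EvidenceLevel):
        return level
    token = str(level).strip().upper()
    try:
        return EvidenceLevel(token)
    except ValueError:
        where = f" ({context})" if context else ""
        raise SchemaError(
            f"evidence level must be one of A-E, got {level!r}{where}"
        ) from None


def compare_levels(a: EvidenceLevel | str, b: EvidenceLevel | str) -> int:
    """Compare two evidence levels on the strength order (A strongest).

    Returns -1 if ``a`` is stronger than ``b``, 0 if equal, +1 if weaker,
    so that sorting ascending by this key puts the strongest first.
    """
    ra = validate_level(a).rank
    rb = validate_level(b).rank
    return (ra > rb) - (ra < rb)


@dataclass(frozen=True)
class ExternalMappings:
    """Cross-references into external vocabularies.

    umls_cui: UMLS Concept Unique Identifier, ``C`` + 7 digits.
    mesh_id: MeSH descriptor/concept identifier, ``D`` or ``C`` + digits.
    kegg_compound: KEGG compound "C number", ``C`` + 5 digits; only
        meaningful for neurotransmitters (small molecules).
    kegg_pathways: KEGG pathway "map numbers", ``map`` + 5 digits.
    """

    umls_cui: str | None = None
    mesh_id: str | None = None
    kegg_compound: str | None = None
    kegg_pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.umls_cui is not None and not _CUI_RE.match(self.umls_cui):
            raise SchemaError(f"malformed UMLS CUI {self.umls_cui!r} (expected C + 7 digits)")
        if self.mesh_id is not None and not _MESH_RE.match(self.mesh_id):
            raise SchemaError(f"malformed MeSH ID {self.mesh_id!r} (expected D or C + digits)")
        if self.kegg_compound is not None and not _KEGG_COMPOUND_RE.match(self.kegg_compound):
            raise SchemaError(
                f"malformed KEGG compound {self.kegg_compound!r} (expected C + 5 digits)"
            )
        object.__setattr__(self, "kegg_pathways", tuple(self.kegg_pathways))
        for pw in self.kegg_pathways:
            if not _KEGG_PATHWAY_RE.match(pw):
                raise SchemaError(f"malformed KEGG pathway {pw!r} (expected map + 5 digits)")

    def is_empty(self) -> bool:
        return (
            self.umls_cui is None
            and self.mesh_id is None
            and self.kegg_compound is None
            and not self.kegg_pathways
        )


@dataclass(frozen=True)
class EntityRecord:
    """A node of the graph: microbe taxon, neurotransmitter, mental
    disorder, or KEGG pathway, with multilingual labels.

    Taxa are flat nodes regardless of rank (a genus like *Clostridium*
    and a species like *Escherichia coli* are peers); the schema does not
    model taxonomic hierarchy.
    """

    kind: EntityKind
    local_id: str
    labels: tuple[tuple[str, str], ...]  # (text, language-tag) pairs
    mappings: ExternalMappings | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EntityKind(self.kind))
        object.__setattr__(self, "labels", tuple(tuple(p) for p in self.labels))
        if not self.local_id or not _SLUG_RE.match(self.local_id):
            raise SchemaError(
                f"local_id {self.local_id!r} must be non-empty lowercase [a-z0-9_]"
            )
        if not any(lang == "en" for _, lang in self.labels):
            raise SchemaError(f"entity {self.local_id!r} has no English (en) label")
        if self.mappings is not None and self.kind not in (
            EntityKind.NEUROTRANSMITTER,
            EntityKind.KEGG_PATHWAY,
        ):
            if self.mappings.kegg_compound is not None or self.mappings.kegg_pathways:
                raise SchemaError(
                    f"KEGG compound/pathway mappings are only valid on "
                    f"neurotransmitter or kegg_pathway entities, not {self.kind.value}"
                )

    @property
    def key(self) -> tuple[EntityKind, str]:
        return (self.kind, self.local_id)

    @property
    def uri(self) -> str:
        return f"{BASE_NAMESPACE}{self.kind.uri_segment}/{self.local_id}"

    def label(self, language: str = "en") -> str:
        for text, lang in self.labels:
            if lang == language:
                return text
        raise KeyError(f"entity {self.local_id!r} has no {language!r} label")

    @classmethod
    def from_label(
        cls,
        kind: EntityKind,
        label: str,
        *,
        extra_labels: tuple[tuple[str, str], ...] = (),
        mappings: ExternalMappings | None = None,
    ) -> "EntityRecord":
        return cls(
            kind=EntityKind(kind),
            local_id=slugify(label),
            labels=((label, "en"), *extra_labels),
            mappings=mappings,
        )

    def with_mappings(self, mappings: ExternalMappings) -> "EntityRecord":
        return EntityRecord(self.kind, self.local_id, self.labels, mappings)


@dataclass(frozen=True)
class Reference:
    """A literature citation: display label, PubMed identifier, and
    evidence level. The level is a property of the study design, so a
    reference reused across statements carries a single level."""

    label: str
    pmid: int
    level: EvidenceLevel

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", validate_level(self.level))
        if int(self.pmid) <= 0:
            raise SchemaError(f"PMID must be positive, got {self.pmid}")
        object.__setattr__(self, "pmid", int(self.pmid))

    @property
    def is_placeholder(self) -> bool:
        return self.pmid >= PLACEHOLDER_PMID_FLOOR

    @property
    def uri(self) -> str:
        return f"{BASE_NAMESPACE}ref/{self.pmid}"


@dataclass(frozen=True)
class Statement:
    """Reified microbe -> neurotransmitter modulation edge, supported by
    exactly one reference."""

    microbe: EntityRecord
    neurotransmitter: EntityRecord
    direction: Direction
    reference: Reference

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.microbe.kind is not EntityKind.GUT_MICROBIOTA:
            raise SchemaError("statement subject must be a gut_microbiota entity")
        if self.neurotransmitter.kind is not EntityKind.NEUROTRANSMITTER:
            raise SchemaError("statement object must be a neurotransmitter entity")

    @property
    def uri(self) -> str:
        return (
            f"{BASE_NAMESPACE}stmt/{self.microbe.local_id}"
            f"__{self.neurotransmitter.local_id}__{self.reference.pmid}"
        )


@dataclass(frozen=True)
class Relationship:
    """Reified neurotransmitter -> mental-disorder association edge,
    supported by one to five references with distinct PMIDs."""

    neurotransmitter: EntityRecord
    disorder: EntityRecord
    references: tuple[Reference, ...]

    def __post_init__(self) -> None:
        refs = tuple(sorted(self.references, key=lambda r: r.pmid))
        object.__setattr__(self, "references", refs)
        if not 1 <= len(refs) <= 5:
            raise SchemaError(
                f"relationship must carry 1-5 references, got {len(refs)}"
            )
        pmids = [r.pmid for r in refs]
        if len(set(pmids)) != len(pmids):
            raise SchemaError(f"duplicate PMIDs within one relationship: {pmids}")
        if self.neurotransmitter.kind is not EntityKind.NEUROTRANSMITTER:
            raise SchemaError("relationship subject must be a neurotransmitter entity")
        if self.disorder.kind is not EntityKind.MENTAL_DISORDER:
            raise SchemaError("relationship object must be a mental_disorder entity")

    @property
    def uri(self) -> str:
        return (
            f"{BASE_NAMESPACE}rel/{self.neurotransmitter.local_id}"
            f"__{self.disorder.local_id}"
        )


@dataclass
class KnowledgeBase:
    """The assembled ABox: entities keyed by (kind, local_id), references
    deduplicated by PMID, and the two reified edge sets.

    Referential integrity (edges only touch stored entities/references)
    is maintained by the ``add_*`` builders and checkable at any time via
    :meth:`check_integrity`.
    """

    entities: dict[tuple[EntityKind, str], EntityRecord] = field(default_factory=dict)
    references: dict[int, Reference] = field(default_factory=dict)
    statements: set[Statement] = field(default_factory=set)
    relationships: set[Relationship] = field(default_factory=set)

    def add_entity(self, entity: EntityRecord) -> EntityRecord:
        """Insert or return the stored entity with the same key.

        Mapping-bearing records replace mapping-free duplicates; any other
        conflict on the same key is an error.
        """
        existing = self.entities.get(entity.key)
        if existing is None:
            self.entities[entity.key] = entity
            return entity
        if existing == entity:
            return existing
        if existing.labels == entity.labels:
            if existing.mappings is None and entity.mappings is not None:
                self.entities[entity.key] = entity
                return entity
            if entity.mappings is None:
                return existing
        raise SchemaError(
            f"conflicting entity records for {entity.key}: {existing} vs {entity}"
        )

    def add_reference(self, ref: Reference) -> Reference:
        existing = self.references.get(ref.pmid)
        if existing is None:
            self.references[ref.pmid] = ref
            return ref
        if existing.level is not ref.level:
            raise SchemaError(
                f"PMID {ref.pmid} curated with conflicting evidence levels "
                f"{existing.level.value} and {ref.level.value}"
            )
        return existing

    def add_statement(self, stmt: Statement) -> Statement:
        microbe = self.add_entity(stmt.microbe)
        ntm = self.add_entity(stmt.neurotransmitter)
        ref = self.add_reference(stmt.reference)
        canonical = Statement(microbe, ntm, stmt.direction, ref)
        self.statements.add(canonical)
        return canonical

    def add_relationship(self, rel: Relationship) -> Relationship:
        ntm = self.add_entity(rel.neurotransmitter)
        disorder = self.add_entity(rel.disorder)
        refs = tuple(self.add_reference(r) for r in rel.references)
        canonical = Relationship(ntm, disorder, refs)
        self.relationships.add(canonical)
        return canonical

    def find_entity(self, kind: EntityKind, label: str) -> EntityRecord | None:
        """Exact case-insensitive English-label lookup (no fuzzy matching)."""
        needle = label.strip().lower()
        for entity in self.entities.values():
            if entity.kind is kind and any(
                text.lower() == needle for text, lang in entity.labels if lang == "en"
            ):
                return entity
        return None

    def entities_of_kind(self, kind: EntityKind) -> list[EntityRecord]:
        return sorted(
            (e for e in self.entities.values() if e.kind is kind),
            key=lambda e: e.local_id,
        )

    def check_integrity(self) -> None:
        """Raise :class:`SchemaError` if any edge touches an unstored
        entity or reference."""
        for stmt in self.statements:
            for ent in (stmt.microbe, stmt.neurotransmitter):
                if self.entities.get(ent.key) != ent:
                    raise SchemaError(f"statement references unstored entity {ent.key}")
            if self.references.get(stmt.reference.pmid) != stmt.reference:
                raise SchemaError(
                    f"statement references unstored PMID {stmt.reference.pmid}"
                )
        for rel in self.relationships:
            for ent in (rel.neurotransmitter, rel.disorder):
                if self.entities.get(ent.key) != ent:
                    raise SchemaError(f"relationship references unstored entity {ent.key}")
            for ref in rel.references:
                if self.references.get(ref.pmid) != ref:
                    raise SchemaError(f"relationship references unstored PMID {ref.pmid}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.references == other.references
            and self.statements == other.statements
            and self.relationships == other.relationships
        )
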