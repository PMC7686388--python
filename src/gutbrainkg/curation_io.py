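"""Reading and validating tabular curation files, and Turtle round-trip
serialization of the knowledge graph.

Curation tables are UTF-8 tab-separated files with a mandatory header.
Three table shapes exist:

``statements``
    one microbe -> neurotransmitter modulation fact per row, with its
    single supporting reference (columns: microbe, neurotransmitter,
    direction, ref_label, pmid, level; direction may be blank and then
    defaults to "modulate").

``relationships``
    one neurotransmitter -> disorder association per row, with one to
    five references packed into semicolon-separated cells (columns:
    neurotransmitter, disorder, ref_labels, pmids, levels).

``mappings`` / ``entities``
    external-identifier attachments and bare entity rosters.

Validation is total: a file with k violations produces a single
:class:`CurationError` carrying all k findings, each naming its file
line and column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import Graph, Literal, RDF, RDFS, URIRef

from . import vocab
from .schema_model import (
    Direction,
    EntityKind,
    EntityRecord,
    EvidenceLevel,
    ExternalMappings,
    KnowledgeBase,
    Reference,
    Relationship,
    SchemaError,
    Statement,
    validate_level,
)

__all__ = [
    "CurationError",
    "Finding",
    "StatementTableRow",
    "RelationshipTableRow",
    "MappingTableRow",
    "EntityTableRow",
    "read_statement_table",
    "read_relationship_table",
    "read_mapping_table",
    "read_entity_table",
    "write_statement_table",
    "write_relationship_table",
    "write_mapping_table",
    "write_entity_table",
    "write_turtle",
    "turtle_string",
    "read_turtle",
    "TurtleLoadReport",
]

MAX_REFS_PER_RELATIONSHIP = 5

_KIND_TOKENS = {k.value: k for k in EntityKind}


@dataclass(frozen=True)
class Finding:
    """One validation violation, located by file line (header = line 1)."""

    line: int
    column: str
    message: str

    def __str__(self) -> str:
        return f"line {self.line}, column {self.column!r}: {self.message}"


class CurationError(ValueError):
    """All violations found in one curation file, reported together."""

    def __init__(self, path: str | Path, findings: Sequence[Finding]):
        self.path = str(path)
        self.findings = list(findings)
        lines = "\n".join(f"  - {f}" for f in self.findings)
        super().__init__(
            f"{len(self.findings)} curation error(s) in {self.path}:\n{lines}"
        )


@dataclass(frozen=True)
class StatementTableRow:
    microbe_label: str
    ntm_label: str
    direction: Direction
    ref_label: str
    pmid: int
    level: EvidenceLevel


@dataclass(frozen=True)
class RelationshipTableRow:
    ntm_label: str
    disorder_label: str
    ref_labels: tuple[str, ...]
    pmids: tuple[int, ...]
    levels: tuple[EvidenceLevel, ...]


@dataclass(frozen=True)
class MappingTableRow:
    kind: EntityKind
    label: str
    mappings: ExternalMappings


@dataclass(frozen=True)
class EntityTableRow:
    kind: EntityKind
    label: str


# ---------------------------------------------------------------------------
# TSV reading


def _read_rows(
    path: str | Path, required: Sequence[str], delimiter: str
) -> tuple[list[tuple[int, dict[str, str]]], list[Finding]]:
    """Return (line_number, row_dict) pairs and header-level findings."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        findings = [
            Finding(1, col, "missing mandatory column")
            for col in required
            if col not in header
        ]
        if findings:
            return [], findings
        rows = [
            (lineno, {k: (v or "").strip() for k, v in row.items() if k is not None})
            for lineno, row in enumerate(reader, start=2)
        ]
    return rows, []


def read_statement_table(
    path: str | Path, *, delimiter: str = "\t"
) -> list[StatementTableRow]:
    """Read and validate a statement curation table.

    A blank ``direction`` cell is the explicit unknown and becomes
    ``modulate``. Raises :class:`CurationError` listing every violation.
    """
    required = ("microbe", "neurotransmitter", "direction", "ref_label", "pmid", "level")
    raw, findings = _read_rows(path, required, delimiter)
    out: list[StatementTableRow] = []
    for lineno, row in raw:
        ok = True
        for col in ("microbe", "neurotransmitter", "ref_label"):
            if not row[col]:
                findings.append(Finding(lineno, col, "value must be non-empty"))
                ok = False
        direction = Direction.MODULATE
        if row["direction"]:
            try:
                direction = Direction(row["direction"].lower())
            except ValueError:
                findings.append(
                    Finding(
                        lineno,
                        "direction",
                        f"{row['direction']!r} not in "
                        f"{{increase, decrease, modulate}} (or blank)",
                    )
                )
                ok = False
        pmid = _parse_pmid(row["pmid"], lineno, "pmid", findings)
        level = _parse_level(row["level"], lineno, "level", findings)
        if ok and pmid is not None and level is not None:
            out.append(
                StatementTableRow(
                    microbe_label=row["microbe"],
                    ntm_label=row["neurotransmitter"],
                    direction=direction,
                    ref_label=row["ref_label"],
                    pmid=pmid,
                    level=level,
                )
            )
    if findings:
        raise CurationError(path, findings)
    return out


def read_relationship_table(
    path: str | Path, *, delimiter: str = "\t"
) -> list[RelationshipTableRow]:
    """Read and validate a relationship curation table.

    The three reference cells are semicolon-separated and must agree in
    length; at most five references per relationship are accepted.
    """
    required = ("neurotransmitter", "disorder", "ref_labels", "pmids", "levels")
    raw, findings = _read_rows(path, required, delimiter)
    out: list[RelationshipTableRow] = []
    for lineno, row in raw:
        ok = True
        for col in ("neurotransmitter", "disorder"):
            if not row[col]:
                findings.append(Finding(lineno, col, "value must be non-empty"))
                ok = False
        labels = _split_cell(row["ref_labels"])
        pmid_tokens = _split_cell(row["pmids"])
        level_tokens = _split_cell(row["levels"])
        if not (len(labels) == len(pmid_tokens) == len(level_tokens)):
            findings.append(
                Finding(
                    lineno,
                    "pmids",
                    f"ref_labels/pmids/levels counts differ "
                    f"({len(labels)}/{len(pmid_tokens)}/{len(level_tokens)})",
                )
            )
            ok = False
        if not labels:
            findings.append(Finding(lineno, "ref_labels", "at least one reference required"))
            ok = False
        if len(labels) > MAX_REFS_PER_RELATIONSHIP:
            findings.append(
                Finding(
                    lineno,
                    "ref_labels",
                    f"{len(labels)} references exceed the maximum of "
                    f"{MAX_REFS_PER_RELATIONSHIP} per relationship",
                )
            )
            ok = False
        pmids = [_parse_pmid(tok, lineno, "pmids", findings) for tok in pmid_tokens]
        levels = [_parse_level(tok, lineno, "levels", findings) for tok in level_tokens]
        if None in pmids or None in levels:
            ok = False
        elif len(set(pmids)) != len(pmids):
            findings.append(Finding(lineno, "pmids", "duplicate PMIDs within one relationship"))
            ok = False
        if ok:
            out.append(
                RelationshipTableRow(
                    ntm_label=row["neurotransmitter"],
                    disorder_label=row["disorder"],
                    ref_labels=tuple(labels),
                    pmids=tuple(pmids),  # type: ignore[arg-type]
                    levels=tuple(levels),  # type: ignore[arg-type]
                )
            )
    if findings:
        raise CurationError(path, findings)
    return out


def read_mapping_table(
    path: str | Path, *, delimiter: str = "\t"
) -> list[MappingTableRow]:
    required = ("kind", "label", "cui", "mesh_id", "kegg_compound", "kegg_pathways")
    raw, findings = _read_rows(path, required, delimiter)
    out: list[MappingTableRow] = []
    for lineno, row in raw:
        kind = _parse_kind(row["kind"], lineno, findings)
        if not row["label"]:
            findings.append(Finding(lineno, "label", "value must be non-empty"))
            kind = None
        try:
            mappings = ExternalMappings(
                umls_cui=row["cui"] or None,
                mesh_id=row["mesh_id"] or None,
                kegg_compound=row["kegg_compound"] or None,
                kegg_pathways=tuple(_split_cell(row["kegg_pathways"])),
            )
        except SchemaError as exc:
            findings.append(Finding(lineno, "cui", str(exc)))
            continue
        if kind is not None:
            out.append(MappingTableRow(kind=kind, label=row["label"], mappings=mappings))
    if findings:
        raise CurationError(path, findings)
    return out


def read_entity_table(path: str | Path, *, delimiter: str = "\t") -> list[EntityTableRow]:
    raw, findings = _read_rows(path, ("kind", "label"), delimiter)
    out: list[EntityTableRow] = []
    for lineno, row in raw:
        kind = _parse_kind(row["kind"], lineno, findings)
        if not row["label"]:
            findings.append(Finding(lineno, "label", "value must be non-empty"))
        elif kind is not None:
            out.append(EntityTableRow(kind=kind, label=row["label"]))
    if findings:
        raise CurationError(path, findings)
    return out


def _split_cell(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def _parse_pmid(token: str, lineno: int, column: str, findings: list[Finding]) -> int | None:
    try:
        pmid = int(token)
        if pmid <= 0:
            raise ValueError
        return pmid
    except (TypeError, ValueError):
        findings.append(Finding(lineno, column, f"PMID must be a positive integer, got {token!r}"))
        return None


def _parse_level(
    token: str, lineno: int, column: str, findings: list[Finding]
) -> EvidenceLevel | None:
    try:
        return validate_level(token)
    except SchemaError as exc:
        findings.append(Finding(lineno, column, str(exc)))
        return None


def _parse_kind(token: str, lineno: int, findings: list[Finding]) -> EntityKind | None:
    kind = _KIND_TOKENS.get(token.strip().lower())
    if kind is None:
        findings.append(
            Finding(lineno, "kind", f"{token!r} not one of {sorted(_KIND_TOKENS)}")
        )
    return kind


# ---------------------------------------------------------------------------
# TSV writing (used by the fixture generator and the CLI)


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_statement_table(rows: Iterable[StatementTableRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ("microbe", "neurotransmitter", "direction", "ref_label", "pmid", "level"),
        (
            (r.microbe_label, r.ntm_label, r.direction.value, r.ref_label, str(r.pmid), r.level.value)
            for r in rows
        ),
    )


def write_relationship_table(rows: Iterable[RelationshipTableRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ("neurotransmitter", "disorder", "ref_labels", "pmids", "levels"),
        (
            (
                r.ntm_label,
                r.disorder_label,
                ";".join(r.ref_labels),
                ";".join(str(p) for p in r.pmids),
                ";".join(lv.value for lv in r.levels),
            )
            for r in rows
        ),
    )


def write_mapping_table(rows: Iterable[MappingTableRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ("kind", "label", "cui", "mesh_id", "kegg_compound", "kegg_pathways"),
        (
            (
                r.kind.value,
                r.label,
                r.mappings.umls_cui or "",
                r.mappings.mesh_id or "",
                r.mappings.kegg_compound or "",
                ";".join(r.mappings.kegg_pathways),
            )
            for r in rows
        ),
    )


def write_entity_table(rows: Iterable[EntityTableRow], path: str | Path) -> None:
    _write_tsv(path, ("kind", "label"), ((r.kind.value, r.label) for r in rows))


# ---------------------------------------------------------------------------
# Turtle serialization

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape(text: str) -> str:
    return "".join(_ESCAPES.get(ch, ch) for ch in text)


def _term(node, prefixes: list[tuple[str, str]]) -> str:
    if isinstance(node, URIRef):
        uri = str(node)
        for prefix, ns in prefixes:
            if uri.startswith(ns):
                local = uri[len(ns):]
                if local and all(c.isalnum() or c in "_-." for c in local):
                    return f"{prefix}:{local}"
        return f"<{uri}>"
    if isinstance(node, Literal):
        if node.datatype is not None and node.datatype.endswith("integer"):
            return str(int(node))
        lang = f"@{node.language}" if node.language else ""
        return f'"{_escape(str(node))}"{lang}'
    raise SchemaError(f"blank nodes are not allowed in this graph: {node!r}")


def turtle_string(kb: KnowledgeBase) -> str:
    """Serialize a KnowledgeBase as Turtle with fully deterministic
    triple ordering: equal knowledge bases yield byte-identical text."""
    kb.check_integrity()
    # reified edges are keyed by URI on disk; two edge values that mint
    # the same URI (e.g. same NTM-disorder pair with different reference
    # sets, as a merge can produce) cannot be serialized faithfully
    for edges, what in ((kb.statements, "statement"), (kb.relationships, "relationship")):
        uris = [e.uri for e in edges]
        if len(uris) != len(set(uris)):
            raise SchemaError(
                f"cannot serialize: multiple distinct {what}s share a URI; "
                f"merge or deduplicate them first"
            )
    graph = vocab.kb_to_graph(kb, include_tbox=True)
    # longest namespace first so resource prefixes win over the base
    prefixes = sorted(vocab.PREFIXES.items(), key=lambda kv: -len(kv[1]))
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(vocab.PREFIXES.items())]
    lines.append("")
    triples = sorted(
        (_term(s, prefixes), _term(p, prefixes), _term(o, prefixes))
        for s, p, o in graph
    )
    lines.extend(f"{s} {p} {o} ." for s, p, o in triples)
    return "\n".join(lines) + "\n"


def write_turtle(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(turtle_string(kb), encoding="utf-8")


@dataclass
class TurtleLoadReport:
    """Triples outside the project vocabulary, preserved on load."""

    extra_triples: list[tuple] = field(default_factory=list)

    @property
    def n_extras(self) -> int:
        return len(self.extra_triples)


def read_turtle(
    path: str | Path | None = None, *, data: str | None = None
) -> tuple[KnowledgeBase, TurtleLoadReport]:
    """Parse a Turtle file back into a KnowledgeBase.

    Unknown-vocabulary triples are preserved in the returned
    :class:`TurtleLoadReport` rather than rejected, so third-party
    annotations survive a load. Structural defects (a statement without a
    reference, an edge pointing at an undeclared resource) raise
    :class:`SchemaError`.
    """
    graph = Graph()
    if data is not None:
        graph.parse(data=data, format="turtle")
    else:
        graph.parse(str(path), format="turtle")

    V = vocab.CLASSES
    P = vocab.PROPERTIES
    kb = KnowledgeBase()

    kind_by_class = {V[k.class_name]: k for k in EntityKind}
    entity_by_uri: dict[URIRef, EntityRecord] = {}
    for cls_uri, kind in kind_by_class.items():
        for subj in sorted(graph.subjects(RDF.type, cls_uri)):
            labels = tuple(
                sorted(
                    (str(o), o.language or "")
                    for o in graph.objects(subj, RDFS.label)
                    if isinstance(o, Literal)
                )
            )
            mappings = _extract_mappings(graph, subj)
            local_id = str(subj).rsplit("/", 1)[-1]
            try:
                record = EntityRecord(kind, local_id, labels, mappings)
            except SchemaError as exc:
                raise SchemaError(f"invalid entity {subj}: {exc}") from exc
            entity_by_uri[subj] = kb.add_entity(record)

    ref_by_uri: dict[URIRef, Reference] = {}
    for subj in sorted(graph.subjects(RDF.type, V["Reference"])):
        label = _one_literal(graph, subj, RDFS.label, "Reference", "label")
        pmid = _one_literal(graph, subj, P["pmid"], "Reference", "pmid")
        level = _one_literal(graph, subj, P["evidenceLevel"], "Reference", "evidenceLevel")
        ref_by_uri[subj] = kb.add_reference(
            Reference(label=str(label), pmid=int(pmid), level=validate_level(str(level)))
        )

    for subj in sorted(graph.subjects(RDF.type, V["Statement"])):
        microbe = _one_resource(graph, subj, P["hasMicrobe"], entity_by_uri, "Statement")
        ntm = _one_resource(graph, subj, P["hasNeurotransmitter"], entity_by_uri, "Statement")
        ref = _one_resource(graph, subj, P["hasReference"], ref_by_uri, "Statement")
        direction = _one_literal(graph, subj, P["direction"], "Statement", "direction")
        kb.add_statement(Statement(microbe, ntm, Direction(str(direction)), ref))

    for subj in sorted(graph.subjects(RDF.type, V["Relationship"])):
        ntm = _one_resource(graph, subj, P["hasNeurotransmitter"], entity_by_uri, "Relationship")
        disorder = _one_resource(graph, subj, P["hasDisorder"], entity_by_uri, "Relationship")
        refs = []
        for obj in graph.objects(subj, P["hasReference"]):
            if obj not in ref_by_uri:
                raise SchemaError(f"relationship {subj} points at undeclared reference {obj}")
            refs.append(ref_by_uri[obj])
        if not refs:
            raise SchemaError(f"relationship {subj} has no reference")
        kb.add_relationship(Relationship(ntm, disorder, tuple(refs)))

    kb.check_integrity()

    known = set(vocab.kb_to_graph(kb, include_tbox=True))
    report = TurtleLoadReport(extra_triples=sorted(set(graph) - known))
    return kb, report


def _extract_mappings(graph: Graph, subj: URIRef) -> ExternalMappings | None:
    P = vocab.PROPERTIES
    cui = next((str(o) for o in graph.objects(subj, P["cui"])), None)
    mesh = next((str(o) for o in graph.objects(subj, P["meshId"])), None)
    compound = next((str(o) for o in graph.objects(subj, P["keggCompound"])), None)
    pathways = tuple(sorted(str(o) for o in graph.objects(subj, P["keggPathway"])))
    if cui is None and mesh is None and compound is None and not pathways:
        return None
    return ExternalMappings(cui, mesh, compound, pathways)


def _one_literal(graph: Graph, subj, pred, cls: str, name: str):
    values = list(graph.objects(subj, pred))
    if len(values) != 1:
        raise SchemaError(
            f"{cls} {subj} must carry exactly one {name}, found {len(values)}"
        )
    return values[0]


def _one_resource(graph: Graph, subj, pred, table: dict, cls: str):
    values = list(graph.objects(subj, pred))
    if len(values) != 1:
        raise SchemaError(
            f"{cls} {subj} must carry exactly one {pred.rsplit('#', 1)[-1]}, "
            f"found {len(values)}"
        )
    obj = values[0]
    if obj not in table:
        raise SchemaError(f"{cls} {subj} points at undeclared resource {obj}")
    return table[obj]
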