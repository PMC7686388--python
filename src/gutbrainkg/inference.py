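"""The three matchmaker query patterns over the knowledge graph.

Neurotransmitters act as the matchmaker hop between gut microbes and
mental disorders: a microbe that modulates a neurotransmitter which is
in turn associated with a disorder yields an implicit microbe-disorder
link, with the modulation statement's literature reference as the
provenance of each result row.

Three entry points mirror the three directions users ask from:

``by_microbe``
    given one microbe and a set of disorders of interest, list the
    neurotransmitter routes (the disorder patterns are UNION'd, and
    every disorder reached through the same statement is reported on one
    row).

``by_neurotransmitter``
    given one neurotransmitter, list every microbe that modulates it and
    every disorder it associates with, one row per (statement, disorder).

``by_disorder``
    given one disorder and a set of neurotransmitters that must ALL be
    modulated, list (microbe, reference) pairs where a single reference
    supports the modulation statement for every requested
    neurotransmitter (intersection via FILTER EXISTS; binding the same
    reference across the statements is what keeps one Ref/PMID column
    per row meaningful).

Each query runs twice in testing: as rendered SPARQL executed by rdflib
over the materialized RDF graph (:func:`run_query`), and as a direct
relational join over the in-memory model (:func:`native_join`), which
serves as the independent oracle for the SPARQL path.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from . import vocab
from .schema_model import (
    Direction,
    EntityKind,
    EvidenceLevel,
    KnowledgeBase,
    validate_level,
)

__all__ = [
    "QueryMode",
    "QuerySpec",
    "QuerySpecError",
    "ResultRow",
    "render_sparql",
    "run_query",
    "native_join",
    "infer_microbe_disorder_pairs",
    "MicrobeDisorderPair",
    "result_header",
    "rows_to_tsv",
]


class QuerySpecError(ValueError):
    """The query specification is internally inconsistent."""


class QueryMode(str, enum.Enum):
    BY_MICROBE = "by_microbe"
    BY_NEUROTRANSMITTER = "by_neurotransmitter"
    BY_DISORDER = "by_disorder"


@dataclass(frozen=True)
class QuerySpec:
    """Parameters of one matchmaker query.

    ``level_filter`` is a set-membership predicate over evidence levels
    (e.g. ``{"C"}`` for exactly level C, ``{"A", "B"}`` for "B or
    better"), applied to the statement's reference. ``language`` selects
    the label language of returned rows.
    """

    mode: QueryMode
    microbe: str | None = None
    neurotransmitters: tuple[str, ...] = ()
    disorders: tuple[str, ...] = ()
    level_filter: frozenset[EvidenceLevel] | None = None
    language: str = "en"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", QueryMode(self.mode))
        object.__setattr__(self, "neurotransmitters", tuple(self.neurotransmitters))
        object.__setattr__(self, "disorders", tuple(self.disorders))
        if self.level_filter is not None:
            object.__setattr__(
                self,
                "level_filter",
                frozenset(validate_level(lv) for lv in self.level_filter),
            )
        if self.mode is QueryMode.BY_MICROBE:
            if not self.microbe:
                raise QuerySpecError("by_microbe mode requires a microbe label")
        elif self.mode is QueryMode.BY_NEUROTRANSMITTER:
            if len(self.neurotransmitters) != 1:
                raise QuerySpecError(
                    "by_neurotransmitter mode requires exactly one neurotransmitter"
                )
        elif self.mode is QueryMode.BY_DISORDER:
            if len(self.disorders) != 1:
                raise QuerySpecError("by_disorder mode requires exactly one disorder")
            if not self.neurotransmitters:
                raise QuerySpecError(
                    "by_disorder mode requires at least one neurotransmitter"
                )


@dataclass(frozen=True)
class ResultRow:
    """One row of a matchmaker query result.

    Field population follows the query direction: ``direction`` is
    reported only by the neurotransmitter-based query; the microbe-based
    query packs every disorder reached through one statement into
    ``disorder_labels``; the disorder-based query reports all requested
    neurotransmitters in ``neurotransmitter_labels``.
    """

    microbe_label: str
    neurotransmitter_labels: tuple[str, ...]
    direction: Direction | None
    reference_label: str
    pmid: int
    level: EvidenceLevel
    disorder_labels: tuple[str, ...]

    @property
    def sort_key(self):
        # strongest evidence first, then pmid, then labels
        return (
            self.level.rank,
            self.pmid,
            self.microbe_label,
            self.neurotransmitter_labels,
            self.disorder_labels,
        )


# ---------------------------------------------------------------------------
# SPARQL rendering


def _prefix_block() -> str:
    return "\n".join(
        f"PREFIX {p}: <{ns}>" for p, ns in sorted(vocab.PREFIXES.items())
    )


def _literal(text: str, language: str) -> str:
    escaped = text.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"@{language}'


def _level_filter_clause(levels: frozenset[EvidenceLevel] | None) -> str:
    if levels is None:
        return ""
    values = sorted(lv.value for lv in levels)
    if len(values) == 1:
        return f'  FILTER ( ?level = "{values[0]}" )\n'
    joined = ", ".join(f'"{v}"' for v in values)
    return f"  FILTER ( ?level IN ({joined}) )\n"


_STATEMENT_BLOCK = """\
  ?stmt rdf:type gb:Statement ;
        gb:hasMicrobe ?gm ;
        gb:hasNeurotransmitter ?ntm ;
        gb:direction ?direction ;
        gb:hasReference ?ref .
  ?ref rdfs:label ?refLabel ;
       gb:pmid ?pmid ;
       gb:evidenceLevel ?level .
"""


def render_sparql(spec: QuerySpec) -> str:
    """Render a query specification as SPARQL 1.1 SELECT DISTINCT text.

    The rendered text is what :func:`run_query` executes and is worth
    saving alongside results for auditability.
    """
    lang = spec.language
    if spec.mode is QueryMode.BY_MICROBE:
        body = _STATEMENT_BLOCK
        body += f"  ?gm rdfs:label {_literal(spec.microbe, lang)} .\n"
        body += "  ?gm rdfs:label ?gmLabel .\n  ?ntm rdfs:label ?ntmLabel .\n"
        body += (
            "  ?rel rdf:type gb:Relationship ;\n"
            "       gb:hasNeurotransmitter ?ntm ;\n"
            "       gb:hasDisorder ?md .\n"
        )
        if spec.disorders:
            branches = [
                f"{{ ?md rdfs:label {_literal(d, lang)} . }}" for d in spec.disorders
            ]
            body += "  " + "\n  UNION\n  ".join(branches) + "\n"
        body += "  ?md rdfs:label ?mdLabel .\n"
        body += (
            f'  FILTER ( LANG(?gmLabel) = "{lang}" )\n'
            f'  FILTER ( LANG(?ntmLabel) = "{lang}" )\n'
            f'  FILTER ( LANG(?mdLabel) = "{lang}" )\n'
        )
        body += _level_filter_clause(spec.level_filter)
        select = "?gmLabel ?ntmLabel ?refLabel ?pmid ?level ?mdLabel"

    elif spec.mode is QueryMode.BY_NEUROTRANSMITTER:
        body = _STATEMENT_BLOCK
        body += f"  ?ntm rdfs:label {_literal(spec.neurotransmitters[0], lang)} .\n"
        body += "  ?gm rdfs:label ?gmLabel .\n  ?ntm rdfs:label ?ntmLabel .\n"
        body += (
            "  ?rel rdf:type gb:Relationship ;\n"
            "       gb:hasNeurotransmitter ?ntm ;\n"
            "       gb:hasDisorder ?md .\n"
            "  ?md rdfs:label ?mdLabel .\n"
        )
        body += (
            f'  FILTER ( LANG(?gmLabel) = "{lang}" )\n'
            f'  FILTER ( LANG(?ntmLabel) = "{lang}" )\n'
            f'  FILTER ( LANG(?mdLabel) = "{lang}" )\n'
        )
        body += _level_filter_clause(spec.level_filter)
        select = "?gmLabel ?ntmLabel ?direction ?refLabel ?pmid ?level ?mdLabel"

    else:  # BY_DISORDER
        first, *rest = spec.neurotransmitters
        body = _STATEMENT_BLOCK
        body += f"  ?ntm rdfs:label {_literal(first, lang)} .\n"
        body += "  ?gm rdfs:label ?gmLabel .\n"
        body += (
            "  ?rel rdf:type gb:Relationship ;\n"
            "       gb:hasNeurotransmitter ?ntm ;\n"
            "       gb:hasDisorder ?md .\n"
        )
        body += f"  ?md rdfs:label {_literal(spec.disorders[0], lang)} .\n"
        body += "  ?md rdfs:label ?mdLabel .\n"
        for i, ntm_label in enumerate(rest, start=2):
            body += (
                "  FILTER EXISTS {\n"
                f"    ?stmt{i} rdf:type gb:Statement ;\n"
                f"          gb:hasMicrobe ?gm ;\n"
                f"          gb:hasNeurotransmitter ?ntm{i} ;\n"
                f"          gb:hasReference ?ref .\n"
                f"    ?ntm{i} rdfs:label {_literal(ntm_label, lang)} .\n"
                f"    ?rel{i} rdf:type gb:Relationship ;\n"
                f"         gb:hasNeurotransmitter ?ntm{i} ;\n"
                f"         gb:hasDisorder ?md .\n"
                "  }\n"
            )
        body += (
            f'  FILTER ( LANG(?gmLabel) = "{lang}" )\n'
            f'  FILTER ( LANG(?mdLabel) = "{lang}" )\n'
        )
        body += _level_filter_clause(spec.level_filter)
        select = "?gmLabel ?refLabel ?pmid ?level ?mdLabel"

    return (
        f"{_prefix_block()}\n\n"
        f"SELECT DISTINCT {select}\n"
        f"WHERE {{\n{body}}}\n"
    )


# ---------------------------------------------------------------------------
# Execution


def _canonicalize(spec: QuerySpec, kb: KnowledgeBase) -> QuerySpec:
    """Resolve spec labels to the knowledge base's canonical entity
    labels (exact case-insensitive match); labels that resolve to
    nothing are kept verbatim and simply match no rows."""

    def canon(kind: EntityKind, label: str) -> str:
        entity = kb.find_entity(kind, label)
        if entity is None:
            return label
        try:
            return entity.label(spec.language)
        except KeyError:
            # no label in the requested language: keep the input verbatim,
            # which matches no rows in that language
            return label

    return replace(
        spec,
        microbe=canon(EntityKind.GUT_MICROBIOTA, spec.microbe) if spec.microbe else None,
        neurotransmitters=tuple(
            canon(EntityKind.NEUROTRANSMITTER, n) for n in spec.neurotransmitters
        ),
        disorders=tuple(canon(EntityKind.MENTAL_DISORDER, d) for d in spec.disorders),
    )


def run_query(kb: KnowledgeBase, spec: QuerySpec) -> list[ResultRow]:
    """Execute the rendered SPARQL over the RDF materialization of the
    knowledge base and assemble deterministic, DISTINCT result rows."""
    spec = _canonicalize(spec, kb)
    graph = vocab.kb_to_graph(kb, include_tbox=True)
    bindings = graph.query(render_sparql(spec))

    rows: set[ResultRow] = set()
    if spec.mode is QueryMode.BY_MICROBE:
        grouped: dict[tuple, set[str]] = {}
        for b in bindings:
            key = (str(b.gmLabel), str(b.ntmLabel), str(b.refLabel), int(b.pmid), str(b.level))
            grouped.setdefault(key, set()).add(str(b.mdLabel))
        for (gm, ntm, ref, pmid, level), mds in grouped.items():
            rows.add(
                ResultRow(gm, (ntm,), None, ref, pmid, validate_level(level), tuple(sorted(mds)))
            )
    elif spec.mode is QueryMode.BY_NEUROTRANSMITTER:
        for b in bindings:
            rows.add(
                ResultRow(
                    str(b.gmLabel),
                    (str(b.ntmLabel),),
                    Direction(str(b.direction)),
                    str(b.refLabel),
                    int(b.pmid),
                    validate_level(str(b.level)),
                    (str(b.mdLabel),),
                )
            )
    else:
        for b in bindings:
            rows.add(
                ResultRow(
                    str(b.gmLabel),
                    spec.neurotransmitters,
                    None,
                    str(b.refLabel),
                    int(b.pmid),
                    validate_level(str(b.level)),
                    (str(b.mdLabel),),
                )
            )
    return sorted(rows, key=lambda r: r.sort_key)


def native_join(kb: KnowledgeBase, spec: QuerySpec) -> list[ResultRow]:
    """The same query computed by direct iteration over the in-memory
    statements and relationships — the independent oracle for
    :func:`run_query`."""
    spec = _canonicalize(spec, kb)
    lang = spec.language
    admit = (
        (lambda lv: True)
        if spec.level_filter is None
        else (lambda lv: lv in spec.level_filter)
    )

    def lbl(entity) -> str | None:
        try:
            return entity.label(lang)
        except KeyError:
            return None

    rows: set[ResultRow] = set()

    if spec.mode is QueryMode.BY_MICROBE:
        wanted = set(spec.disorders) or None
        grouped: dict[tuple, set[str]] = {}
        for stmt in kb.statements:
            if lbl(stmt.microbe) != spec.microbe or not admit(stmt.reference.level):
                continue
            for rel in kb.relationships:
                if rel.neurotransmitter != stmt.neurotransmitter:
                    continue
                md = lbl(rel.disorder)
                if md is None or (wanted is not None and md not in wanted):
                    continue
                gm, ntm = lbl(stmt.microbe), lbl(stmt.neurotransmitter)
                if gm is None or ntm is None:
                    continue
                key = (gm, ntm, stmt.reference.label, stmt.reference.pmid, stmt.reference.level)
                grouped.setdefault(key, set()).add(md)
        for (gm, ntm, ref, pmid, level), mds in grouped.items():
            rows.add(ResultRow(gm, (ntm,), None, ref, pmid, level, tuple(sorted(mds))))

    elif spec.mode is QueryMode.BY_NEUROTRANSMITTER:
        target = spec.neurotransmitters[0]
        for stmt in kb.statements:
            if lbl(stmt.neurotransmitter) != target or not admit(stmt.reference.level):
                continue
            for rel in kb.relationships:
                if rel.neurotransmitter != stmt.neurotransmitter:
                    continue
                gm, ntm, md = lbl(stmt.microbe), lbl(stmt.neurotransmitter), lbl(rel.disorder)
                if None in (gm, ntm, md):
                    continue
                rows.add(
                    ResultRow(
                        gm,
                        (ntm,),
                        stmt.direction,
                        stmt.reference.label,
                        stmt.reference.pmid,
                        stmt.reference.level,
                        (md,),
                    )
                )

    else:  # BY_DISORDER
        disorder = spec.disorders[0]
        requested = spec.neurotransmitters
        # every requested neurotransmitter must itself associate with the disorder
        linked = {
            lbl(rel.neurotransmitter)
            for rel in kb.relationships
            if lbl(rel.disorder) == disorder
        }
        if all(n in linked for n in requested):
            # index statements by (microbe, reference) -> modulated ntm labels
            by_pair: dict[tuple, set[str]] = {}
            stmt_meta: dict[tuple, tuple] = {}
            for stmt in kb.statements:
                gm, ntm = lbl(stmt.microbe), lbl(stmt.neurotransmitter)
                if gm is None or ntm is None:
                    continue
                pair = (gm, stmt.reference.pmid)
                by_pair.setdefault(pair, set()).add(ntm)
                stmt_meta[pair] = (stmt.reference.label, stmt.reference.level)
            for (gm, pmid), ntms in by_pair.items():
                ref_label, level = stmt_meta[(gm, pmid)]
                if all(n in ntms for n in requested) and admit(level):
                    rows.add(
                        ResultRow(gm, requested, None, ref_label, pmid, level, (disorder,))
                    )

    return sorted(rows, key=lambda r: r.sort_key)


# ---------------------------------------------------------------------------
# Implicit microbe-disorder pairs


@dataclass(frozen=True)
class MicrobeDisorderPair:
    """An implicit microbe-disorder association inferred through shared
    neurotransmitters, with the strongest supporting evidence level and
    the number of distinct evidence chains (statement + relationship
    sharing the neurotransmitter)."""

    microbe_label: str
    disorder_label: str
    best_level: EvidenceLevel
    n_chains: int


def infer_microbe_disorder_pairs(
    kb: KnowledgeBase,
    level_filter: Iterable[EvidenceLevel | str] | None = None,
    *,
    language: str = "en",
) -> list[MicrobeDisorderPair]:
    """Enumerate every implicit (microbe, disorder) pair connected by at
    least one shared neurotransmitter.

    A chain's strength is its statement reference's evidence level (the
    modulation study is the limiting evidence; relationship references
    may include flagged placeholders). ``level_filter`` restricts the
    chains considered, as in :class:`QuerySpec`.
    """
    admitted = (
        None if level_filter is None else {validate_level(lv) for lv in level_filter}
    )
    chains: dict[tuple[str, str], list[EvidenceLevel]] = {}
    for stmt in kb.statements:
        level = stmt.reference.level
        if admitted is not None and level not in admitted:
            continue
        for rel in kb.relationships:
            if rel.neurotransmitter != stmt.neurotransmitter:
                continue
            try:
                gm = stmt.microbe.label(language)
                md = rel.disorder.label(language)
            except KeyError:
                continue
            chains.setdefault((gm, md), []).append(level)
    pairs = [
        MicrobeDisorderPair(gm, md, min(levels, key=lambda lv: lv.rank), len(levels))
        for (gm, md), levels in chains.items()
    ]
    return sorted(pairs, key=lambda p: (p.best_level.rank, p.microbe_label, p.disorder_label))


# ---------------------------------------------------------------------------
# Tabular export

_HEADERS = {
    QueryMode.BY_MICROBE: ("GM", "NTM", "Ref", "PMID", "Level", "MD"),
    QueryMode.BY_NEUROTRANSMITTER: ("GM", "NTM", "Modulate", "Level", "Ref", "PMID", "MD"),
    QueryMode.BY_DISORDER: ("GM", "NTM", "Level", "Ref", "PMID", "MD"),
}


def result_header(mode: QueryMode) -> tuple[str, ...]:
    return _HEADERS[QueryMode(mode)]


def rows_to_tsv(mode: QueryMode, rows: Sequence[ResultRow]) -> str:
    """Render result rows in the tabular column layout of the query mode
    (multi-valued label columns join with ' | ')."""
    mode = QueryMode(mode)
    lines = ["\t".join(result_header(mode))]
    for r in rows:
        ntm = " | ".join(r.neurotransmitter_labels)
        md = " | ".join(r.disorder_labels)
        if mode is QueryMode.BY_MICROBE:
            cells = (r.microbe_label, ntm, r.reference_label, str(r.pmid), r.level.value, md)
        elif mode is QueryMode.BY_NEUROTRANSMITTER:
            cells = (
                r.microbe_label,
                ntm,
                r.direction.value if r.direction else "",
                r.level.value,
                r.reference_label,
                str(r.pmid),
                md,
            )
        else:
            cells = (r.microbe_label, ntm, r.level.value, r.reference_label, str(r.pmid), md)
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
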