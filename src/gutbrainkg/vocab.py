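"""RDF vocabulary (TBox terms) and the KnowledgeBase -> rdflib.Graph
materialization shared by serialization and query execution."""

from __future__ import annotations

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .schema_model import (
    BASE_NAMESPACE,
    VOCAB,
    EntityKind,
    KnowledgeBase,
)

__all__ = [
    "CLASSES",
    "PROPERTIES",
    "PREFIXES",
    "tbox_graph",
    "kb_to_graph",
]

#: The seven classes: four entity classes and three relation classes.
CLASSES: dict[str, URIRef] = {
    name: VOCAB[name]
    for name in (
        "GutMicrobiota",
        "Neurotransmitter",
        "MentalDisorder",
        "KEGGPathway",
        "Statement",
        "Relationship",
        "Reference",
    )
}

#: Edge and attribute properties. Entity display names use rdfs:label.
PROPERTIES: dict[str, URIRef] = {
    name: VOCAB[name]
    for name in (
        "hasMicrobe",
        "hasNeurotransmitter",
        "hasDisorder",
        "hasReference",
        "direction",
        "evidenceLevel",
        "pmid",
        "cui",
        "meshId",
        "keggCompound",
        "keggPathway",
    )
}

_KIND_CLASS_URI = {kind: CLASSES[kind.class_name] for kind in EntityKind}

#: Prefix table used for deterministic Turtle output and SPARQL rendering.
PREFIXES: dict[str, str] = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "gb": str(VOCAB),
    "gm": BASE_NAMESPACE + "gm/",
    "ntm": BASE_NAMESPACE + "ntm/",
    "md": BASE_NAMESPACE + "md/",
    "pw": BASE_NAMESPACE + "pw/",
    "ref": BASE_NAMESPACE + "ref/",
    "stmt": BASE_NAMESPACE + "stmt/",
    "rel": BASE_NAMESPACE + "rel/",
}


def _bind(graph: Graph) -> Graph:
    for prefix, ns in PREFIXES.items():
        graph.bind(prefix, Namespace(ns), replace=True)
    return graph


def tbox_graph() -> Graph:
    """The terminological box: class and property declarations."""
    g = _bind(Graph())
    for name, uri in CLASSES.items():
        g.add((uri, RDF.type, RDFS.Class))
        g.add((uri, RDFS.label, Literal(name, lang="en")))
    for name, uri in PROPERTIES.items():
        g.add((uri, RDF.type, RDF.Property))
        g.add((uri, RDFS.label, Literal(name, lang="en")))
    return g


def kb_to_graph(kb: KnowledgeBase, *, include_tbox: bool = True) -> Graph:
    """Materialize a KnowledgeBase as an RDF graph.

    Statements and relationships are reified resources (never plain
    triples, never blank nodes) so each can carry direction, reference,
    and level provenance, and so graph equality is exact.
    """
    g = tbox_graph() if include_tbox else _bind(Graph())

    for entity in kb.entities.values():
        uri = URIRef(entity.uri)
        g.add((uri, RDF.type, _KIND_CLASS_URI[entity.kind]))
        for text, lang in entity.labels:
            g.add((uri, RDFS.label, Literal(text, lang=lang)))
        m = entity.mappings
        if m is not None:
            if m.umls_cui:
                g.add((uri, PROPERTIES["cui"], Literal(m.umls_cui)))
            if m.mesh_id:
                g.add((uri, PROPERTIES["meshId"], Literal(m.mesh_id)))
            if m.kegg_compound:
                g.add((uri, PROPERTIES["keggCompound"], Literal(m.kegg_compound)))
            for pw in m.kegg_pathways:
                g.add((uri, PROPERTIES["keggPathway"], Literal(pw)))

    for ref in kb.references.values():
        uri = URIRef(ref.uri)
        g.add((uri, RDF.type, CLASSES["Reference"]))
        g.add((uri, RDFS.label, Literal(ref.label)))
        g.add((uri, PROPERTIES["pmid"], Literal(ref.pmid)))
        g.add((uri, PROPERTIES["evidenceLevel"], Literal(ref.level.value)))

    for stmt in kb.statements:
        uri = URIRef(stmt.uri)
        g.add((uri, RDF.type, CLASSES["Statement"]))
        g.add((uri, PROPERTIES["hasMicrobe"], URIRef(stmt.microbe.uri)))
        g.add((uri, PROPERTIES["hasNeurotransmitter"], URIRef(stmt.neurotransmitter.uri)))
        g.add((uri, PROPERTIES["direction"], Literal(stmt.direction.value)))
        g.add((uri, PROPERTIES["hasReference"], URIRef(stmt.reference.uri)))

    for rel in kb.relationships:
        uri = URIRef(rel.uri)
        g.add((uri, RDF.type, CLASSES["Relationship"]))
        g.add((uri, PROPERTIES["hasNeurotransmitter"], URIRef(rel.neurotransmitter.uri)))
        g.add((uri, PROPERTIES["hasDisorder"], URIRef(rel.disorder.uri)))
        for ref in rel.references:
            g.add((uri, PROPERTIES["hasReference"], URIRef(ref.uri)))

    return g
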