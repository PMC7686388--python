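# Methods

## The knowledge model

The store is a small description-logic-style knowledge base split into a
TBox (7 classes — the four entity kinds plus Statement, Relationship and
Reference — and the edge/attribute properties) and an ABox of
individuals. Modulation statements and disorder associations are
*reified*: each is a named resource carrying its own properties
(direction, evidence level via its reference, PMID provenance) rather
than a bare triple. No blank nodes are used anywhere, so two graphs are
equal exactly when their triple sets are equal, which the round-trip and
merge contracts test directly.

Assumptions baked into the model:

- **Flat taxonomy.** Microbe taxa are flat nodes; a genus (e.g.
  *Clostridium*) and a species (e.g. *Escherichia coli*) are peers with
  no hierarchy between them. Nothing is inferred from taxonomic
  containment.
- **Evidence level is a property of the reference**, not of the edge
  that cites it: the grade reflects the study's design, so a reference
  reused by several statements carries one level. A PMID appearing with
  two different levels anywhere in the corpus is a hard curation error
  (never last-write-wins), because evidence grading must stay auditable.
- **`modulate` is an explicit value**, not a missing one: curated
  sources often assert modulation without resolving the sign, and a
  blank direction cell in a curation file means exactly that.
- **References are deduplicated globally by PMID**; the citation label
  ("Barrett 2012") is display-only.

## Identifiers and serialization

Entity URIs are minted deterministically from a project-owned base
namespace, a kind segment (`gm/`, `ntm/`, `md/`, `pw/`), and a slug
(lowercase, non-alphanumeric runs collapsed to `_`). Statement URIs key
on (microbe, neurotransmitter, PMID); relationship URIs on
(neurotransmitter, disorder). The base namespace is a single module
constant, intentionally under an example domain: graphs meant for
publication should re-mint under the publisher's authority.

Turtle output is produced by a deliberately simple line-per-triple
serializer with a fixed prefix table and fully sorted triples, so that
equal knowledge bases produce byte-identical files — a property used for
reproducible builds and cheap diffing, and one that general-purpose
serializers do not guarantee. Parsing uses rdflib; triples outside the
project vocabulary are preserved in a side report instead of rejected,
so third-party annotations survive a load.

One consequence of pair-keyed relationship URIs: a merge can legally
hold two relationship values with the same (neurotransmitter, disorder)
pair but different reference sets, and such a graph cannot be written to
Turtle faithfully. Serialization detects the URI collision and raises
rather than silently conflating the edges.

## Query semantics

All three modes join statements to relationships on the shared
neurotransmitter; the reference shown in every result row is the
*statement's* reference (the modulation study), which is the limiting
evidence of the two-hop chain.

- `by_microbe`: the requested disorders are alternatives (UNION). The
  raw SPARQL solutions are grouped per statement, so one row carries
  every requested disorder reachable through that statement's
  neurotransmitter — matching how a curator reads the result ("this
  reference links the microbe to both disorders via GABA").
- `by_neurotransmitter`: one row per (statement, disorder); the
  modulation direction is reported in this mode only.
- `by_disorder`: the requested neurotransmitters are conjunctive, and
  the intersection binds the **same reference** across all modulation
  statements (`FILTER EXISTS` per additional neurotransmitter with the
  shared `?gm` and `?ref`). This is deliberately stricter than "the
  microbe modulates each neurotransmitter, somehow": it keeps a single
  Ref/PMID/Level column per row meaningful, and it is the reading under
  which a microbe supported by two independent single-neurotransmitter
  studies does *not* appear. A free cross-product over references would
  instead duplicate rows per reference combination.
  (The curated corpus this package grew from describes this mode
  inconsistently in one place — naming serotonin where the worked
  result uses norepinephrine; the dopamine + norepinephrine semantics
  implemented here are the ones the worked result follows.)

`level_filter` is a set-membership predicate over {A..E} rather than a
threshold, which expresses both "exactly C" and "B or better". Row order
is an artifact decision (the upstream query language leaves it
unspecified): strongest evidence level first, then ascending PMID, then
labels — fully deterministic.

Every SPARQL execution is mirrored by `native_join`, an independent
relational implementation of the same semantics over the in-memory
model. The test suite asserts row-set equality between the two engines
on the seed graph and on twenty random synthetic graphs in every mode;
the two paths share no query code.

Entity lookup in queries and mapping attachment is exact
case-insensitive English-label matching, never fuzzy: silently merging
near-identical taxon names would be worse than leaving duplicates
visible.

## Seed dataset

The bundled seed data is the desk-scale curated inventory: 20 modulation
statements over 8 taxa backed by 7 citable PMIDs, 12
neurotransmitter–disorder relationships, and the complete rosters of 6
neurotransmitters and 10 mental disorders (several roster members occur
in no edge; they exist so the schema is complete). Two statements
(L. plantarum increasing serotonin and dopamine) derive from narrative
text without a printed PMID; they carry a flagged placeholder reference
(level E, PMID in the reserved sentinel range ≥ 900 000 000) and are
excluded from citable-PMID counts. The 12 relationships likewise carry
placeholder references, because the curated source records which
associations exist but not their citations. Placeholders are real graph
citizens — queries demonstrably filter them out by level — but nothing
citable is fabricated.

Genus-level "and/or" production claims (Bacillus/Escherichia producing
dopamine and/or norepinephrine) were *not* curated as genus statements:
"and/or" is ambiguous and the species-level facts already cover the
ground.

## Synthetic generator

`generate_synthetic(FixtureConfig(...))` emulates a sparse tripartite
evidence graph: Bernoulli sampling per (microbe, neurotransmitter) pair
at `statement_density` and per (neurotransmitter, disorder) pair at
`relationship_density`, directions uniform, levels drawn from
`level_weights`, and fresh unique PMIDs (each seed owns a disjoint PMID
block so fixtures from different seeds merge cleanly). Defaults mirror
the curated corpus's scale (45 taxa × 6 neurotransmitters × 10
disorders, sparse statements, levels concentrated in B–D since
randomized designs are rare in this literature).

What the generator does **not** emulate — and therefore what passing
property tests do not establish about real data: references shared
across multiple statements (every synthetic statement gets its own
PMID, so multi-neurotransmitter intersections are only exercised
non-trivially by the seed data), multilingual labels, label noise and
near-duplicate taxa, and any correlation structure between which
microbes modulate which neurotransmitters. The synthetic suites test
structural contracts (round-trip, merge algebra, engine equivalence,
filter monotonicity), not biological realism.

Test problem sizes: property suites run on twenty random graphs of
6 × 4 × 5 entities at densities 0.35/0.45 — large enough that every
query mode returns rows on most fixtures, small enough that the whole
suite is quick on one CPU. The density-calibration check uses 200 seeds
of a 10 × 5 grid and a 3-standard-error band on the mean statement
count.

## Numerical / degenerate-input choices

- Level comparison is the index order on A..E; the exhaustive 25-pair
  (and 125-triple) check fixes antisymmetry and transitivity.
- Curation validation is total: all violations in a file are collected
  and reported with line and column, not just the first.
- Empty inputs are legal everywhere: an empty KB serializes to a
  TBox-only Turtle file, queries on it return empty lists, and the empty
  KB is the merge identity.
- Labels that slug to the empty string (pure punctuation) are rejected
  at URI-minting time rather than producing colliding URIs.

## Limitations

- No OWL reasoning or entailment; the only inference is the fixed
  two-hop matchmaker join.
- No live UMLS/MeSH/KEGG lookups; external identifiers arrive via
  curation files and are validated only syntactically.
- Coverage is whatever the curation files contain; query results are
  correct relative to the curated corpus, not complete relative to the
  literature.
- The implicit-pair lister reports chain counts and best evidence level,
  not calibrated association scores; it is a hypothesis enumerator.
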