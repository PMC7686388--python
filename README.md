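# gutbrainkg

A toolkit for building and querying a knowledge graph of the
**microbiota–gut–brain axis**: gut microbes modulate neurotransmitter
levels, and neurotransmitters are implicated in mental disorders, so
neurotransmitters act as the *matchmaker* hop that links microbes to
disorders. The package turns tabular literature curation into an RDF
(Turtle) knowledge base with per-reference evidence grading, and answers
three families of two-hop "matchmaker" queries with full literature
provenance.

It is aimed at researchers curating microbiome–mental-health literature
who want their extracted facts in a queryable, extendable semantic store
rather than spreadsheets.

## The model

The graph has four entity classes — gut microbiota, neurotransmitter,
mental disorder, and KEGG pathway — and three relation classes, reified
as resources so each can carry provenance:

- **Statement**: `microbe --(direction ∈ {increase, decrease, modulate})--> neurotransmitter`,
  backed by exactly one **Reference** (citation label, PMID, evidence
  level A–E with A strongest, graded by study design).
- **Relationship**: `neurotransmitter --> mental disorder`, backed by
  one to five References (no duplicate PMIDs within one edge).

Entities carry multilingual labels and optional cross-references to
UMLS (CUI, `C` + 7 digits), MeSH, and KEGG (compound `C` numbers,
pathway `map` numbers). A two-hop chain *statement + relationship
sharing a neurotransmitter* is an implicit microbe–disorder link; the
query engine surfaces these with the statement's reference as evidence.

Queries run in three modes — `by_microbe`, `by_neurotransmitter`,
`by_disorder` — each rendered as SPARQL 1.1 `SELECT DISTINCT` text
(`UNION` over requested disorders, `FILTER` on label language and
evidence level, `FILTER EXISTS` for multi-neurotransmitter
intersections) and executed in-process with rdflib. An independent
relational-join implementation of the same semantics (`native_join`)
cross-checks every SPARQL result in the test suite.

## Worked example

The package ships a small seed dataset: 20 curated modulation statements
(7 distinct citable PMIDs), 12 neurotransmitter–disorder relationships,
and the full rosters of 6 neurotransmitters and 10 mental disorders.

```python
from gutbrainkg import QuerySpec, build_seed_kb, run_query
from gutbrainkg.inference import QueryMode, rows_to_tsv

kb = build_seed_kb()
spec = QuerySpec(
    mode="by_disorder",
    disorders=("Bipolar disorder",),
    neurotransmitters=("Dopamine", "Norepinephrine"),
)
print(rows_to_tsv(QueryMode.BY_DISORDER, run_query(kb, spec)), end="")
```

prints

```
GM	NTM	Level	Ref	PMID	MD
Clostridium	Dopamine | Norepinephrine	B	Asano 2012	23064760	Bipolar disorder
Bacillus mycoides	Dopamine | Norepinephrine	C	Tsavkelova 2000	10935181	Bipolar disorder
Bacillus subtilis	Dopamine | Norepinephrine	C	Tsavkelova 2000	10935181	Bipolar disorder
Escherichia coli	Dopamine | Norepinephrine	C	Tsavkelova 2000	10935181	Bipolar disorder
Proteus vulgaris	Dopamine | Norepinephrine	C	Tsavkelova 2000	10935181	Bipolar disorder
Serratia marcescens	Dopamine | Norepinephrine	C	Tsavkelova 2000	10935181	Bipolar disorder
Escherichia coli	Dopamine | Norepinephrine	C	Shishov 2009	19845286	Bipolar disorder
```

Seven rows: each is a (microbe, reference) pair where that *single*
reference supports modulation statements for **both** requested
neurotransmitters, which are in turn both associated with bipolar
disorder. *Escherichia coli* appears twice because two independent
references support it. Rows sort strongest-evidence-first, then by PMID.

The `examples/` directory walks through every capability (microbe-based
query, evidence-level filtering with the rendered SPARQL, the
intersection query above, implicit-pair enumeration, and synthetic-data
round-tripping); each script prints its results with a short reading.

## Command line

```bash
gutbrainkg build statements.tsv relationships.tsv --entities entities.tsv -o kg.ttl
gutbrainkg query kg.ttl --mode microbe --microbe "Bifidobacterium dentium" \
    --disorder "Anxiety disorders" --disorder "Depressive disorder"
gutbrainkg query kg.ttl --mode ntm --ntm Acetylcholine --level C --emit-sparql q.rq
gutbrainkg infer kg.ttl
gutbrainkg simulate --out-dir fixtures/ --seed 7
```

Curation files are tab-separated UTF-8 with a header; see the module
docstring of `gutbrainkg.curation_io` for the exact column layouts, and
`docs/methods.md` for the modelling decisions.

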