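"""Ask which microbes may relate to one disorder by modulating ALL of a
set of neurotransmitters, with the same reference supporting every
modulation statement.

Binding one shared reference across the statements keeps a single
Ref/PMID/Level provenance column per row; microbes whose dopamine and
norepinephrine evidence comes from different studies are excluded.
"""

from gutbrainkg import QuerySpec, build_seed_kb, native_join, run_query
from gutbrainkg.inference import QueryMode, rows_to_tsv

kb = build_seed_kb()
spec = QuerySpec(
    mode="by_disorder",
    disorders=("Bipolar disorder",),
    neurotransmitters=("Dopamine", "Norepinephrine"),
)
rows = run_query(kb, spec)
print(rows_to_tsv(QueryMode.BY_DISORDER, rows))

# the SPARQL path and the in-memory relational join are interchangeable
assert rows == native_join(kb, spec)
print(
    f"{len(rows)} rows; six species across three references each modulate both\n"
    "dopamine and norepinephrine, the two neurotransmitters requested for\n"
    "bipolar disorder. Note Escherichia coli appears twice - once per\n"
    "supporting reference."
)
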