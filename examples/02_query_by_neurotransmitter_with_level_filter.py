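"""Ask which microbes modulate one neurotransmitter and which disorders
that neurotransmitter touches, keeping only level-C evidence.

The evidence-level filter is a set-membership predicate on the statement
reference's A-E grade; pass e.g. {"A", "B"} for "B or better".
"""

from gutbrainkg import QuerySpec, build_seed_kb, run_query
from gutbrainkg.inference import QueryMode, render_sparql, rows_to_tsv

kb = build_seed_kb()
spec = QuerySpec(
    mode="by_neurotransmitter",
    neurotransmitters=("Acetylcholine",),
    level_filter=frozenset({"C"}),
)

print(render_sparql(spec))  # the exact SPARQL that will be executed
rows = run_query(kb, spec)
print(rows_to_tsv(QueryMode.BY_NEUROTRANSMITTER, rows))
print(
    f"{len(rows)} rows: one microbe (L. plantarum) increases acetylcholine\n"
    "(single level-C reference), and acetylcholine is associated with six\n"
    "disorders - one row per disorder."
)
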