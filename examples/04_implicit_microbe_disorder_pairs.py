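"""Enumerate every implicit microbe-disorder pair in the graph: pairs
connected by at least one statement + relationship chain sharing a
neurotransmitter.

best-level is the strongest statement evidence over all chains; chains
counts the distinct supporting chains.
"""

from gutbrainkg import build_seed_kb, infer_microbe_disorder_pairs

kb = build_seed_kb()
pairs = infer_microbe_disorder_pairs(kb)
print("GM\tMD\tBestLevel\tChains")
for p in pairs[:10]:
    print(f"{p.microbe_label}\t{p.disorder_label}\t{p.best_level.value}\t{p.n_chains}")
print(f"... {len(pairs)} pairs total")
print(
    "\nThese are hypotheses, not findings: a pair is listed whenever a\n"
    "modulation statement and a disorder association share a neurotransmitter,\n"
    "regardless of modulation direction."
)
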