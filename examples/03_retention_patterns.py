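"""Classify duplicate-retention patterns of UCNE-hosting genes.

First applies the winner / concordant / reciprocal rule to the
published per-species triplets of the DACH1 gene, then recovers the
generating scenario from synthetic winner-takes-all data.
"""
from grbcontext.published import TOP_GENES
from grbcontext.retention import classify_case, classify_pattern
from grbcontext.synth import (
    SynthConfig, cases_from_synthetic, generate_reference, hits_from_wgd,
    simulate_wgd,
)

dach1 = next(r for r in TOP_GENES if r.name == "DACH1")
print("DACH1, published per-species (a,b,c) triplets:")
for species, (a, b, c) in dach1.triplets.items():
    n = a + b + c
    print(f"  {species:>12}: {a:2d}-{b:d}-{c:d}  a/n={a / n:.2f}  -> {classify_pattern(a, b, c)}")

cfg = SynthConfig(
    n_genes=3, ucnes_per_gene=5, seed=4,
    retention_scenario="winner", retention_prob=0.9,
)
ref = generate_reference(cfg)
dup = simulate_wgd(ref, cfg)
cases = cases_from_synthetic(ref, dup, hits_from_wgd(ref, dup, score=False))
print("\nsynthetic winner-takes-all data (retention_prob=0.9):")
for case in cases:
    p = classify_case(case)
    print(f"  {p.gene_id}: ({p.a},{p.b},{p.c})  major={p.major_ortholog_id}  -> {p.label}")
print("\nA case is 'winner' when a/(a+b+c) > 0.8 (strict).")
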