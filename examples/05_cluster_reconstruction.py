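"""Reconstruct UCNE clusters and their post-duplication subclusters.

Synthetic genes share one reference chromosome, so their UCNEs chain
into a single cluster (0.5 Mb rule in both reference genomes); after
duplication the surviving homologs split into syntenic subclusters per
duplicate chromosome, the larger one being the major subcluster.
"""
from grbcontext.clusters import (
    associate_genes, build_clusters, classify_cluster_retention,
    find_subclusters,
)
from grbcontext.synth import (
    SynthConfig, dual_coordinates, generate_reference, hits_from_wgd,
    simulate_wgd,
)

cfg = SynthConfig(
    n_genes=3, ucnes_per_gene=4, seed=8, intergenic_fraction=0.25,
    retention_scenario="winner", retention_prob=0.95,
)
ref = generate_reference(cfg)
dup = simulate_wgd(ref, cfg)

clusters = build_clusters(dual_coordinates(ref))
print(f"{len(clusters)} reference cluster(s):")
for cl in clusters:
    cl.gene_ids = associate_genes(cl, ref.ucne_by_id(), ref.genes)
    print(f"  {cl.id}: {cl.size} UCNEs, genes: {', '.join(cl.gene_ids)}")

hits = hits_from_wgd(ref, dup, score=False)
for cl in clusters:
    subs = find_subclusters(cl, hits, "dup")
    print(f"\nsubclusters of {cl.id} in the duplicated genome:")
    for s in subs:
        print(f"  {s.span.chrom}: {len(s.member_ucnes):2d} UCNEs  role={s.role}")
    pat = classify_cluster_retention(cl, subs, "dup")
    print(f"  cluster retention: ({pat.a},{pat.b},{pat.c}) -> {pat.label}")
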