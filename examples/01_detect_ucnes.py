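"""Detect ultraconserved elements from pairwise alignments.

Builds a small synthetic genome with perfectly conserved elements on a
30%-divergent background, emits pairwise alignment blocks, and runs the
sliding-window scan (61-bp window, >=95% identity, CDS subtracted,
>=200 bp).  Printed intervals should track the planted ones to within
~30 bp of boundary smear from the window-flank rule.
"""
from grbcontext.scan import scan_alignments
from grbcontext.synth import (
    SynthConfig, emit_alignments, generate_reference, simulate_wgd,
)

cfg = SynthConfig(
    n_genes=2, ucnes_per_gene=3, seed=11,
    ucne_divergence=0.0, background_divergence=0.3,
    ucne_length_bp=(280, 500), retention_prob=1.0,
    retention_scenario="concordant",
)
ref = generate_reference(cfg)
dup = simulate_wgd(ref, cfg)
detected = scan_alignments(
    emit_alignments(ref, dup), ref.genes, sequences=ref.sequences
)

print("planted elements:")
for u in ref.ucnes:
    print(f"  {u.id}  {u.interval.chrom}:{u.interval.start}-{u.interval.end}  {u.position_class}")
print("detected elements:")
for u in detected:
    host = ",".join(u.genes)
    print(f"  {u.id}  {u.interval.chrom}:{u.interval.start}-{u.interval.end}  {u.position_class}  ({host})")
print(f"\n{len(detected)}/{len(ref.ucnes)} recovered; boundaries differ by the "
      "window-flank smear only.")
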