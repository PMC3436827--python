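"""End-to-end orchestration: scan → homologs → retention → clusters.

The pipeline is deliberately thin: every stage is a call into the
corresponding module, stitched together by the TSV contracts described
in docs/FORMATS.md, with one seed governing every random draw and a
JSON run log recording parameters and per-stage counts.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .alignments import candidate_regions, read_maf
from .clusters import (
    DualCoordUcne, associate_fish_genes, associate_genes, build_clusters,
    call_targets, classify_cluster_retention, find_subclusters,
    merge_assembly_fragments,
)
from .homology import ScoringScheme, find_homologs
from .intervals import GenomicInterval
from .retention import (
    case_from_hits, classify_case, eligibility_filter, patterns_table,
    permutation_null, winner_score,
)
from .scan import scan_alignments


@dataclass
class PipelineConfig:
    outdir: str
    ref_fasta: str
    ref_genes_gff: str
    maf: dict[str, str]                      # genome name -> pairwise MAF
    dup_genes_gff: dict[str, str] = field(default_factory=dict)
    orthologs_tsv: str | None = None
    window: int = 61
    min_identity: float = 95.0
    min_len: int = 200
    evalue: float = 1e-4
    shuffles: int = 500
    shuffle_window: int = 20
    max_gap: int = 500_000
    assoc_dist: int = 100_000
    null_shuffles: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_len < 1 or self.evalue <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns the in-memory
    results and writes the TSV outputs plus ``run_log.json``."""
    for path in [config.ref_fasta, config.ref_genes_gff, *config.maf.values()]:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    os.makedirs(config.outdir, exist_ok=True)
    log: dict = {"parameters": asdict(config), "counts": {}}
    sequences = gio.read_fasta(config.ref_fasta)
    genes = gio.read_gff(config.ref_genes_gff)
    scheme = ScoringScheme()

    # --- scan (conservation partner = first configured genome)
    first_genome = next(iter(config.maf))
    blocks_by_genome = {g: read_maf(p) for g, p in config.maf.items()}
    ucnes = scan_alignments(
        blocks_by_genome[first_genome], genes, sequences=sequences,
        window=config.window, threshold=config.min_identity,
        min_len=config.min_len,
    )
    log["counts"]["ucnes"] = len(ucnes)
    ucne_df = pd.DataFrame(
        [
            {
                "ucne_id": u.id, "chrom": u.interval.chrom,
                "start": u.interval.start, "end": u.interval.end,
                "position_class": u.position_class, "genes": ",".join(u.genes),
            }
            for u in ucnes
        ]
    )
    gio.write_table(ucne_df, os.path.join(config.outdir, "ucnes.tsv"))

    # --- homologs
    hits_by_genome: dict[str, list] = {}
    second_coords: dict[str, GenomicInterval] = {}
    rng = np.random.default_rng(config.seed)
    for genome, blocks in blocks_by_genome.items():
        hits = []
        for u in ucnes:
            cands = candidate_regions(u.interval, blocks)
            if genome == first_genome and cands:
                second_coords[u.id] = cands[0].interval
            hits.extend(
                find_homologs(
                    u, cands, genome=genome, scheme=scheme,
                    threshold=config.evalue, n_shuffles=config.shuffles,
                    shuffle_window=config.shuffle_window,
                    seed=int(rng.integers(2**31)),
                )
            )
        hits_by_genome[genome] = hits
    hit_rows = [
        {
            "ucne_id": h.ucne_id, "genome": h.genome,
            "chrom": h.interval.chrom, "start": h.interval.start,
            "end": h.interval.end, "strand": h.interval.strand,
            "raw": h.raw, "bitscore": h.bitscore, "evalue": h.e_value,
            "accepted": h.accepted, "paralog_flag": h.paralog_flag,
        }
        for hits in hits_by_genome.values() for h in hits
    ]
    gio.write_table(pd.DataFrame(hit_rows), os.path.join(config.outdir, "hits.tsv"))
    log["counts"]["hits_accepted"] = sum(r["accepted"] for r in hit_rows)

    # --- retention
    patterns = []
    eligible_input = []
    if config.orthologs_tsv:
        orth = gio.read_table(config.orthologs_tsv)
        dup_genes = {
            genome: {g.id: g for g in gio.read_gff(path)}
            for genome, path in config.dup_genes_gff.items()
        }
        gene_ucnes: dict[str, list[str]] = {}
        for u in ucnes:
            if u.position_class in ("intronic", "UTR"):
                for gid in u.genes:
                    gene_ucnes.setdefault(gid, []).append(u.id)
        for genome, hits in hits_by_genome.items():
            if genome not in dup_genes:
                continue
            spans = {gid: g.interval for gid, g in dup_genes[genome].items()}
            for gene_id, uids in gene_ucnes.items():
                orth_ids = orth.loc[
                    orth.ref_gene_id == gene_id, "ortholog_gene_id"
                ].tolist()
                orth_spans = {o: spans[o] for o in orth_ids if o in spans}
                if not orth_spans:
                    continue
                case = case_from_hits(gene_id, genome, uids, hits, orth_spans)
                eligible_input.append(case)
                patterns.append(classify_case(case))
        gio.write_table(
            patterns_table(patterns), os.path.join(config.outdir, "patterns.tsv")
        )
        eligible = eligibility_filter(eligible_input)
        scores = [winner_score(c) for c in eligible]
        gio.write_table(
            pd.DataFrame(
                [
                    {
                        "gene": s.gene_id, "genome": s.genome,
                        "c_total": s.c_total, "c_major": s.c_major, "W": s.w,
                    }
                    for s in scores
                ]
            ),
            os.path.join(config.outdir, "winner_scores.tsv"),
        )
        if eligible:
            null = permutation_null(
                eligible, n_shuffles=config.null_shuffles, seed=config.seed
            )
            gio.write_table(
                pd.DataFrame(
                    {
                        "bin_lo": null.bin_edges[:-1],
                        "bin_hi": null.bin_edges[1:],
                        "mean_freq": null.mean_freq,
                        "sd_freq": null.sd_freq,
                    }
                ),
                os.path.join(config.outdir, "null_histogram.tsv"),
            )
        log["counts"]["retention_cases"] = len(patterns)
        log["counts"]["eligible_cases"] = len(eligible)

    # --- clusters
    dual = [
        DualCoordUcne(u.id, u.interval, second_coords.get(u.id))
        for u in ucnes
    ]
    clusters = build_clusters(dual, max_gap=config.max_gap)
    ucne_map = {u.id: u for u in ucnes}
    cluster_rows, retention_rows, call_rows = [], [], []
    for cl in clusters:
        cl.gene_ids = associate_genes(cl, ucne_map, genes)
        cluster_rows.append(
            {
                "cluster_id": cl.id, "n_ucnes": cl.size,
                "chrom": cl.ref_span.chrom, "start": cl.ref_span.start,
                "end": cl.ref_span.end, "genes": ",".join(cl.gene_ids),
            }
        )
        assoc: dict[str, set] = {}
        for genome, hits in hits_by_genome.items():
            subs = find_subclusters(cl, hits, genome, max_gap=config.max_gap)
            subs, _ = merge_assembly_fragments(cl, subs)
            pat = classify_cluster_retention(cl, subs, genome)
            if pat is not None:
                retention_rows.append(
                    {
                        "cluster_id": cl.id, "genome": genome, "a": pat.a,
                        "b": pat.b, "c": pat.c, "label": pat.label,
                    }
                )
            if genome in config.dup_genes_gff:
                dgenes = gio.read_gff(config.dup_genes_gff[genome])
                orth = (
                    gio.read_table(config.orthologs_tsv)
                    if config.orthologs_tsv else None
                )
                associated_ref = set()
                for sub in subs:
                    fish = associate_fish_genes(
                        sub, dgenes, max_dist=config.assoc_dist
                    )
                    if orth is not None:
                        associated_ref |= set(
                            orth.loc[
                                orth.ortholog_gene_id.isin(fish), "ref_gene_id"
                            ]
                        )
                assoc[genome] = associated_ref
        if assoc:
            for call in call_targets(cl.gene_ids, assoc):
                call_rows.append(
                    {
                        "cluster_id": cl.id, "gene": call.gene_id,
                        "call": call.call,
                    }
                )
    gio.write_table(
        pd.DataFrame(cluster_rows), os.path.join(config.outdir, "clusters.tsv")
    )
    gio.write_table(
        pd.DataFrame(retention_rows),
        os.path.join(config.outdir, "cluster_retention.tsv"),
    )
    gio.write_table(
        pd.DataFrame(call_rows), os.path.join(config.outdir, "gene_calls.tsv")
    )
    log["counts"]["clusters"] = len(clusters)
    with open(os.path.join(config.outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1)
    return {
        "ucnes": ucnes,
        "hits": hits_by_genome,
        "patterns": patterns,
        "clusters": clusters,
        "log": log,
    }


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
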