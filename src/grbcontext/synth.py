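"""Synthetic reference + post-duplication genomes with known ground truth.

The generator emulates the data regime the analysis was designed for: a
reference genome whose genes host clustered ultraconserved elements,
and a duplicated genome in which every gene survives in ``n_copies``
copies while each UCNE survives according to a configurable retention
scenario:

- ``winner``     — surviving UCNEs all land in one designated copy;
- ``concordant`` — surviving UCNEs are present in every copy;
- ``reciprocal`` — each surviving UCNE lands in one uniformly random copy;
- ``random``     — independent Bernoulli survival per (UCNE, copy).

Sequence is uniform-random over ACGT (no repeat structure).  Divergence
is substitution-only by default: a low rate inside surviving UCNEs
(so they stay >=95% identical) and a high background rate elsewhere; a
*lost* UCNE is replaced by fresh random sequence, which destroys
homology while keeping coordinates alignable.  Optional short deletions
(1–5 bp, placed outside UCNEs) exercise gap handling in the alignment
emitter.  Every random draw flows from the single config seed.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import io as gio
from .alignments import AlignmentBlock
from .homology import ScoringScheme
from .intervals import GeneModel, GenomicInterval
from .retention import ScoreMatrix
from .scan import Ucne
from .clusters import DualCoordUcne
from .homology import HomologyHit

SCENARIOS = ("winner", "concordant", "reciprocal", "random")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate(b"ACGT")}


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_genes: int = 5
    ucnes_per_gene: int | tuple[int, int] = 5
    ucne_length_bp: tuple[int, int] = (200, 600)
    intergenic_fraction: float = 0.0
    cluster_gap_bp: int = 5_000
    background_divergence: float = 0.30
    ucne_divergence: float = 0.01
    retention_scenario: str = "winner"
    retention_prob: float = 0.9
    n_copies: int = 2
    seed: int = 0
    # geometry knobs
    gene_length: int | None = None       # hard cap; infeasible load errors
    intergene_gap: int = 2_000
    scatter_copies: bool = False         # one scaffold per (gene, copy)
    inject_indels: bool = False          # 1-5 bp deletions outside UCNEs
    indels_per_segment: int = 1

    def __post_init__(self) -> None:
        for p in (
            self.intergenic_fraction, self.background_divergence,
            self.ucne_divergence, self.retention_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.ucne_length_bp[0] < 200:
            raise ConfigError("minimum UCNE length is 200 bp")
        if self.ucne_length_bp[0] > self.ucne_length_bp[1]:
            raise ConfigError("bad UCNE length range")
        if self.n_copies < 1:
            raise ConfigError("n_copies must be >= 1")
        if self.retention_scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.retention_scenario!r}")
        if self.cluster_gap_bp < 1_000:
            raise ConfigError("cluster_gap_bp below generator geometry (>=1000)")

    def draw_n_ucnes(self, rng: np.random.Generator) -> int:
        if isinstance(self.ucnes_per_gene, int):
            return self.ucnes_per_gene
        lo, hi = self.ucnes_per_gene
        return int(rng.integers(lo, hi + 1))


@dataclass
class GroundTruth:
    """One record per emitted UCNE / gene / cluster."""

    ucne_class: dict[str, str] = field(default_factory=dict)
    ucne_genes: dict[str, list[str]] = field(default_factory=dict)
    ucne_retained_copies: dict[str, list[int]] = field(default_factory=dict)
    gene_major_copy: dict[str, int] = field(default_factory=dict)
    cluster_label: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ucne_class": self.ucne_class,
                "ucne_genes": self.ucne_genes,
                "ucne_retained_copies": self.ucne_retained_copies,
                "gene_major_copy": self.gene_major_copy,
                "cluster_label": self.cluster_label,
            },
            indent=1, sort_keys=True,
        )


@dataclass
class GeneLayout:
    gene_id: str
    intronic_ucnes: list[str]
    intergenic_ucnes: list[str]
    segment: GenomicInterval            # reference span duplicated as a unit


@dataclass
class Reference:
    config: SynthConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    ucnes: list[Ucne]
    layouts: list[GeneLayout]
    ground_truth: GroundTruth

    def ucne_by_id(self) -> dict[str, Ucne]:
        return {u.id: u for u in self.ucnes}


@dataclass
class DuplicatedGenome:
    config: SynthConfig
    sequences: dict[str, str]
    genes: list[GeneModel]              # per-copy gene models
    # (ucne_id, copy) -> coordinates of the surviving homolog
    ucne_coords: dict[tuple[str, int], GenomicInterval]
    ortholog_table: pd.DataFrame
    # (ref segment, target segment, deletions [(ref offset, len)])
    segments: list[tuple[GenomicInterval, GenomicInterval, list[tuple[int, int]]]]
    genome_name: str = "dup"


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(
    sequence: str, rate: float, rng: np.random.Generator | int
) -> str:
    """Substitute each base, independently with probability ``rate``, by
    a uniformly chosen *different* base.  Length is preserved."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not sequence:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    codes = np.searchsorted(_BASES, arr)       # ACGT are sorted
    hit = rng.random(len(arr)) < rate
    shift = rng.integers(1, 4, size=len(arr))
    codes = np.where(hit, (codes + shift) % 4, codes)
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# reference genome

_UTR_LEN = 200
_CDS_EXON = 120
_CDS_STUB = 60
_UCNE_MARGIN = 150
_INTERGENIC_GAP = 300
_CHROM = "chr1"


def generate_reference(config: SynthConfig) -> Reference:
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    layouts: list[GeneLayout] = []
    truth = GroundTruth()
    ucne_ivs: list[tuple[GenomicInterval, str, list[str]]] = []  # iv, class, hosts
    cursor = 500
    plans = []
    for g in range(config.n_genes):
        n_u = config.draw_n_ucnes(rng)
        n_inter = int(round(config.intergenic_fraction * n_u))
        plans.append((f"gene{g + 1:03d}", n_u - n_inter, n_inter))
    for gene_id, n_intron, n_inter in plans:
        gene_start = cursor
        exons: list[GenomicInterval] = []
        cds: list[GenomicInterval] = []
        intronic: list[GenomicInterval] = []
        pos = gene_start
        # 5'UTR + first CDS stub
        exons.append(GenomicInterval(_CHROM, pos, pos + _UTR_LEN + _CDS_STUB, "+"))
        cds.append(GenomicInterval(_CHROM, pos + _UTR_LEN, pos + _UTR_LEN + _CDS_STUB, "+"))
        pos += _UTR_LEN + _CDS_STUB
        for i in range(n_intron):
            ulen = int(rng.integers(config.ucne_length_bp[0], config.ucne_length_bp[1] + 1))
            u_start = pos + _UCNE_MARGIN
            intronic.append(GenomicInterval(_CHROM, u_start, u_start + ulen))
            pos = u_start + ulen + _UCNE_MARGIN
            if i < n_intron - 1:
                exons.append(GenomicInterval(_CHROM, pos, pos + _CDS_EXON, "+"))
                cds.append(GenomicInterval(_CHROM, pos, pos + _CDS_EXON, "+"))
                pos += _CDS_EXON
        # terminal CDS stub + 3'UTR
        exons.append(GenomicInterval(_CHROM, pos, pos + _CDS_STUB + _UTR_LEN, "+"))
        cds.append(GenomicInterval(_CHROM, pos, pos + _CDS_STUB, "+"))
        pos += _CDS_STUB + _UTR_LEN
        gene_end = pos
        if config.gene_length is not None and gene_end - gene_start > config.gene_length:
            raise ConfigError(
                f"gene {gene_id}: {n_intron} intronic UCNEs need "
                f"{gene_end - gene_start} bp > gene_length={config.gene_length}"
            )
        gene_iv = GenomicInterval(_CHROM, gene_start, gene_end, "+")
        genes.append(GeneModel(gene_id, gene_iv, exons=exons, cds=cds))
        intergenic: list[GenomicInterval] = []
        for _ in range(n_inter):
            ulen = int(rng.integers(config.ucne_length_bp[0], config.ucne_length_bp[1] + 1))
            u_start = pos + _INTERGENIC_GAP
            intergenic.append(GenomicInterval(_CHROM, u_start, u_start + ulen))
            pos = u_start + ulen
        seg = GenomicInterval(_CHROM, max(0, gene_start - 200), pos + 200, "+")
        layouts.append(
            GeneLayout(gene_id, [], [], seg)  # ucne ids filled after numbering
        )
        for iv in intronic:
            ucne_ivs.append((iv, "intronic", [gene_id]))
        for iv in intergenic:
            ucne_ivs.append((iv, "intergenic", [gene_id]))
        cursor = pos + 200 + config.intergene_gap
    chrom_len = cursor + 500
    sequence = random_sequence(chrom_len, rng)
    # number UCNEs by genomic order and fill layouts + ground truth
    ucne_ivs.sort(key=lambda t: t[0].start)
    ucnes: list[Ucne] = []
    layout_by_gene = {l.gene_id: l for l in layouts}
    for i, (iv, pclass, hosts) in enumerate(ucne_ivs, 1):
        uid = f"UCNE_{i:04d}"
        ucnes.append(
            Ucne(uid, iv, sequence=sequence[iv.start:iv.end],
                 position_class=pclass, genes=list(hosts))
        )
        truth.ucne_class[uid] = pclass
        truth.ucne_genes[uid] = list(hosts)
        layout = layout_by_gene[hosts[0]]
        (layout.intronic_ucnes if pclass != "intergenic" else layout.intergenic_ucnes).append(uid)
    for gene_id, _, _ in plans:
        truth.cluster_label[gene_id] = config.retention_scenario
    return Reference(
        config=config, sequences={_CHROM: sequence}, genes=genes,
        ucnes=ucnes, layouts=layouts, ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# whole-genome duplication

def _draw_retention(
    config: SynthConfig, ucne_ids: list[str], major_copy: int,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """Which copies retain each UCNE, per the configured scenario."""
    k = config.n_copies
    out: dict[str, list[int]] = {}
    for uid in ucne_ids:
        if config.retention_scenario == "random":
            copies = [c for c in range(k) if rng.random() < config.retention_prob]
        else:
            if rng.random() >= config.retention_prob:
                copies = []
            elif config.retention_scenario == "winner":
                copies = [major_copy]
            elif config.retention_scenario == "concordant":
                copies = list(range(k))
            else:  # reciprocal
                copies = [int(rng.integers(k))]
        out[uid] = copies
    return out


def simulate_wgd(reference: Reference, config: SynthConfig | None = None) -> DuplicatedGenome:
    config = config or reference.config
    rng = np.random.default_rng(config.seed + 1)
    truth = reference.ground_truth
    ref_seq = reference.sequences[_CHROM]
    ucne_map = reference.ucne_by_id()

    retained: dict[str, list[int]] = {}
    for layout in reference.layouts:
        major = int(rng.integers(config.n_copies))
        truth.gene_major_copy[layout.gene_id] = major
        all_ids = layout.intronic_ucnes + layout.intergenic_ucnes
        retained.update(_draw_retention(config, all_ids, major, rng))
    truth.ucne_retained_copies.update(retained)

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    ucne_coords: dict[tuple[str, int], GenomicInterval] = {}
    segments: list[tuple[GenomicInterval, GenomicInterval, list[tuple[int, int]]]] = []
    orth_rows = []
    cursors: dict[str, int] = {}
    chunks: dict[str, list[str]] = {}

    gene_by_id = {g.id: g for g in reference.genes}
    for copy in range(config.n_copies):
        for layout in reference.layouts:
            seg = layout.segment
            seg_seq = ref_seq[seg.start:seg.end]
            local_ucnes = [
                (uid, ucne_map[uid].interval.start - seg.start,
                 ucne_map[uid].interval.end - seg.start)
                for uid in layout.intronic_ucnes + layout.intergenic_ucnes
            ]
            # mutate: UCNE bodies at ucne_divergence if retained (else
            # replaced by fresh sequence), everything else at background
            arr = list(mutate_sequence(seg_seq, config.background_divergence, rng))
            for uid, lo, hi in local_ucnes:
                body = seg_seq[lo:hi]
                if copy in retained[uid]:
                    arr[lo:hi] = mutate_sequence(body, config.ucne_divergence, rng)
                else:
                    arr[lo:hi] = random_sequence(hi - lo, rng)
            mutated = "".join(arr)
            deletions: list[tuple[int, int]] = []
            if config.inject_indels:
                forbidden = [(lo, hi) for _, lo, hi in local_ucnes]
                for _ in range(config.indels_per_segment):
                    for _try in range(50):
                        dlen = int(rng.integers(1, 6))
                        dpos = int(rng.integers(0, len(mutated) - dlen))
                        if not any(lo - dlen < dpos < hi for lo, hi in forbidden):
                            deletions.append((dpos, dlen))
                            break
                deletions.sort()
                out = []
                prev = 0
                for dpos, dlen in deletions:
                    out.append(mutated[prev:dpos])
                    prev = dpos + dlen
                out.append(mutated[prev:])
                target_seq = "".join(out)
            else:
                target_seq = mutated

            def shift(off: int) -> int:
                return off - sum(d for p, d in deletions if p < off)

            if config.scatter_copies and copy > 0:
                chrom = f"scf_{layout.gene_id}_c{copy + 1}"
            else:
                chrom = f"chrD{copy + 1}"
            cur = cursors.get(chrom, 0)
            if cur == 0:
                chunks[chrom] = []
            t_start = cur
            chunks[chrom].append(target_seq)
            cursors[chrom] = cur + len(target_seq) + 200
            chunks[chrom].append(random_sequence(200, rng))
            t_iv = GenomicInterval(chrom, t_start, t_start + len(target_seq), "+")
            segments.append((seg, t_iv, deletions))

            gene = gene_by_id[layout.gene_id]
            copy_id = f"{layout.gene_id}_c{copy + 1}"

            def lift(iv: GenomicInterval) -> GenomicInterval:
                return GenomicInterval(
                    chrom,
                    t_start + shift(iv.start - seg.start),
                    t_start + shift(iv.end - seg.start),
                    iv.strand,
                )

            genes.append(
                GeneModel(
                    copy_id, lift(gene.interval),
                    exons=[lift(e) for e in gene.exons],
                    cds=[lift(c) for c in gene.cds],
                )
            )
            orth_rows.append(
                {
                    "ref_gene_id": layout.gene_id, "species": "dup",
                    "ortholog_gene_id": copy_id, "orthology_confidence": "ortholog",
                }
            )
            for uid, lo, hi in local_ucnes:
                if copy in retained[uid]:
                    ucne_coords[(uid, copy)] = GenomicInterval(
                        chrom, t_start + shift(lo), t_start + shift(hi)
                    )
    sequences = {chrom: "".join(parts) for chrom, parts in chunks.items()}
    return DuplicatedGenome(
        config=config, sequences=sequences, genes=genes,
        ucne_coords=ucne_coords,
        ortholog_table=pd.DataFrame(orth_rows),
        segments=segments,
    )


# ---------------------------------------------------------------------------
# alignments and downstream glue

def emit_alignments(
    reference: Reference, dup: DuplicatedGenome
) -> list[AlignmentBlock]:
    """One alignment block per homologous (reference segment, copy)
    pair; deletions injected during duplication appear as gap columns in
    the target row."""
    blocks = []
    ref_seq = reference.sequences[_CHROM]
    ref_len = len(ref_seq)
    for seg, t_iv, deletions in dup.segments:
        ref_row = ref_seq[seg.start:seg.end]
        t_seq = dup.sequences[t_iv.chrom][t_iv.start:t_iv.end]
        if deletions:
            cols = []
            prev = 0
            removed = 0
            for dpos, dlen in deletions:
                cols.append(t_seq[prev - removed:dpos - removed])
                cols.append("-" * dlen)
                prev = dpos + dlen
                removed += dlen
            cols.append(t_seq[prev - removed:])
            target_row = "".join(cols)
        else:
            target_row = t_seq
        blocks.append(
            AlignmentBlock(
                ref_interval=seg, target_interval=t_iv,
                ref_row=ref_row, target_row=target_row,
                ref_src_size=ref_len,
                target_src_size=len(dup.sequences[t_iv.chrom]),
            )
        )
    return blocks


def hits_from_wgd(
    reference: Reference,
    dup: DuplicatedGenome,
    scheme: ScoringScheme | None = None,
    score: bool = True,
) -> list[HomologyHit]:
    """Hit table straight from the duplicated-genome UCNE annotation:
    presence comes from the annotation, the bitscore from an actual
    local alignment of the reference UCNE to its surviving copy.

    This is the fast route for retention/cluster analyses on synthetic
    data; the full shuffle-E-value machinery lives in
    :mod:`grbcontext.homology` and is exercised on its own.
    """
    scheme = scheme or ScoringScheme()
    ucne_map = reference.ucne_by_id()
    hits = []
    for (uid, copy), iv in sorted(dup.ucne_coords.items()):
        target = dup.sequences[iv.chrom][iv.start:iv.end]
        if score:
            raw = scheme.score(ucne_map[uid].sequence, target)
        else:
            raw = scheme.match * len(target)
        hits.append(
            HomologyHit(
                ucne_id=uid, genome=dup.genome_name, interval=iv,
                raw=raw, bitscore=scheme.bitscore(raw), e_value=0.0,
                accepted=True,
            )
        )
    return hits


def cases_from_synthetic(
    reference: Reference,
    dup: DuplicatedGenome,
    hits: list[HomologyHit],
) -> list[ScoreMatrix]:
    """One retention case per reference gene (intronic/UTR UCNEs only),
    with ortholog spans taken from the duplicated annotation."""
    from .retention import case_from_hits

    spans = {g.id: g.interval for g in dup.genes}
    cases = []
    for layout in reference.layouts:
        if not layout.intronic_ucnes:
            continue
        orth = {
            row.ortholog_gene_id: spans[row.ortholog_gene_id]
            for row in dup.ortholog_table.itertuples()
            if row.ref_gene_id == layout.gene_id
        }
        cases.append(
            case_from_hits(
                layout.gene_id, dup.genome_name, layout.intronic_ucnes,
                hits, orth,
            )
        )
    return cases


def dual_coordinates(reference: Reference) -> list[DualCoordUcne]:
    """Dual-genome coordinates for cluster building; the synthetic
    second reference genome conserves synteny exactly, so second-genome
    coordinates mirror the reference on a renamed chromosome."""
    return [
        DualCoordUcne(
            u.id, u.interval,
            GenomicInterval("b_" + u.interval.chrom, u.interval.start, u.interval.end),
        )
        for u in reference.ucnes
    ]


def write_outputs(
    reference: Reference, dup: DuplicatedGenome, outdir: str | os.PathLike
) -> None:
    os.makedirs(outdir, exist_ok=True)
    gio.write_fasta(reference.sequences, os.path.join(outdir, "reference.fa"))
    gio.write_fasta(dup.sequences, os.path.join(outdir, "duplicated.fa"))
    gio.write_gff(reference.genes, os.path.join(outdir, "reference.gff3"))
    gio.write_gff(dup.genes, os.path.join(outdir, "duplicated.gff3"))
    bed = gio.intervals_to_bed(
        [u.interval for u in reference.ucnes], [u.id for u in reference.ucnes]
    )
    gio.write_bed(bed, os.path.join(outdir, "ucnes.bed"))
    from .alignments import write_maf

    write_maf(emit_alignments(reference, dup), os.path.join(outdir, "alignments.maf"))
    gio.write_table(dup.ortholog_table, os.path.join(outdir, "orthologs.tsv"))
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        fh.write(reference.ground_truth.to_json())
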