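"""Pairwise alignment blocks and MAF I/O.

A block pairs one reference segment with one target segment as two
aligned rows of equal column count.  The reference row is always on the
forward strand; minus-strand target rows keep their aligned (reference-
oriented) bases, with the forward-strand coordinates recorded on the
target interval.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

GAP = "-"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class AlignmentBlock:
    ref_interval: GenomicInterval
    target_interval: GenomicInterval
    ref_row: str
    target_row: str
    ref_src_size: int = 0
    target_src_size: int = 0

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.target_row):
            raise ValueError("aligned rows differ in column count")
        for row, iv, label in (
            (self.ref_row, self.ref_interval, "reference"),
            (self.target_row, self.target_interval, "target"),
        ):
            ungapped = len(row) - row.count(GAP)
            if ungapped != len(iv):
                raise ValueError(
                    f"{label} row has {ungapped} bases but interval spans {len(iv)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.ref_row)


def _chrom_id(src: str) -> str:
    # MAF "src" is conventionally assembly.chrom; keep the full name if no dot
    return src


def read_maf(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Read a pairwise MAF into AlignmentBlocks.

    Blocks with more than two rows are rejected.  Minus-strand target
    coordinates are converted to the forward strand; a minus-strand
    *reference* row flips the whole block so the reference is forward.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "maf"):
            recs = list(aln)
            if len(recs) != 2:
                raise ValueError(
                    f"pairwise MAF expected, got block with {len(recs)} rows"
                )
            ref, tgt = recs
            rrow, trow = str(ref.seq).upper(), str(tgt.seq).upper()
            ra, ta = ref.annotations, tgt.annotations
            if ra["strand"] == -1:
                # flip block to put reference on the forward strand
                rrow, trow = revcomp(rrow), revcomp(trow)
                ra = dict(ra, start=ra["srcSize"] - ra["start"] - ra["size"], strand=1)
                ta = dict(ta, strand=-ta["strand"])
            r_iv = GenomicInterval(
                _chrom_id(ref.id), ra["start"], ra["start"] + ra["size"], "+"
            )
            if ta["strand"] == 1:
                t_start, t_strand = ta["start"], "+"
            else:
                t_start = ta["srcSize"] - ta["start"] - ta["size"]
                t_strand = "-"
            t_iv = GenomicInterval(
                _chrom_id(tgt.id), t_start, t_start + ta["size"], t_strand
            )
            blocks.append(
                AlignmentBlock(
                    r_iv, t_iv, rrow, trow,
                    ref_src_size=ra["srcSize"], target_src_size=ta["srcSize"],
                )
            )
    return blocks


def write_maf(blocks: list[AlignmentBlock], path: str | os.PathLike) -> None:
    alignments = []
    for b in blocks:
        r_size = b.ref_src_size or b.ref_interval.end
        t_size = b.target_src_size or b.target_interval.end
        t_iv = b.target_interval
        if t_iv.strand == "-":
            t_start, t_strand = t_size - t_iv.end, -1
        else:
            t_start, t_strand = t_iv.start, 1
        aln = MultipleSeqAlignment([])
        aln.append(
            SeqRecord(
                Seq(b.ref_row), id=b.ref_interval.chrom,
                annotations={
                    "start": b.ref_interval.start, "size": len(b.ref_interval),
                    "strand": 1, "srcSize": r_size,
                },
            )
        )
        aln.append(
            SeqRecord(
                Seq(b.target_row), id=t_iv.chrom,
                annotations={
                    "start": t_start, "size": len(t_iv),
                    "strand": t_strand, "srcSize": t_size,
                },
            )
        )
        alignments.append(aln)
    with open(path, "w") as fh:
        AlignIO.write(alignments, fh, "maf")


@dataclass
class CandidateRegion:
    """A target-genome segment alignable to a reference region.

    ``seq`` is in reference orientation (minus-strand segments already
    reverse-complemented), so it can be aligned to the reference query
    directly; ``interval`` is on the target forward strand.
    """

    interval: GenomicInterval
    seq: str
    strand: str = "+"


def candidate_regions(
    region: GenomicInterval, blocks: list[AlignmentBlock]
) -> list[CandidateRegion]:
    """Slice out the target segments aligned to ``region``.

    One candidate per overlapping block (the paper-style "all sequences
    alignable to the reference region"); gap-only slices are dropped.
    """
    out: list[CandidateRegion] = []
    for b in blocks:
        if not b.ref_interval.overlaps(region):
            continue
        lo = max(region.start, b.ref_interval.start)
        hi = min(region.end, b.ref_interval.end)
        ref_pos = b.ref_interval.start
        col_lo = col_hi = None
        for col, base in enumerate(b.ref_row):
            if base == GAP:
                continue
            if ref_pos == lo and col_lo is None:
                col_lo = col
            if ref_pos == hi - 1:
                col_hi = col + 1
                break
            ref_pos += 1
        if col_lo is None or col_hi is None:
            continue
        tgt_before = col_lo - b.target_row[:col_lo].count(GAP)
        sub = b.target_row[col_lo:col_hi].replace(GAP, "")
        if not sub:
            continue
        t_iv = b.target_interval
        if t_iv.strand == "-":
            # aligned orientation runs down the forward strand
            t_end = t_iv.end - tgt_before
            t_start = t_end - len(sub)
        else:
            t_start = t_iv.start + tgt_before
            t_end = t_start + len(sub)
        out.append(
            CandidateRegion(
                GenomicInterval(t_iv.chrom, t_start, t_end, t_iv.strand),
                sub,
                strand=t_iv.strand,
            )
        )
    return out
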