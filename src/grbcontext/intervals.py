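"""Genomic intervals and gene models.

All coordinates are 0-based, half-open ``[start, end)`` on a named
chromosome, matching BED conventions; GFF3 I/O converts at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same chromosome; 0 if they
        overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals."""
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def subtract_intervals(
    interval: GenomicInterval, others: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set-difference ``interval − union(others)`` as ordered fragments."""
    frags: list[GenomicInterval] = []
    pos = interval.start
    blockers = merge_intervals(o for o in others if o.overlaps(interval))
    for b in blockers:
        if b.start > pos:
            frags.append(GenomicInterval(interval.chrom, pos, b.start, interval.strand))
        pos = max(pos, b.end)
    if pos < interval.end:
        frags.append(GenomicInterval(interval.chrom, pos, interval.end, interval.strand))
    return frags


@dataclass
class GeneModel:
    """A gene with exon/CDS structure; UTRs are exons minus CDS.

    ``exons`` and ``cds`` are unions over transcripts.  ``biotype`` and
    ``is_pseudogene`` drive the protein-coding filter used when genes are
    associated with UCNE clusters.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        exon_union = merge_intervals(self.exons) if self.exons else []
        for c in self.cds:
            if not any(e.contains(c) for e in exon_union):
                raise ValueError(f"gene {self.id}: CDS {c} outside exons")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def utrs(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for exon in self.exons:
            out.extend(subtract_intervals(exon, self.cds))
        return out

    @property
    def is_coding(self) -> bool:
        return bool(self.cds) and not self.is_pseudogene
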