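"""Readers and writers for the formats the pipeline exchanges.

BED is 0-based half-open; GFF3 is 1-based closed and converted at the
boundary.  Tab-separated stage outputs carry a header line and are read
back with pandas (see docs/FORMATS.md for the column contracts).
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with BED6 columns.

    Missing name/score/strand columns are filled with ".", 0, ".".
    Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) "
                    "(BED is 0-based half-open; is this 1-based input?)"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df = df.loc[:, BED6_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_to_bed(
    intervals: Iterable[GenomicInterval], names: Iterable[str] | None = None
) -> pd.DataFrame:
    intervals = list(intervals)
    if names is None:
        names = ["."] * len(intervals)
    rows = [
        (iv.chrom, iv.start, iv.end, name, "0", iv.strand)
        for iv, name in zip(intervals, names, strict=True)
    ]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _gff_attr(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.split(";"):
        field = field.strip()
        if field and "=" in field:
            k, v = field.split("=", 1)
            out[k] = v
    return out


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features from GFF3 into GeneModels.

    Exons and CDS of all transcripts of a gene are unioned.  1-based
    closed GFF coordinates become 0-based half-open.  A CDS outside the
    gene's exons raises a validation error.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str},
    )
    genes: dict[str, dict] = {}
    feature_gene: dict[str, str] = {}
    deferred: list[tuple] = []
    for row in df.itertuples():
        attrs = _gff_attr(row.attributes)
        fid = attrs.get("ID")
        parent = attrs.get("Parent")
        iv = GenomicInterval(str(row.seqid), int(row.start) - 1, int(row.end), row.strand)
        if row.type == "gene":
            genes[fid] = {
                "interval": iv,
                "exons": [],
                "cds": [],
                "biotype": attrs.get("biotype", "protein_coding"),
                "pseudo": attrs.get("biotype") == "pseudogene"
                or attrs.get("pseudo", "false") == "true",
            }
            feature_gene[fid] = fid
        elif row.type in ("mRNA", "transcript"):
            feature_gene[fid] = feature_gene.get(parent, parent)
        elif row.type in ("exon", "CDS"):
            deferred.append((row.type, parent, iv))
    for ftype, parent, iv in deferred:
        gene_id = feature_gene.get(parent, parent)
        if gene_id not in genes:
            raise ValueError(f"{ftype} with unknown parent {parent!r}")
        genes[gene_id]["exons" if ftype == "exon" else "cds"].append(iv)
    out = []
    for gid, g in sorted(genes.items()):
        out.append(
            GeneModel(
                id=gid,
                interval=g["interval"],
                exons=sorted(g["exons"], key=lambda i: i.start),
                cds=sorted(g["cds"], key=lambda i: i.start),
                biotype=g["biotype"],
                is_pseudogene=g["pseudo"],
            )
        )
    return out


def write_gff(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.id};biotype={g.biotype}"
            if g.is_pseudogene:
                attrs += ";pseudo=true"
            fh.write(
                f"{iv.chrom}\tgrbcontext\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.id}.t1"
            fh.write(
                f"{iv.chrom}\tgrbcontext\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tid};Parent={g.id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chrom}\tgrbcontext\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{iv.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for i, c in enumerate(g.cds, 1):
                fh.write(
                    f"{c.chrom}\tgrbcontext\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{iv.strand}\t0\tID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV stage outputs

def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
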