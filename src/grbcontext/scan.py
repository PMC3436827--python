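"""Detection of ultraconserved non-coding elements (UCNEs).

A UCNE is called from a pairwise alignment as a maximal run of
reference bases whose sliding-window percent identity stays at or above
a threshold (default 95% in a 61-bp window), minus any coding overlap,
kept only if at least 200 bp survive.  Identity is asymmetric: windows
are taken over alignment columns centered on reference bases, so the
reference genome fixes the coordinate system.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import GAP, AlignmentBlock
from .intervals import GeneModel, GenomicInterval, merge_intervals, subtract_intervals

DEFAULT_WINDOW = 61
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_LENGTH = 200


@dataclass
class ConservationProfile:
    """Per-reference-base percent identity for one alignment block."""

    ref_interval: GenomicInterval
    identity: np.ndarray

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=float)
        if len(self.identity) == 0:
            return                      # degenerate (empty) block
        if len(self.identity) != len(self.ref_interval):
            raise ValueError("profile length must equal reference span")
        if len(self.identity) and (
            self.identity.min() < 0 or self.identity.max() > 100
        ):
            raise ValueError("identity values must lie in [0, 100]")


@dataclass
class Ucne:
    id: str
    interval: GenomicInterval
    sequence: str = ""
    position_class: str = ""          # intronic | UTR | intergenic
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.interval) < DEFAULT_MIN_LENGTH:
            raise ValueError(f"UCNE {self.id} shorter than {DEFAULT_MIN_LENGTH} bp")


def _column_matches(block: AlignmentBlock) -> np.ndarray:
    ref = np.frombuffer(block.ref_row.upper().encode(), dtype="S1")
    tgt = np.frombuffer(block.target_row.upper().encode(), dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    acgt = np.isin(ref, bases) & np.isin(tgt, bases)
    return (ref == tgt) & acgt   # gaps and ambiguity codes count as mismatches


def compute_identity_profile(
    block: AlignmentBlock, window: int = DEFAULT_WINDOW
) -> ConservationProfile:
    """Sliding-window identity assigned to the central reference base.

    The first and last full windows also supply the values for the
    (window−1)/2 reference bases at each block end; blocks shorter than
    one window get the whole-block identity everywhere.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    ncol = block.n_columns
    if ncol == 0:
        return ConservationProfile(block.ref_interval, np.empty(0))
    matches = _column_matches(block)
    half = (window - 1) // 2
    if ncol < window:
        value = 100.0 * matches.sum() / ncol
        per_col = np.full(ncol, value)
    else:
        win_sum = np.convolve(matches.astype(float), np.ones(window), mode="valid")
        per_col = np.empty(ncol)
        per_col[half:ncol - half] = 100.0 * win_sum / window
        per_col[:half] = per_col[half]
        per_col[ncol - half:] = per_col[ncol - half - 1]
    ref_cols = np.array([c != GAP for c in block.ref_row])
    return ConservationProfile(block.ref_interval, per_col[ref_cols])


def extract_ultraconserved(
    profile: ConservationProfile, threshold: float = DEFAULT_MIN_IDENTITY
) -> list[GenomicInterval]:
    """Maximal runs of reference bases with identity >= threshold."""
    above = profile.identity >= threshold
    out: list[GenomicInterval] = []
    if not above.any():
        return out
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    base = profile.ref_interval.start
    chrom = profile.ref_interval.chrom
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, base + int(s), base + int(e)))
    return out


def subtract_coding(
    intervals: list[GenomicInterval], genes: list[GeneModel]
) -> list[GenomicInterval]:
    """Remove every CDS base; an interval may split into fragments."""
    cds = [c for g in genes for c in g.cds]
    out: list[GenomicInterval] = []
    for iv in intervals:
        out.extend(subtract_intervals(iv, cds))
    return out


def filter_length(
    intervals: list[GenomicInterval],
    min_len: int = DEFAULT_MIN_LENGTH,
    sequences: dict[str, str] | None = None,
    id_prefix: str = "UCNE",
) -> list[Ucne]:
    """Drop fragments shorter than ``min_len`` (strictly) and assign
    stable identifiers ordered by (chrom, start)."""
    kept = sorted(
        (iv for iv in intervals if len(iv) >= min_len),
        key=lambda iv: (iv.chrom, iv.start),
    )
    out = []
    for i, iv in enumerate(kept, 1):
        seq = ""
        if sequences is not None:
            seq = sequences[iv.chrom][iv.start:iv.end]
        out.append(Ucne(id=f"{id_prefix}_{i:04d}", interval=iv, sequence=seq))
    return out


def classify_position(
    interval: GenomicInterval, genes: list[GeneModel]
) -> tuple[str, list[str]]:
    """Position class of a (non-coding) element relative to gene models.

    UTR overlap wins over intronic (a single UTR base suffices); an
    element inside a gene span without UTR overlap is intronic; anything
    else is intergenic, reported with its two flanking genes.
    """
    utr_hosts = []
    span_hosts = []
    for g in genes:
        if not g.interval.overlaps(interval):
            continue
        if any(u.overlaps(interval) for u in g.utrs):
            utr_hosts.append(g.id)
        else:
            span_hosts.append(g.id)
    if utr_hosts:
        return "UTR", sorted(utr_hosts)
    if span_hosts:
        return "intronic", sorted(span_hosts)
    left = right = None
    for g in genes:
        if g.interval.chrom != interval.chrom:
            continue
        if g.interval.end <= interval.start:
            if left is None or g.interval.end > left.interval.end:
                left = g
        elif g.interval.start >= interval.end:
            if right is None or g.interval.start < right.interval.start:
                right = g
    flanks = [g.id for g in (left, right) if g is not None]
    return "intergenic", flanks


def scan_alignments(
    blocks: list[AlignmentBlock],
    genes: list[GeneModel],
    sequences: dict[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> list[Ucne]:
    """Full detection pipeline: profile -> >=threshold runs -> coding
    subtraction -> length filter -> positional classification.

    Overlapping blocks contribute the per-base maximum identity
    (best-alignment semantics), applied before run extraction.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    for block in blocks:
        prof = compute_identity_profile(block, window=window)
        chrom = prof.ref_interval.chrom
        store = per_chrom.setdefault(chrom, {})
        for off, val in enumerate(prof.identity):
            pos = prof.ref_interval.start + off
            if val > store.get(pos, -1.0):
                store[pos] = val
    runs: list[GenomicInterval] = []
    for chrom, store in per_chrom.items():
        positions = sorted(p for p, v in store.items() if v >= threshold)
        if not positions:
            continue
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                runs.append(GenomicInterval(chrom, start, prev + 1))
                start = p
            prev = p
        runs.append(GenomicInterval(chrom, start, prev + 1))
    noncoding = subtract_coding(runs, genes)
    ucnes = filter_length(noncoding, min_len=min_len, sequences=sequences)
    for u in ucnes:
        u.position_class, u.genes = classify_position(u.interval, genes)
    return ucnes


def merge_covered(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Convenience re-export of interval union (used by reports)."""
    return merge_intervals(intervals)
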