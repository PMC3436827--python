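"""Homolog detection by optimal local alignment with shuffle statistics.

Each candidate target segment is scored against the query element by
Smith–Waterman local alignment (affine gaps).  Significance is
calibrated per pair: the subject is shuffled in fixed-width windows
(preserving local base composition), an extreme-value (Gumbel)
distribution is fitted to the shuffled score sample, and
``E = db_size × P(score ≥ observed)``.  Hits at E ≤ 1e-4 are accepted
as homologs; a hit scoring better (lower E) against a reference-genome
paralog of the query than against the query itself is flagged as a
paralog and excluded from retention tallies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from Bio import Align
from scipy import optimize, stats

from .alignments import CandidateRegion
from .intervals import GenomicInterval
from .scan import Ucne

DEFAULT_EVALUE = 1e-4
DEFAULT_SHUFFLES = 500
DEFAULT_SHUFFLE_WINDOW = 20


@dataclass(frozen=True)
class ScoringScheme:
    """DNA scoring scheme with bit-score scale parameters.

    Defaults follow common SSEARCH-style DNA scoring: +5 match, −4
    mismatch, gap of length L costs open + L×extend.  ``lam`` (the
    Karlin–Altschul lambda) defaults to the ungapped value solved for a
    uniform base composition; ``K`` is a conventional small constant —
    both only set the scale of bitscores, which are compared within one
    scheme.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 4.0
    lam: float | None = None
    K: float = 0.1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam is None:
            object.__setattr__(self, "lam", self._solve_lambda())
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")

    def _solve_lambda(self) -> float:
        # sum_ij p_i p_j exp(lam * s_ij) = 1 at uniform composition
        def f(lam: float) -> float:
            return (
                0.25 * math.exp(lam * self.match)
                + 0.75 * math.exp(lam * self.mismatch)
                - 1.0
            )
        return optimize.brentq(f, 1e-9, 5.0)

    @cached_property
    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def score(self, query: str, subject: str) -> float:
        return float(self.aligner.score(query, subject))

    def bitscore(self, raw: float) -> float:
        return max(0.0, (self.lam * raw - math.log(self.K)) / math.log(2.0))


@dataclass
class HomologyHit:
    ucne_id: str
    genome: str
    interval: GenomicInterval
    raw: float
    bitscore: float
    e_value: float
    accepted: bool
    paralog_flag: bool = False


@dataclass
class ParalogEntry:
    interval: GenomicInterval
    seq: str
    e_value: float


# ucne_id -> reference-genome paralogous sequences
ParalogCatalog = dict[str, list[ParalogEntry]]


def local_align(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> tuple[float, float, tuple[tuple[int, int], tuple[int, int]]]:
    """Optimal local alignment; returns (raw, bitscore, (qspan, sspan)).

    Spans are half-open offsets into query and subject; an all-mismatch
    pair floors at score 0 with empty spans.
    """
    scheme = scheme or ScoringScheme()
    if not query or not subject:
        raise ValueError("empty sequence")
    alns = scheme.aligner.align(query, subject)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, scheme.bitscore(0.0), ((0, 0), (0, 0))
    aln = alns[0]
    q_blocks, s_blocks = aln.aligned
    qspan = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    sspan = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return float(aln.score), scheme.bitscore(float(aln.score)), (qspan, sspan)


def shuffle_subject(subject: str, window: int, rng: np.random.Generator) -> str:
    """Permute the subject within consecutive fixed-width windows; a
    shorter remainder window is permuted on its own."""
    chars = np.frombuffer(subject.encode(), dtype="S1").copy()
    for lo in range(0, len(chars), window):
        rng.shuffle(chars[lo:lo + window])
    return chars.tobytes().decode()


def shuffle_evalue(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    shuffle_window: int = DEFAULT_SHUFFLE_WINDOW,
    db_size: int = 1,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> float:
    """Composition-adjusted E-value from window-shuffled subjects.

    A Gumbel distribution is fitted by maximum likelihood to the
    shuffled score sample so that tail probabilities far below 1/n are
    resolvable.  With a degenerate sample (zero variance, e.g. a
    mononucleotide subject) the empirical rank ``(r+1)/(n+1)`` is used
    instead.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    scheme = scheme or ScoringScheme()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if observed is None:
        observed = scheme.score(query, subject)
    scores = np.array(
        [
            scheme.score(query, shuffle_subject(subject, shuffle_window, rng))
            for _ in range(n_shuffles)
        ]
    )
    if scores.std() < 1e-9:
        r = int((scores >= observed).sum())
        p = (r + 1) / (n_shuffles + 1)
    else:
        loc, scale = stats.gumbel_r.fit(scores)
        p = float(stats.gumbel_r.sf(observed, loc, scale))
    return db_size * p


def find_homologs(
    ucne: Ucne,
    candidates: list[CandidateRegion],
    genome: str = "target",
    scheme: ScoringScheme | None = None,
    threshold: float = DEFAULT_EVALUE,
    n_shuffles: int = DEFAULT_SHUFFLES,
    shuffle_window: int = DEFAULT_SHUFFLE_WINDOW,
    db_size: int | None = None,
    seed: int = 0,
) -> list[HomologyHit]:
    """Score every candidate region against the UCNE; accept at
    E ≤ threshold (the bound is inclusive).

    db_size defaults to the number of candidate regions evaluated.
    """
    scheme = scheme or ScoringScheme()
    if db_size is None:
        db_size = max(1, len(candidates))
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    for cand in candidates:
        raw, bit, (qspan, sspan) = local_align(ucne.sequence, cand.seq, scheme)
        e = shuffle_evalue(
            ucne.sequence, cand.seq, scheme,
            n_shuffles=n_shuffles, shuffle_window=shuffle_window,
            db_size=db_size, seed=rng, observed=raw,
        )
        iv = cand.interval
        if sspan[1] > sspan[0]:
            if cand.strand == "-":
                hit_iv = GenomicInterval(
                    iv.chrom, iv.end - sspan[1], iv.end - sspan[0], "-"
                )
            else:
                hit_iv = GenomicInterval(
                    iv.chrom, iv.start + sspan[0], iv.start + sspan[1], "+"
                )
        else:
            hit_iv = iv
        hits.append(
            HomologyHit(
                ucne_id=ucne.id, genome=genome, interval=hit_iv,
                raw=raw, bitscore=bit, e_value=e, accepted=e <= threshold,
            )
        )
    return hits


def build_paralog_catalog(
    ucnes: list[Ucne],
    self_candidates: dict[str, list[CandidateRegion]],
    scheme: ScoringScheme | None = None,
    threshold: float = DEFAULT_EVALUE,
    n_shuffles: int = DEFAULT_SHUFFLES,
    shuffle_window: int = DEFAULT_SHUFFLE_WINDOW,
    seed: int = 0,
) -> ParalogCatalog:
    """Reference-genome paralogs per UCNE, found by aligning each UCNE
    to conserved reference segments outside its own locus.

    Paralogs need not themselves qualify as UCNEs; candidates
    overlapping the UCNE's own locus are skipped defensively.
    """
    scheme = scheme or ScoringScheme()
    catalog: ParalogCatalog = {}
    rng = np.random.default_rng(seed)
    for ucne in ucnes:
        entries: list[ParalogEntry] = []
        for cand in self_candidates.get(ucne.id, []):
            if cand.interval.overlaps(ucne.interval):
                continue
            raw = scheme.score(ucne.sequence, cand.seq)
            e = shuffle_evalue(
                ucne.sequence, cand.seq, scheme,
                n_shuffles=n_shuffles, shuffle_window=shuffle_window,
                db_size=max(1, len(self_candidates.get(ucne.id, []))),
                seed=rng, observed=raw,
            )
            if e <= threshold:
                entries.append(ParalogEntry(cand.interval, cand.seq, e))
        catalog[ucne.id] = entries
    return catalog


def flag_paralogs(
    hit: HomologyHit,
    hit_seq: str,
    ucne_seq: str,
    catalog: ParalogCatalog,
    scheme: ScoringScheme | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    shuffle_window: int = DEFAULT_SHUFFLE_WINDOW,
    db_size: int = 1,
    seed: int = 0,
) -> HomologyHit:
    """Flag the hit as a paralog if some catalog paralog aligns to the
    hit sequence with a strictly lower E-value than the UCNE itself.

    An exact tie keeps ortholog status.  The target (fish) sequence is
    the shuffled subject in both comparisons, so E-values are on a
    common footing.
    """
    scheme = scheme or ScoringScheme()
    paralogs = catalog.get(hit.ucne_id, [])
    if not paralogs:
        return replace(hit, paralog_flag=False)
    e_self = shuffle_evalue(
        ucne_seq, hit_seq, scheme, n_shuffles=n_shuffles,
        shuffle_window=shuffle_window, db_size=db_size, seed=seed,
    )
    for p in paralogs:
        e_par = shuffle_evalue(
            p.seq, hit_seq, scheme, n_shuffles=n_shuffles,
            shuffle_window=shuffle_window, db_size=db_size, seed=seed,
        )
        if e_par < e_self:
            return replace(hit, paralog_flag=True)
    return replace(hit, paralog_flag=False)
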