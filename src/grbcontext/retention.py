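"""Retention patterns of UCNEs across duplicate orthologs.

For a reference gene and one duplicated genome, each of the gene's
intronic/UTR UCNEs either survives (has an accepted, non-paralog
homolog) in a given ortholog copy or not.  The copy with the most
surviving UCNEs is the *major ortholog*; with

- ``a`` = UCNEs present only in the major copy,
- ``b`` = present in the major and at least one minor copy,
- ``c`` = present only in minor copies,

a case is *winner-takes-all* if ``a/(a+b+c) > 0.8``, *reciprocal* if
``c/(a+b+c) > 0.2`` and *concordant* otherwise (strict inequalities;
the two conditions are mutually exclusive).

The *winner score* weighs each UCNE by its alignment bitscore:
``W = 100 · C_major / C_total`` where ``C_total`` sums the score matrix
``c_ij`` over all UCNEs i and ortholog columns j and ``C_major`` is the
largest column sum.  A permutation null is built by shuffling each
UCNE's row of scores across ortholog columns independently, re-deriving
the major copy within every replicate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology import HomologyHit
from .intervals import GenomicInterval

WINNER_CUT = 0.8
RECIPROCAL_CUT = 0.2

LABEL_WINNER = "winner"
LABEL_CONCORDANT = "concordant"
LABEL_RECIPROCAL = "reciprocal"


def classify_pattern(
    a: int, b: int, c: int,
    winner_cut: float = WINNER_CUT,
    reciprocal_cut: float = RECIPROCAL_CUT,
) -> str:
    """Label an (a, b, c) retention triplet.

    Strict inequalities: a boundary case like (4, 0, 1) — a/n exactly
    0.8 and c/n exactly 0.2 — is concordant.
    """
    if min(a, b, c) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c
    if n == 0:
        raise ValueError("retention pattern undefined for a+b+c == 0")
    if a / n > winner_cut:
        return LABEL_WINNER
    if c / n > reciprocal_cut:
        return LABEL_RECIPROCAL
    return LABEL_CONCORDANT


@dataclass
class ScoreMatrix:
    """Conservation scores c_ij for one (reference gene, genome) case."""

    gene_id: str
    genome: str
    ucne_ids: list[str]
    ortholog_ids: list[str]
    scores: np.ndarray  # shape (n_ucnes, n_orthologs); 0 = not retained

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.ucne_ids), len(self.ortholog_ids)):
            raise ValueError("score matrix shape mismatch")
        if (self.scores < 0).any():
            raise ValueError("conservation scores must be >= 0")

    @property
    def n_orthologs(self) -> int:
        return len(self.ortholog_ids)

    @property
    def presence(self) -> np.ndarray:
        return self.scores > 0


@dataclass
class RetentionPattern:
    gene_id: str
    genome: str
    a: int
    b: int
    c: int
    major_ortholog_id: str
    label: str | None = None
    major_tie: bool = False


@dataclass
class WinnerScoreCase:
    gene_id: str
    genome: str
    c_total: float
    c_major: float
    w: float
    major_ortholog_id: str


@dataclass
class NullHistogram:
    bin_edges: np.ndarray
    mean_freq: np.ndarray
    sd_freq: np.ndarray
    n_shuffles: int


def case_from_hits(
    gene_id: str,
    genome: str,
    ucne_ids: list[str],
    hits: list[HomologyHit],
    ortholog_spans: dict[str, GenomicInterval],
) -> ScoreMatrix:
    """Build the c_ij matrix from accepted, non-paralog hits.

    A hit contributes to ortholog j if its target interval overlaps
    that ortholog's span; c_ij is the best bitscore among contributing
    hits (zero if none).
    """
    ortholog_ids = sorted(ortholog_spans)
    scores = np.zeros((len(ucne_ids), len(ortholog_ids)))
    index = {u: i for i, u in enumerate(ucne_ids)}
    for hit in hits:
        if not hit.accepted or hit.paralog_flag or hit.ucne_id not in index:
            continue
        for j, oid in enumerate(ortholog_ids):
            if ortholog_spans[oid].overlaps(hit.interval):
                i = index[hit.ucne_id]
                scores[i, j] = max(scores[i, j], hit.bitscore)
    return ScoreMatrix(gene_id, genome, list(ucne_ids), ortholog_ids, scores)


def tally_pattern(case: ScoreMatrix) -> RetentionPattern:
    """Count a/b/c with all minor orthologs pooled.

    The major ortholog is the copy retaining the most UCNEs; ties break
    by larger bitscore column sum, then lexicographic id, and are
    flagged.
    """
    if case.n_orthologs < 1:
        raise ValueError(f"gene {case.gene_id}: no orthologs in {case.genome}")
    pres = case.presence
    counts = pres.sum(axis=0)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    major_tie = len(tied) > 1
    if major_tie:
        sums = case.scores[:, tied].sum(axis=0)
        tied = tied[np.flatnonzero(sums == sums.max())]
        j_major = min(tied, key=lambda j: case.ortholog_ids[j])
    else:
        j_major = int(tied[0])
    in_major = pres[:, j_major]
    in_minor = np.delete(pres, j_major, axis=1).any(axis=1)
    a = int((in_major & ~in_minor).sum())
    b = int((in_major & in_minor).sum())
    c = int((~in_major & in_minor).sum())
    return RetentionPattern(
        case.gene_id, case.genome, a, b, c,
        major_ortholog_id=case.ortholog_ids[j_major], major_tie=major_tie,
    )


def classify_case(case: ScoreMatrix) -> RetentionPattern:
    pattern = tally_pattern(case)
    pattern.label = classify_pattern(pattern.a, pattern.b, pattern.c)
    return pattern


def eligibility_filter(
    cases: list[ScoreMatrix],
    min_orthologs: int = 2,
    min_major_ucnes: int = 3,
) -> list[ScoreMatrix]:
    """Winner-score eligibility.

    Per case: at least two orthologs and at least ``min_major_ucnes``
    UCNEs retained in the major ortholog.  Per gene (across genomes): a
    gene is dropped outright if no ortholog anywhere retained a UCNE or
    no genome annotates more than one ortholog.
    """
    by_gene: dict[str, list[ScoreMatrix]] = {}
    for case in cases:
        by_gene.setdefault(case.gene_id, []).append(case)
    keep: list[ScoreMatrix] = []
    for gene_cases in by_gene.values():
        any_retained = any(c.presence.any() for c in gene_cases)
        any_duplicated = any(c.n_orthologs > 1 for c in gene_cases)
        if not (any_retained and any_duplicated):
            continue
        for case in gene_cases:
            if case.n_orthologs < min_orthologs:
                continue
            major_count = case.presence.sum(axis=0).max()
            if major_count >= min_major_ucnes:
                keep.append(case)
    return keep


def winner_score(case: ScoreMatrix) -> WinnerScoreCase:
    """W = 100 × C_major / C_total with the major column re-derived as
    the largest bitscore column sum."""
    col_sums = case.scores.sum(axis=0)
    c_total = float(col_sums.sum())
    if c_total == 0:
        raise ValueError(f"gene {case.gene_id}: zero total conservation score")
    j = int(col_sums.argmax())
    c_major = float(col_sums[j])
    return WinnerScoreCase(
        case.gene_id, case.genome, c_total, c_major,
        w=100.0 * c_major / c_total, major_ortholog_id=case.ortholog_ids[j],
    )


def default_bins(cases: list[ScoreMatrix]) -> np.ndarray:
    """Width-5 bins; from 50 when every case has two orthologs (W >= 50
    then), from 0 otherwise."""
    lo = 50 if all(c.n_orthologs == 2 for c in cases) else 0
    return np.arange(lo, 105, 5, dtype=float)


def _w_of_matrix(scores: np.ndarray) -> float:
    col = scores.sum(axis=0)
    return 100.0 * col.max() / col.sum()


def winner_score_histogram(
    ws: list[float], bin_edges: np.ndarray
) -> np.ndarray:
    counts, _ = np.histogram(
        np.clip(ws, bin_edges[0], bin_edges[-1] - 1e-9), bins=bin_edges
    )
    return counts / max(1, len(ws))


def permutation_null(
    cases: list[ScoreMatrix],
    n_shuffles: int = 500,
    bin_edges: np.ndarray | None = None,
    seed: int = 0,
) -> NullHistogram:
    """Random-retention null for the winner-score histogram.

    Per shuffle, each UCNE's row of c_ij is permuted across its gene's
    ortholog columns independently; winner scores are recomputed with
    the major column re-identified; the histogram frequency vector is
    recorded.  Returns the per-bin mean and standard deviation over
    shuffles.
    """
    if not cases:
        raise ValueError("no eligible cases")
    if bin_edges is None:
        bin_edges = default_bins(cases)
    rng = np.random.default_rng(seed)
    freqs = np.empty((n_shuffles, len(bin_edges) - 1))
    for s in range(n_shuffles):
        ws = []
        for case in cases:
            perm = case.scores.copy()
            for row in perm:
                rng.shuffle(row)
            ws.append(_w_of_matrix(perm))
        freqs[s] = winner_score_histogram(ws, bin_edges)
    return NullHistogram(
        bin_edges=bin_edges,
        mean_freq=freqs.mean(axis=0),
        sd_freq=freqs.std(axis=0),
        n_shuffles=n_shuffles,
    )


def patterns_table(patterns: list[RetentionPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": p.gene_id, "genome": p.genome, "a": p.a, "b": p.b,
                "c": p.c, "label": p.label, "major_id": p.major_ortholog_id,
                "major_tie": p.major_tie,
            }
            for p in patterns
        ]
    )
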