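"""UCNE clusters, orthologous syntenic subclusters, and target calls.

A cluster is a maximal run of UCNEs on one chromosome in *both*
reference genomes with neighbors at most 0.5 Mb apart in both.  After a
whole-genome duplication, the surviving homologs of a cluster's UCNEs
form syntenic subclusters in the duplicated genome (same chromosome or
scaffold, 0.5 Mb chaining rule); the subcluster retaining the most
UCNEs is the *major* one.  Minor subclusters that look like assembly
artifacts can be merged back into the major one under explicit,
audited conditions.  Genes associated with subclusters in every tested
genome are called regulatory *targets*; the rest are bystanders.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .homology import HomologyHit
from .intervals import GeneModel, GenomicInterval
from .retention import RetentionPattern, classify_pattern
from .scan import Ucne

DEFAULT_MAX_GAP = 500_000
DEFAULT_ASSOC_DIST = 100_000
DEFAULT_GAP_FLANK_DIST = 50_000


@dataclass
class DualCoordUcne:
    """A UCNE with coordinates in both reference genomes (the second
    genome's location comes from its alignment provenance)."""

    ucne_id: str
    ref: GenomicInterval
    second: GenomicInterval | None


@dataclass
class UcneCluster:
    id: str
    ucne_ids: list[str]                      # ordered along the reference
    ref_span: GenomicInterval
    second_span: GenomicInterval | None
    gene_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.ucne_ids)


@dataclass
class SyntenicSubcluster:
    cluster_id: str
    genome: str
    hits: list[HomologyHit]
    span: GenomicInterval
    role: str = "minor"                       # major | minor
    merged_from: list[str] = field(default_factory=list)
    unplaced: bool = False
    gap_flanked: bool = False

    @property
    def member_ucnes(self) -> set[str]:
        return {h.ucne_id for h in self.hits}

    @property
    def id(self) -> str:
        return f"{self.cluster_id}:{self.genome}:{self.span.chrom}:{self.span.start}"


@dataclass
class GeneCall:
    gene_id: str
    associated: dict[str, bool]
    call: str                                 # target | bystander


@dataclass
class AssemblyAnnotation:
    """Scaffold placement and assembly-gap annotation for one genome."""

    unplaced_scaffolds: set[str] = field(default_factory=set)
    gaps: list[GenomicInterval] = field(default_factory=list)

    def is_unplaced(self, chrom: str) -> bool:
        return chrom in self.unplaced_scaffolds

    def is_gap_flanked(
        self, span: GenomicInterval, flank_dist: int = DEFAULT_GAP_FLANK_DIST
    ) -> bool:
        left = right = False
        for g in self.gaps:
            if g.chrom != span.chrom:
                continue
            if g.end <= span.start and span.start - g.end <= flank_dist:
                left = True
            if g.start >= span.end and g.start - span.end <= flank_dist:
                right = True
        return left and right


def build_clusters(
    ucnes: list[DualCoordUcne], max_gap: int = DEFAULT_MAX_GAP
) -> list[UcneCluster]:
    """Chain UCNEs along the reference; a link requires the same
    chromosome in both genomes and a gap <= max_gap in both.

    UCNEs without second-genome coordinates are unlinkable and come out
    as singleton clusters.
    """
    ordered = sorted(ucnes, key=lambda u: (u.ref.chrom, u.ref.start))
    clusters: list[list[DualCoordUcne]] = []
    current: list[DualCoordUcne] = []
    for u in ordered:
        if current:
            prev = current[-1]
            linkable = (
                u.second is not None
                and prev.second is not None
                and u.ref.chrom == prev.ref.chrom
                and u.second.chrom == prev.second.chrom
                and u.ref.distance_to(prev.ref) <= max_gap
                and u.second.distance_to(prev.second) <= max_gap
            )
            if not linkable:
                clusters.append(current)
                current = []
        current.append(u)
    if current:
        clusters.append(current)
    out = []
    for i, members in enumerate(clusters, 1):
        ref_span = GenomicInterval(
            members[0].ref.chrom, members[0].ref.start, members[-1].ref.end
        )
        seconds = [m.second for m in members if m.second is not None]
        second_span = None
        if seconds:
            second_span = GenomicInterval(
                seconds[0].chrom,
                min(s.start for s in seconds),
                max(s.end for s in seconds),
            )
        out.append(
            UcneCluster(
                id=f"cluster_{i:03d}",
                ucne_ids=[m.ucne_id for m in members],
                ref_span=ref_span,
                second_span=second_span,
            )
        )
    return out


def associate_genes(
    cluster: UcneCluster, ucnes: dict[str, Ucne], genes: list[GeneModel]
) -> list[str]:
    """Genes associated with a cluster in the reference genome: hosts of
    intronic/UTR members plus flanks of intergenic members, restricted
    to protein-coding non-pseudogenes with annotated CDS."""
    coding = {g.id for g in genes if g.is_coding}
    out: set[str] = set()
    for uid in cluster.ucne_ids:
        u = ucnes[uid]
        out.update(g for g in u.genes if g in coding)
    return sorted(out)


def find_subclusters(
    cluster: UcneCluster,
    hits: list[HomologyHit],
    genome: str,
    max_gap: int = DEFAULT_MAX_GAP,
    assembly: AssemblyAnnotation | None = None,
) -> list[SyntenicSubcluster]:
    """Chain a cluster's accepted non-paralog hits in one genome into
    syntenic subclusters; the one retaining the most distinct UCNEs is
    the major subcluster."""
    member_ids = set(cluster.ucne_ids)
    usable = [
        h for h in hits
        if h.accepted and not h.paralog_flag and h.ucne_id in member_ids
    ]
    if not usable:
        return []
    usable.sort(key=lambda h: (h.interval.chrom, h.interval.start))
    chains: list[list[HomologyHit]] = []
    current = [usable[0]]
    for h in usable[1:]:
        prev = current[-1]
        if (
            h.interval.chrom == prev.interval.chrom
            and h.interval.distance_to(prev.interval) <= max_gap
        ):
            current.append(h)
        else:
            chains.append(current)
            current = [h]
    chains.append(current)
    subs = []
    for chain in chains:
        span = GenomicInterval(
            chain[0].interval.chrom,
            min(h.interval.start for h in chain),
            max(h.interval.end for h in chain),
        )
        sub = SyntenicSubcluster(cluster.id, genome, chain, span)
        if assembly is not None:
            sub.unplaced = assembly.is_unplaced(span.chrom)
            sub.gap_flanked = assembly.is_gap_flanked(span)
        subs.append(sub)
    best = max(subs, key=lambda s: len(s.member_ucnes))
    best.role = "major"
    return subs


def _index_range(
    sub: SyntenicSubcluster, cluster: UcneCluster
) -> tuple[int, int]:
    idx = [cluster.ucne_ids.index(u) for u in sub.member_ucnes]
    return min(idx), max(idx)


def merge_assembly_fragments(
    cluster: UcneCluster,
    subclusters: list[SyntenicSubcluster],
) -> tuple[list[SyntenicSubcluster], list[dict]]:
    """Merge assembly-artifact minors into the major subcluster.

    A minor is merged iff (it is on an unplaced scaffold OR flanked by
    assembly gaps on both sides) AND its members map to a region of the
    reference cluster disjoint from the major's member range.  Returns
    the revised subcluster list plus an audit report of every minor
    considered (the published analysis did this step by eye; here it is
    automated with provenance).
    """
    majors = [s for s in subclusters if s.role == "major"]
    if not majors:
        return subclusters, []
    major = majors[0]
    report = []
    kept: list[SyntenicSubcluster] = []
    for sub in subclusters:
        if sub is major:
            continue
        assembly_suspect = sub.unplaced or sub.gap_flanked
        lo_m, hi_m = _index_range(major, cluster)
        lo_s, hi_s = _index_range(sub, cluster)
        disjoint = hi_s < lo_m or hi_m < lo_s
        merged = assembly_suspect and disjoint
        report.append(
            {
                "minor_id": sub.id, "unplaced": sub.unplaced,
                "gap_flanked": sub.gap_flanked, "ref_range_disjoint": disjoint,
                "merged": merged,
            }
        )
        if merged:
            major.merged_from.append(sub.id)
            major.hits = major.hits + sub.hits
        else:
            kept.append(sub)
    return [major] + kept, report


def associate_fish_genes(
    sub: SyntenicSubcluster,
    genes: list[GeneModel],
    max_dist: int = DEFAULT_ASSOC_DIST,
) -> list[str]:
    """Duplicate-genome genes associated with a subcluster: containing a
    member hit, or within ``max_dist`` of the nearest one (gap distance,
    zero when overlapping)."""
    out = []
    for g in genes:
        dists = [
            g.interval.distance_to(h.interval)
            for h in sub.hits
            if h.interval.chrom == g.interval.chrom
        ]
        if dists and min(dists) <= max_dist:
            out.append(g.id)
    return sorted(out)


def call_targets(
    gene_ids: list[str],
    associations: dict[str, set[str]],
) -> list[GeneCall]:
    """Target = associated with the (sub)cluster in every tested genome;
    anything else (including genes with no ortholog anywhere) is a
    bystander."""
    calls = []
    for gid in gene_ids:
        flags = {genome: gid in assoc for genome, assoc in associations.items()}
        target = bool(flags) and all(flags.values())
        calls.append(GeneCall(gid, flags, "target" if target else "bystander"))
    return calls


def classify_cluster_retention(
    cluster: UcneCluster,
    subclusters: list[SyntenicSubcluster],
    genome: str,
) -> RetentionPattern | None:
    """Cluster-level (a, b, c) with the gene-level rule: a = UCNEs with
    accepted orthologs only in the major subcluster, b = in major and
    at least one minor, c = only in minors.  None if nothing survived."""
    majors = [s for s in subclusters if s.role == "major"]
    if not majors:
        return None
    in_major = majors[0].member_ucnes
    in_minor: set[str] = set()
    for s in subclusters:
        if s.role != "major":
            in_minor |= s.member_ucnes
    a = len(in_major - in_minor)
    b = len(in_major & in_minor)
    c = len(in_minor - in_major)
    if a + b + c == 0:
        return None
    return RetentionPattern(
        cluster.id, genome, a, b, c,
        major_ortholog_id=majors[0].id,
        label=classify_pattern(a, b, c),
    )
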