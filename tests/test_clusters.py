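"""Cluster construction, subclusters, merging and target calls."""
import pytest

from grbcontext.clusters import (
    AssemblyAnnotation, DualCoordUcne, SyntenicSubcluster, associate_fish_genes,
    associate_genes, build_clusters, call_targets, classify_cluster_retention,
    find_subclusters, merge_assembly_fragments,
)
from grbcontext.homology import HomologyHit
from grbcontext.intervals import GeneModel, GenomicInterval
from grbcontext.scan import Ucne

MB = 1_000_000


def _dual(uid, ref_start, second_start, ref_chrom="chr1", second_chrom="b1"):
    return DualCoordUcne(
        uid,
        GenomicInterval(ref_chrom, ref_start, ref_start + 300),
        GenomicInterval(second_chrom, second_start, second_start + 300),
    )


def _hit(uid, chrom, start, accepted=True, paralog=False, bit=200.0):
    return HomologyHit(
        uid, "fish", GenomicInterval(chrom, start, start + 300),
        raw=800.0, bitscore=bit, e_value=1e-9, accepted=accepted,
        paralog_flag=paralog,
    )


class TestBuildClusters:
    def test_linked_when_close_in_both_genomes(self):
        cl = build_clusters([_dual("u1", 0, 0), _dual("u2", 400_000, 350_000)])
        assert len(cl) == 1 and cl[0].ucne_ids == ["u1", "u2"]

    def test_split_when_far_in_second_genome_only(self):
        cl = build_clusters([_dual("u1", 0, 0), _dual("u2", 400_000, 600_001)])
        assert len(cl) == 2

    def test_split_on_second_genome_chromosome_change(self):
        cl = build_clusters(
            [_dual("u1", 0, 0), _dual("u2", 100_000, 0, second_chrom="b2")]
        )
        assert len(cl) == 2

    def test_missing_second_coordinates_unlinkable(self):
        u = DualCoordUcne("u2", GenomicInterval("chr1", 1000, 1300), None)
        cl = build_clusters([_dual("u1", 0, 0), u])
        assert len(cl) == 2

    def test_maximality_no_mergeable_neighbors(self):
        ucnes = [_dual(f"u{i}", i * 200_000, i * 200_000) for i in range(10)]
        clusters = build_clusters(ucnes)
        assert len(clusters) == 1
        assert clusters[0].size == 10


class TestAssociateGenes:
    def _world(self):
        host = GeneModel(
            "host", GenomicInterval("chr1", 0, 10_000, "+"),
            exons=[GenomicInterval("chr1", 0, 200, "+"),
                   GenomicInterval("chr1", 9_800, 10_000, "+")],
            cds=[GenomicInterval("chr1", 100, 200, "+"),
                 GenomicInterval("chr1", 9_800, 9_900, "+")],
        )
        flank = GeneModel(
            "flank", GenomicInterval("chr1", 40_000, 50_000, "+"),
            exons=[GenomicInterval("chr1", 40_000, 50_000, "+")],
            cds=[GenomicInterval("chr1", 41_000, 42_000, "+")],
        )
        pseudo = GeneModel(
            "pseudo", GenomicInterval("chr1", 60_000, 70_000, "+"),
            exons=[GenomicInterval("chr1", 60_000, 70_000, "+")],
            cds=[GenomicInterval("chr1", 61_000, 62_000, "+")],
            is_pseudogene=True,
        )
        ucnes = {
            "u1": Ucne("u1", GenomicInterval("chr1", 5_000, 5_300),
                       position_class="intronic", genes=["host"]),
            "u2": Ucne("u2", GenomicInterval("chr1", 30_000, 30_300),
                       position_class="intergenic", genes=["host", "flank"]),
            "u3": Ucne("u3", GenomicInterval("chr1", 55_000, 55_300),
                       position_class="intergenic", genes=["flank", "pseudo"]),
        }
        return [host, flank, pseudo], ucnes

    def test_hosts_flanks_and_pseudogene_filter(self):
        genes, ucnes = self._world()
        clusters = build_clusters(
            [
                DualCoordUcne(u.id, u.interval, GenomicInterval("b1", u.interval.start, u.interval.end))
                for u in ucnes.values()
            ]
        )
        assert len(clusters) == 1
        out = associate_genes(clusters[0], ucnes, genes)
        assert out == ["flank", "host"]          # pseudogene excluded


class TestFindSubclusters:
    def _cluster(self, n=5):
        return build_clusters(
            [_dual(f"u{i}", i * 100_000, i * 100_000) for i in range(n)]
        )[0]

    def test_single_scaffold_single_major(self):
        cl = self._cluster(3)
        hits = [_hit(f"u{i}", "scafA", i * 100_000) for i in range(3)]
        subs = find_subclusters(cl, hits, "fish")
        assert len(subs) == 1 and subs[0].role == "major"
        assert subs[0].member_ucnes == {"u0", "u1", "u2"}

    def test_major_is_argmax_of_member_count(self):
        cl = self._cluster(5)
        hits = [_hit(f"u{i}", "chrA", i * 100_000) for i in range(3)]
        hits += [_hit(f"u{i}", "chrB", i * 100_000) for i in (3, 4)]
        subs = find_subclusters(cl, hits, "fish")
        roles = {s.span.chrom: s.role for s in subs}
        assert roles == {"chrA": "major", "chrB": "minor"}

    def test_distant_singleton_becomes_minor(self):
        cl = self._cluster(4)
        hits = [_hit(f"u{i}", "chrA", i * 100_000) for i in range(3)]
        hits.append(_hit("u3", "chrA", 3 * MB))
        subs = find_subclusters(cl, hits, "fish")
        assert len(subs) == 2
        assert {len(s.hits) for s in subs} == {1, 3}

    def test_paralog_and_rejected_hits_excluded(self):
        cl = self._cluster(3)
        hits = [
            _hit("u0", "chrA", 0),
            _hit("u1", "chrA", 100_000, paralog=True),
            _hit("u2", "chrA", 200_000, accepted=False),
        ]
        subs = find_subclusters(cl, hits, "fish")
        assert subs[0].member_ucnes == {"u0"}


class TestMergeAssemblyFragments:
    def _setup(self, minor_chrom="scaf_un", minor_ucnes=(3, 4), unplaced=True,
               gap_flanked=False):
        cl = build_clusters(
            [_dual(f"u{i}", i * 100_000, i * 100_000) for i in range(5)]
        )[0]
        assembly = AssemblyAnnotation(
            unplaced_scaffolds={"scaf_un"} if unplaced else set(),
            gaps=[GenomicInterval("chr9", 1, 1_000),
                  GenomicInterval("chr9", 110_000, 111_000)]
            if gap_flanked else [],
        )
        hits = [_hit(f"u{i}", "chrMain", i * 100_000) for i in range(3)]
        hits += [_hit(f"u{i}", minor_chrom, k * 100_000 + 2_000)
                 for k, i in enumerate(minor_ucnes)]
        subs = find_subclusters(cl, hits, "fish", assembly=assembly)
        return cl, subs

    def test_unplaced_disjoint_minor_merged(self):
        cl, subs = self._setup()
        merged, report = merge_assembly_fragments(cl, subs)
        assert len(merged) == 1
        assert merged[0].member_ucnes == {"u0", "u1", "u2", "u3", "u4"}
        assert report[0]["merged"]
        assert merged[0].merged_from      # provenance recorded

    def test_placed_unflanked_minor_not_merged(self):
        cl, subs = self._setup(minor_chrom="chr7", unplaced=False)
        merged, report = merge_assembly_fragments(cl, subs)
        assert len(merged) == 2
        assert not report[0]["merged"]

    def test_gap_flanked_minor_merged(self):
        cl, subs = self._setup(minor_chrom="chr9", unplaced=False,
                               gap_flanked=True)
        merged, _ = merge_assembly_fragments(cl, subs)
        assert len(merged) == 1

    def test_overlapping_reference_ranges_block_merge(self):
        # minor covers u1 which lies inside the major's u0..u2 range
        cl, subs = self._setup(minor_ucnes=(1, 4))
        merged, report = merge_assembly_fragments(cl, subs)
        assert len(merged) == 2
        assert not report[0]["merged"]


class TestFishGeneAssociationAndTargets:
    def _sub(self):
        hits = [_hit(f"u{i}", "chrA", 500_000 + i * 50_000) for i in range(3)]
        return SyntenicSubcluster(
            "cl1", "fish", hits,
            GenomicInterval("chrA", 500_000, 900_000), role="major",
        )

    def _gene(self, gid, start, end):
        return GeneModel(
            gid, GenomicInterval("chrA", start, end, "+"),
            exons=[GenomicInterval("chrA", start, end, "+")],
            cds=[GenomicInterval("chrA", start + 100, start + 200, "+")],
        )

    def test_distance_rule(self):
        sub = self._sub()
        genes = [
            self._gene("contains", 480_000, 520_000),   # overlaps a hit
            self._gene("near", 350_000, 450_000),       # 50 kb away
            self._gene("far", 100_000, 200_000),        # 300 kb away
        ]
        assert associate_fish_genes(sub, genes) == ["contains", "near"]

    def test_call_targets_requires_all_genomes(self):
        assoc = {
            "fugu": {"gA", "gB"},
            "medaka": {"gA"},
            "zebrafish": {"gA", "gB"},
        }
        calls = {c.gene_id: c.call for c in call_targets(["gA", "gB", "gC"], assoc)}
        assert calls == {"gA": "target", "gB": "bystander", "gC": "bystander"}


class TestClusterRetention:
    def _cluster(self, n):
        return build_clusters(
            [_dual(f"u{i}", i * 100_000, i * 100_000) for i in range(n)]
        )[0]

    def _subs(self, cl, major_ucnes, minor_ucnes, both=()):
        major = SyntenicSubcluster(
            cl.id, "fish",
            [_hit(u, "chrA", 0) for u in list(major_ucnes) + list(both)],
            GenomicInterval("chrA", 1, 2), role="major",
        )
        minor = SyntenicSubcluster(
            cl.id, "fish",
            [_hit(u, "chrB", 0) for u in list(minor_ucnes) + list(both)],
            GenomicInterval("chrB", 1, 2), role="minor",
        )
        return [major, minor] if minor.hits else [major]

    def test_all_in_major_is_winner(self):
        cl = self._cluster(5)
        pat = classify_cluster_retention(
            cl, self._subs(cl, [f"u{i}" for i in range(5)], []), "fish"
        )
        assert (pat.a, pat.b, pat.c) == (5, 0, 0)
        assert pat.label == "winner"

    def test_shared_and_minor_only_counts(self):
        cl = self._cluster(6)
        pat = classify_cluster_retention(
            cl,
            self._subs(cl, ["u0", "u1", "u2"], ["u4", "u5"], both=["u3"]),
            "fish",
        )
        assert (pat.a, pat.b, pat.c) == (3, 1, 2)
        assert pat.label == "reciprocal"     # 2/6 > 0.2

    def test_no_subclusters_gives_none(self):
        cl = self._cluster(3)
        assert classify_cluster_retention(cl, [], "fish") is None
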