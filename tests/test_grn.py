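import numpy as np
import pytest

from cisgrn.core import GeneModel, GenomicInterval
from cisgrn.enhancers import EnhancerRegion
from cisgrn.expression import ProportionProfile
from cisgrn.grn import (
    FootprintCall,
    assign_targets,
    build_links,
    count_bound_motifs,
    subnetwork_x1,
    tss_of,
)
from cisgrn.motifs import MotifTFMap
from oracles import brute_force_assign


def gene(gene_id, start, end, strand, chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end,
                                              name=gene_id, strand=strand))


def enhancer(name, start, end, chrom="chr1"):
    return EnhancerRegion(GenomicInterval(chrom, start, end, name=name),
                          partner_me1_id="m", gap_bp=0)


def footprint(motif_id, start, end, bound=True, chrom="chr1"):
    return FootprintCall(GenomicInterval(chrom, start, end), motif_id, 1.0, bound)


class TestTss:
    def test_plus_strand(self):
        assert tss_of(gene("g", 5000, 8000, "+")) == 5000

    def test_minus_strand(self):
        assert tss_of(gene("g", 12_000, 15_000, "-")) == 14_999


class TestAssignTargets:
    def test_nearest_wins(self):
        genes = [gene("plus", 5000, 8000, "+"), gene("minus", 12_000, 15_000, "-")]
        (a,) = assign_targets([enhancer("e", 9000, 9200)], genes)
        # TSS 5000 is 4000 away; TSS 14999 is 5800 away
        assert a.gene_id == "plus"
        assert a.distance == 4000

    def test_tss_inside_enhancer(self):
        genes = [gene("g", 9100, 12_000, "+")]
        (a,) = assign_targets([enhancer("e", 9000, 9200)], genes)
        assert a.distance == 0

    def test_tie_breaks_to_upstream_tss(self):
        genes = [gene("right", 1200, 2000, "+"), gene("left", 100, 801, "+")]
        # enhancer [900,1101): left TSS 100 -> dist 800; right TSS 1200 -> dist 100
        # craft a true tie: distances to TSSs 800 and 1200 from [900, 1001)
        e = enhancer("e", 900, 1001)
        genes = [gene("right", 1200, 2000, "+"), gene("left", 700, 1900, "+")]
        # left TSS 700: dist min(|700-900|, |700-1000|) = 200
        # right TSS 1200: dist min(|1200-900|,|1200-1000|) = 200
        (a,) = assign_targets([e], genes)
        assert a.gene_id == "left"

    def test_geneless_chromosome_skipped(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = assign_targets([enhancer("e", 0, 100, chrom="chrZ")],
                                 [gene("g", 0, 100, "+")])
        assert out == []

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n_genes = int(rng.integers(1, 60))
            n_enh = int(rng.integers(1, 60))
            genes = []
            for i in range(n_genes):
                chrom = f"chr{int(rng.integers(1, 4))}"
                start = int(rng.integers(0, 90_000))
                genes.append(gene(f"g{i}", start, start + int(rng.integers(100, 5000)),
                                  "+" if rng.random() < 0.5 else "-", chrom=chrom))
            enhancers = []
            for i in range(n_enh):
                chrom = f"chr{int(rng.integers(1, 4))}"
                start = int(rng.integers(0, 95_000))
                enhancers.append(enhancer(f"e{i}", start,
                                          start + int(rng.integers(50, 400)),
                                          chrom=chrom))
            got = assign_targets(enhancers, genes)
            assert got == brute_force_assign(enhancers, genes)

    def test_at_most_one_assignment_per_enhancer(self, rng):
        genes = [gene(f"g{i}", i * 1000, i * 1000 + 500, "+") for i in range(20)]
        enhancers = [enhancer(f"e{i}", i * 900, i * 900 + 100) for i in range(30)]
        out = assign_targets(enhancers, genes)
        assert len(out) == len(enhancers)
        assert len({a.enhancer_id for a in out}) == len(out)

    def test_expression_floor_skips_silent_genes(self):
        genes = [gene("near_silent", 1000, 2000, "+"),
                 gene("far_loud", 5000, 6000, "+")]
        e = enhancer("e", 900, 950)
        (default,) = assign_targets([e], genes)
        assert default.gene_id == "near_silent"
        (floored,) = assign_targets(
            [e], genes,
            min_expression={"near_silent": 0.5, "far_loud": 100.0},
            expression_floor=1.0)
        assert floored.gene_id == "far_loud"


class TestBuildLinks:
    MAPPING = MotifTFMap.from_pairs(
        [("M1", "tfA"), ("M1", "tfB"), ("M1", "tfC"), ("M2", "tfD")])
    TFS = {"tfA", "tfB", "tfC", "tfD"}

    def setup_method(self):
        self.enh = [enhancer("e1", 1000, 1500)]
        self.assign = assign_targets(self.enh, [gene("target", 1600, 3000, "+")])

    def test_three_tf_motif_three_links(self):
        links = build_links(self.enh, self.assign,
                            [footprint("M1", 1100, 1112)], self.MAPPING, self.TFS)
        assert len(links) == 3
        assert {l.tf_gene_id for l in links} == {"tfA", "tfB", "tfC"}
        assert all(l.target_gene_id == "target" and l.bound for l in links)

    def test_footprint_outside_enhancer_no_links(self):
        links = build_links(self.enh, self.assign,
                            [footprint("M2", 1500, 1512)], self.MAPPING, self.TFS)
        assert links == []  # book-ended, zero overlap

    def test_one_bp_overlap_counts(self):
        links = build_links(self.enh, self.assign,
                            [footprint("M2", 1499, 1511)], self.MAPPING, self.TFS)
        assert len(links) == 1

    def test_unbound_footprint_kept_with_flag(self):
        links = build_links(self.enh, self.assign,
                            [footprint("M2", 1100, 1112, bound=False)],
                            self.MAPPING, self.TFS)
        assert len(links) == 1
        assert links[0].bound is False

    def test_non_tf_mapped_gene_excluded(self):
        links = build_links(self.enh, self.assign,
                            [footprint("M1", 1100, 1112)], self.MAPPING, {"tfA"})
        assert {l.tf_gene_id for l in links} == {"tfA"}

    def test_link_count_conservation(self, rng):
        enhancers = [enhancer(f"e{i}", i * 2000, i * 2000 + 500) for i in range(10)]
        genes = [gene(f"g{i}", i * 2000 + 600, i * 2000 + 1600, "+")
                 for i in range(10)]
        assignments = assign_targets(enhancers, genes)
        fps = []
        inside = 0
        for k in range(100):
            start = int(rng.integers(0, 20_000))
            f = footprint("M1" if rng.random() < 0.7 else "M2", start, start + 12,
                          bound=bool(rng.random() < 0.5))
            fps.append(f)
            if any(f.interval.overlaps(e.interval) for e in enhancers):
                inside += len(self.MAPPING.tfs_for(f.motif_id))
        links = build_links(enhancers, assignments, fps, self.MAPPING, self.TFS)
        assert len(links) == len(set(
            (l.tf_gene_id, l.target_gene_id, l.enhancer_id, l.motif_id, l.bound)
            for l in links))
        # conservation holds up to dedup; regenerate without dedup collisions
        assert len(links) <= inside

    def test_every_link_footprint_overlaps_enhancer(self, tiny_data):
        from cisgrn.enhancers import call_enhancers
        enh = call_enhancers(tiny_data["ac_peaks"], tiny_data["me1_peaks"])
        genes = tiny_data["genes"]
        assignments = assign_targets(enh, genes)
        tf_genes = {g.gene_id for g in genes if g.is_tf}
        links = build_links(enh, assignments, tiny_data["footprints"],
                           tiny_data["motif_tf_map"], tf_genes)
        enh_by_id = {e.enhancer_id: e for e in enh}
        fp_by_enh = {}
        for f in tiny_data["footprints"]:
            for e in enh:
                if f.interval.overlaps(e.interval):
                    fp_by_enh.setdefault(e.enhancer_id, []).append(f)
        for l in links:
            e = enh_by_id[l.enhancer_id]
            assert any(f.motif_id == l.motif_id and f.bound == l.bound
                       for f in fp_by_enh.get(e.enhancer_id, []))


class TestCountBoundMotifs:
    def test_no_bound_footprints(self):
        mapping = MotifTFMap.from_pairs([("M1", "a"), ("M1", "b")])
        counts = count_bound_motifs([footprint("M1", 0, 12, bound=False)], mapping)
        assert counts == {"a": 0, "b": 0}

    def test_shared_motif_counts_per_tf(self):
        mapping = MotifTFMap.from_pairs([("M1", "a"), ("M1", "b")])
        fps = [footprint("M1", 0, 12), footprint("M1", 100, 112)]
        assert count_bound_motifs(fps, mapping) == {"a": 2, "b": 2}

    def test_planted_counts_recovered(self, rng):
        mapping = MotifTFMap.from_pairs([(f"M{i}", f"tf{i}") for i in range(5)])
        planted = {f"tf{i}": int(rng.integers(0, 20)) for i in range(5)}
        fps = []
        pos = 0
        for i in range(5):
            for _ in range(planted[f"tf{i}"]):
                fps.append(footprint(f"M{i}", pos, pos + 12))
                pos += 20
            fps.append(footprint(f"M{i}", pos, pos + 12, bound=False))
            pos += 20
        assert count_bound_motifs(fps, mapping) == planted


class TestSubnetworkX1:
    def profile(self, gene_id, p1):
        rest = (1.0 - p1) / 2
        return ProportionProfile(gene_id, p1, rest, 1.0 - p1 - rest)

    def link(self, tf, target, bound=True):
        from cisgrn.grn import RegulatoryLink
        return RegulatoryLink(tf, target, "e1", bound, "M1")

    def test_all_below_threshold_empty(self):
        profiles = {g: self.profile(g, 0.2) for g in ("a", "b")}
        g = subnetwork_x1([self.link("a", "b")], profiles, {"a": 1, "b": 2})
        assert len(g) == 0

    def test_edge_retained_above_threshold(self):
        profiles = {g: self.profile(g, 0.34) for g in ("a", "b")}
        g = subnetwork_x1([self.link("a", "b")], profiles, {"a": 5.0, "b": 2.0})
        assert g.has_edge("a", "b")
        assert g.nodes["a"]["tpm_x1"] == 5.0
        assert g.nodes["a"]["p1"] == pytest.approx(0.34)

    def test_filtered_endpoint_drops_edge_and_orphan(self):
        profiles = {"a": self.profile("a", 0.5), "b": self.profile("b", 0.1)}
        g = subnetwork_x1([self.link("a", "b")], profiles, {})
        assert len(g.edges) == 0
        assert len(g.nodes) == 0  # no orphan nodes

    def test_unbound_links_excluded(self):
        profiles = {g: self.profile(g, 0.5) for g in ("a", "b")}
        g = subnetwork_x1([self.link("a", "b", bound=False)], profiles, {})
        assert len(g.edges) == 0

    def test_support_counts_distinct_evidence(self):
        from cisgrn.grn import RegulatoryLink
        profiles = {g: self.profile(g, 0.5) for g in ("a", "b")}
        links = [
            RegulatoryLink("a", "b", "e1", True, "M1"),
            RegulatoryLink("a", "b", "e2", True, "M1"),
            RegulatoryLink("a", "b", "e1", True, "M1"),  # duplicate evidence
        ]
        g = subnetwork_x1(links, profiles, {})
        assert g.edges["a", "b"]["support"] == 2
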