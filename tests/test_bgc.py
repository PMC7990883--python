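"""BGC curation: profile detection, region calling and completeness,
domain-tree-guided merging of split clusters, expected counts, census,
core/accessory spans and the count-size correlation."""

import numpy as np
import pytest

from taxobgc import bgc
from taxobgc.bgc import (
    BGCRegion,
    DomainHit,
    DomainProfile,
    bgc_census,
    call_regions,
    category_from_domains,
    classify_completeness,
    core_accessory_span,
    count_size_correlation,
    detect_domains,
    domain_tree,
    expected_cluster_count,
    hits_from_features,
    merge_fragmented,
)
from taxobgc.genome_io import reverse_complement
from taxobgc.orthology import OrthologGroup, PanGenomePartition
from taxobgc.synthetic_data import (
    BGCTemplate,
    CladeConfig,
    FragmentationPolicy,
    domain_seed_alignment,
    evolve_sequence,
    generate_clade,
    random_dna,
)


@pytest.fixture(scope="module")
def profiles():
    return {
        t: DomainProfile.from_seed_alignment(t, domain_seed_alignment(t))
        for t in ("KS", "C")
    }


class TestDetection:
    def test_exact_consensus_found_at_planted_position(self, profiles):
        rng = np.random.default_rng(0)
        member = domain_seed_alignment("KS", n_seeds=1, divergence=0.05)[0]
        contig = random_dna(3000, rng) + member + random_dna(3000, rng)
        hits = detect_domains("g", "c", contig, profiles)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.domain_type, h.strand) == (3000, 3450, "KS", "+")

    def test_reverse_complement_planting_found_on_minus_strand(self, profiles):
        rng = np.random.default_rng(1)
        member = domain_seed_alignment("C", n_seeds=1, divergence=0.05)[0]
        contig = random_dna(2000, rng) + reverse_complement(member) + random_dna(1000, rng)
        hits = detect_domains("g", "c", contig, profiles)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.domain_type, h.strand) == (2000, 2450, "C", "-")
        assert h.sequence == member  # stored in profile orientation

    def test_detected_set_equals_planted_features(self, profiles, bgc_clade):
        genomes, _ = bgc_clade
        g1 = genomes[0]
        planted = {
            (f.contig_id, f.start, f.end, f.attributes["domain_type"])
            for f in g1.features
            if f.kind == "BGC_domain"
        }
        detected = set()
        for contig_id, seq in g1.contigs:
            for h in detect_domains(g1.genome_id, contig_id, seq, profiles):
                detected.add((h.contig_id, h.start, h.end, h.domain_type))
        assert detected == planted  # precision = recall = 1


def test_hits_from_table_matches_annotation(bgc_clade):
    import pandas as pd

    genomes, _ = bgc_clade
    g1 = genomes[0]
    ann = hits_from_features(g1)
    df = pd.DataFrame(
        [
            {"genome": h.genome_id, "contig": h.contig_id, "start": h.start,
             "end": h.end, "strand": h.strand, "domain_type": h.domain_type}
            for h in ann
        ]
    )
    from taxobgc.bgc import hits_from_table

    got = hits_from_table(df, g1)
    assert [(h.contig_id, h.start, h.end, h.domain_type, h.sequence) for h in got] == [
        (h.contig_id, h.start, h.end, h.domain_type, h.sequence) for h in ann
    ]


class TestRegions:
    def _hit(self, start, dtype="KS", contig="c"):
        return DomainHit(f"{contig}:{start}:{dtype}", "g", contig, start,
                         start + 450, "+", dtype, 500.0, "A" * 450)

    def test_nearby_hits_chain_into_one_region(self):
        regions = call_regions(
            [self._hit(10_000), self._hit(15_000)], {"c": 100_000}
        )
        assert len(regions) == 1
        assert regions[0].category == "PKS"
        assert regions[0].completeness == "complete"

    def test_mixed_domains_make_hybrid(self):
        regions = call_regions(
            [self._hit(10_000, "KS"), self._hit(15_000, "C")], {"c": 100_000}
        )
        assert regions[0].category == "hybrid"

    def test_distant_hits_split_regions(self):
        regions = call_regions(
            [self._hit(10_000), self._hit(35_500)], {"c": 100_000}
        )
        assert len(regions) == 2

    @pytest.mark.parametrize(
        "start,end,clen,expected",
        [
            (5_000, 65_000, 100_000, "complete"),
            (0, 65_000, 100_000, "partial"),
            (5_000, 100_000, 100_000, "partial"),
        ],
    )
    def test_completeness_boundary_rule(self, start, end, clen, expected):
        assert classify_completeness(start, end, clen) == expected

    def test_category_rule(self):
        assert category_from_domains(["KS", "KS"]) == "PKS"
        assert category_from_domains(["C"]) == "NRPS"
        assert category_from_domains(["KS", "C"]) == "hybrid"


class TestDomainTree:
    def test_split_pair_forms_cherry_against_distant_third(self):
        consensus = domain_seed_alignment("KS", n_seeds=1, divergence=0.0)[0]
        near1, _ = evolve_sequence(consensus, 0.01, 1)
        near2, _ = evolve_sequence(consensus, 0.01, 2)
        far, _ = evolve_sequence(consensus, 0.3, 3)

        def hit(i, seq, contig):
            return DomainHit(f"d{i}", "g", contig, 0, len(seq), "+", "KS", 1.0, seq)

        hits = [hit(1, near1, "c1"), hit(2, near2, "c2"), hit(3, far, "c3")]
        pairs = bgc._sister_pairs(hits)
        assert pairs == {frozenset({"d1", "d2"})}

    def test_two_domains_declared_sisters(self):
        hits = [
            DomainHit("a", "g", "c1", 0, 9, "+", "KS", 1.0, "ACGTACGTA"),
            DomainHit("b", "g", "c2", 0, 9, "+", "KS", 1.0, "ACGTACGTA"),
        ]
        assert bgc._sister_pairs(hits) == {frozenset({"a", "b"})}
        assert domain_tree(hits) is None

    def test_tree_invariant_under_input_order(self):
        rng = np.random.default_rng(9)
        consensus = domain_seed_alignment("C", n_seeds=1, divergence=0.0)[0]
        hits = [
            DomainHit(f"d{i}", "g", f"c{i}", 0, 450, "+", "C", 1.0,
                      evolve_sequence(consensus, 0.05 * (i + 1), i)[0])
            for i in range(5)
        ]
        t1 = domain_tree(hits)
        t2 = domain_tree(list(reversed(hits)))
        from taxobgc.phylogeny import rf_distance

        assert rf_distance(t1, t2)[0] == 0


class TestMerging:
    def test_no_partial_regions_all_singletons(self, bgc_clade):
        genomes, _ = bgc_clade
        g2 = genomes[1]  # G02 carries no clusters
        regions = call_regions(hits_from_features(g2), g2.contig_lengths())
        assert regions == []
        assert merge_fragmented(regions) == []

    def test_two_way_split_merges_and_intact_stays(self, bgc_clade):
        genomes, truth = bgc_clade
        g1 = genomes[0]
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions, sister_mode="clade")
        # planted: split PKS, split NRPS, 3-way-split PKS, intact hybrid
        got = sorted((m.category, len(m.member_region_ids)) for m in merged)
        assert got == [("NRPS", 2), ("PKS", 2), ("PKS", 3), ("hybrid", 1)]
        n_true = sum(1 for c in truth.true_clusters.values() if c["genome"] == "G01")
        assert len(merged) == n_true

    def test_three_way_split_single_cluster_via_transitive_closure(self, bgc_clade):
        genomes, truth = bgc_clade
        g1 = genomes[0]
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions, sister_mode="clade")
        three = [m for m in merged if len(m.member_region_ids) == 3]
        assert len(three) == 1
        # the merged members are exactly the fragments of the planted
        # three-way-split cluster
        region_by_id = {r.region_id: r for r in regions}
        members = {region_by_id[r].contig_id for r in three[0].member_region_ids}
        assert len(members) == 3

    def test_merging_conserves_total_length(self, bgc_clade):
        genomes, _ = bgc_clade
        g1 = genomes[0]
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions, sister_mode="clade")
        assert sum(m.total_length for m in merged) == sum(r.length for r in regions)

    def test_cross_genome_regions_rejected(self):
        r1 = BGCRegion("r1", "g1", "c1", 0, 100, "PKS", "partial")
        r2 = BGCRegion("r2", "g2", "c2", 0, 100, "PKS", "partial")
        with pytest.raises(ValueError, match="one genome"):
            merge_fragmented([r1, r2])


class TestExpectedCount:
    def _region(self, i, length, completeness, category="PKS"):
        return BGCRegion(f"r{i}", "g", f"c{i}", 0 if completeness == "partial" else 10,
                         (0 if completeness == "partial" else 10) + length,
                         category, completeness)

    def test_single_complete_cluster_is_one(self):
        est = expected_cluster_count([self._region(1, 60_000, "complete")], "PKS")
        assert est.expected_count == pytest.approx(1.0)

    def test_arithmetic_with_partials(self):
        regions = [
            self._region(1, 60_000, "complete"),
            self._region(2, 30_000, "partial"),
            self._region(3, 28_000, "partial"),
        ]
        est = expected_cluster_count(regions, "PKS")
        assert est.expected_count == pytest.approx(118_000 / 60_000)
        assert est.expected_count_rounded == 2

    def test_no_complete_clusters_flagged_undefined(self):
        est = expected_cluster_count([self._region(1, 30_000, "partial")], "PKS")
        assert not est.defined
        assert est.expected_count_rounded is None

    def test_expected_count_at_least_n_complete(self):
        regions = [
            self._region(1, 50_000, "complete"),
            self._region(2, 70_000, "complete"),
            self._region(3, 20_000, "partial"),
        ]
        est = expected_cluster_count(regions, "PKS")
        assert est.expected_count >= est.n_complete


class TestCensusAndCorrelation:
    def test_census_counts_merged_clusters(self, bgc_clade):
        genomes, _ = bgc_clade
        g1 = genomes[0]
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions, sister_mode="clade")
        df, n_categories = bgc_census({"G01": merged, "G02": []})
        assert n_categories == 3  # PKS, NRPS, hybrid
        g01 = df[df.genome == "G01"]
        assert int(g01[g01.category == "PKS"].n_clusters.iloc[0]) == 2
        assert int(df[df.genome == "G02"].n_clusters.iloc[0]) == 0

    def test_perfectly_proportional_counts(self):
        counts = {"a": 2, "b": 4, "c": 6}
        sizes = {"a": 1_000, "b": 2_000, "c": 3_000}
        assert count_size_correlation(counts, sizes) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        assert count_size_correlation({"a": 3, "b": 3, "c": 3},
                                      {"a": 1, "b": 2, "c": 3}) is None

    def test_fixture_matches_definitional_formula(self):
        sizes = {"a": 4, "b": 5, "c": 6, "d": 4}
        counts = {"a": 6, "b": 6, "c": 12, "d": 9}
        x = np.array([4, 5, 6, 4], float)
        y = np.array([6, 6, 12, 9], float)
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert count_size_correlation(counts, sizes) == pytest.approx(r_hand)


class TestEnrichment:
    def _setup(self, genome, truth):
        membership = dict(truth.ortholog_membership)
        og_ids = sorted(set(membership.values()))
        groups = []
        for og in og_ids:
            genes = [g for g, o in membership.items() if o == og]
            by_genome = {}
            for gid in genes:
                by_genome.setdefault(gid.split("_")[0], []).append(gid)
            cls = truth.group_class[og]
            groups.append(
                OrthologGroup(og, by_genome, is_core=cls == "core",
                              is_singleton=cls == "singleton")
            )
        n_core = sum(1 for g in groups if g.is_core)
        n_single = sum(1 for g in groups if g.is_singleton)
        part = PanGenomePartition(
            n_core, len(groups) - n_core - n_single, n_single, membership
        )
        return part, groups

    def test_planted_fractions_recovered(self):
        # cluster interiors planted with known accessory and core coding
        # fractions; matching is by annotated coordinates
        tpl = BGCTemplate(
            category="PKS", n_domains=2, cluster_length=22_000,
            inter_domain_spacer=300,
            carrier_genomes=("G01", "G02"),
            n_filler_genes=10, filler_gene_length=900,
            n_core_genes_inside=2, core_inside_gene_length=900,
        )
        cfg = CladeConfig(
            n_genomes=3, tree_shape="((G01:0.01,G02:0.01):0.01,G03:0.02);",
            n_core_genes=20, n_dispensable_genes=0, n_singletons_per_genome=0,
            bgc_templates=(tpl,), seed=17,
        )
        genomes, truth = generate_clade(cfg)
        g1 = genomes[0]
        part, groups = self._setup(g1, truth)
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions)
        enr = core_accessory_span(g1, merged, regions, part, groups)
        # oracle from the planted layout: the region spans both domains and
        # the interior genes; accessory coding = 2 domains + 10 fillers
        assert len(regions) == 1
        region = regions[0]
        acc_planted = (2 * 450 + 10 * 900) / region.length
        core_planted = 2 * 900 / region.length
        assert enr.frac_accessory == pytest.approx(acc_planted, abs=0.02)
        assert enr.frac_core == pytest.approx(core_planted, abs=0.02)

    def test_all_singleton_cluster_has_zero_core(self, bgc_clade):
        genomes, truth = bgc_clade
        g1 = genomes[0]
        part, groups = self._setup(g1, truth)
        regions = call_regions(hits_from_features(g1), g1.contig_lengths())
        merged = merge_fragmented(regions, sister_mode="clade")
        enr = core_accessory_span(g1, merged, regions, part, groups)
        assert enr.frac_core == 0.0
        assert enr.frac_accessory > 0.0
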