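import pytest

from taxobgc.synthetic_data import (
    BGCTemplate,
    CladeConfig,
    FragmentationPolicy,
    generate_clade,
)


@pytest.fixture(scope="session")
def small_clade():
    """4 genomes, modest gene content, known tree — shared by several
    module test files (session-scoped: generated once)."""
    cfg = CladeConfig(
        n_genomes=4,
        tree_shape="((G01:0.01,G02:0.01):0.03,(G03:0.02,G04:0.02):0.02);",
        n_core_genes=40,
        n_dispensable_genes=15,
        dispensable_presence_prob=0.5,
        n_singletons_per_genome=3,
        seed=11,
    )
    return generate_clade(cfg)


@pytest.fixture(scope="session")
def small_clade_orthology(small_clade):
    """Proteomes, RBH graph, groups and partition for the small clade."""
    from taxobgc import orthology

    genomes, _ = small_clade
    proteomes = {
        g.genome_id: {f.feature_id: g.cds_protein(f)
                      for f in g.features_of_kind("CDS")}
        for g in genomes
    }
    rbh = orthology.all_pairs_rbh(proteomes)
    groups = orthology.build_ortholog_groups(
        rbh, {g: list(p) for g, p in proteomes.items()}
    )
    partition = orthology.partition_pangenome(groups)
    return proteomes, rbh, groups, partition


@pytest.fixture(scope="session")
def bgc_clade():
    """2 genomes where G01 carries one split PKS, one split NRPS, one
    three-way-split PKS and one intact hybrid cluster."""
    cfg = CladeConfig(
        n_genomes=2,
        tree_shape="(G01:0.05,G02:0.05);",
        n_core_genes=10,
        n_dispensable_genes=0,
        n_singletons_per_genome=0,
        bgc_templates=(
            BGCTemplate(
                category="PKS", n_domains=2, cluster_length=12_000,
                carrier_genomes=("G01",), split_in={"G01": "midpoint"},
            ),
            BGCTemplate(
                category="NRPS", n_domains=2, cluster_length=12_000,
                carrier_genomes=("G01",), split_in={"G01": "midpoint"},
            ),
            BGCTemplate(
                category="PKS", n_domains=3, cluster_length=15_000,
                carrier_genomes=("G01",), split_in={"G01": "all"},
            ),
            BGCTemplate(category="hybrid", n_domains=2, cluster_length=12_000,
                        carrier_genomes=("G01",)),
        ),
        fragmentation=FragmentationPolicy(breakpoints="at_planted_split_positions"),
        seed=42,
    )
    return generate_clade(cfg)
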