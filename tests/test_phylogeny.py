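"""Phylogenetics: JC correction, NJ against closed-form/brute-force and
scikit-bio oracles, bootstrap behavior, supermatrix concatenation, RF
distance against dendropy."""

import itertools

import numpy as np
import pytest

from taxobgc import phylogeny
from taxobgc.genome_io import newick_str, tree_from_newick
from taxobgc.phylogeny import (
    DistanceMatrix,
    SaturationError,
    bipartitions,
    bootstrap_support,
    concatenate_core,
    jc_distance,
    jc_matrix,
    nj_tree,
    rf_distance,
)


class TestJC:
    def test_zero_mismatch(self):
        assert jc_distance("ACGT", "ACGT") == 0.0

    def test_closed_form(self):
        # p = 0.3 -> d = -(3/4) ln(1 - 0.4) = 0.38312...
        a = "A" * 10
        b = "C" * 3 + "A" * 7
        assert jc_distance(a, b) == pytest.approx(-0.75 * np.log(0.6), abs=1e-10)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jc_distance("AAAA", "CCCC")

    def test_gap_columns_excluded(self):
        assert jc_distance("AC-T", "ACGT") == 0.0


def _star_least_squares(dm, topology):
    """Least-squares branch fit for a labeled 4-taxon unrooted topology
    ((a,b),(c,d)); returns the residual sum of squares (closed form via
    normal equations)."""
    a, b, c, d = topology
    labels = dm.labels
    i = {x: labels.index(x) for x in topology}
    D = dm.data
    # design: paths over branches (ea, eb, ec, ed, em)
    pairs = list(itertools.combinations(topology, 2))
    A, y = [], []
    for x, z in pairs:
        row = [0] * 5
        for k, t in enumerate(topology):
            if t in (x, z):
                row[k] = 1
        same_side = {x, z} in ({a, b}, {c, d})
        row[4] = 0 if same_side else 1
        A.append(row)
        y.append(D[i[x], i[z]])
    A, y = np.array(A, float), np.array(y, float)
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    return float(((pred - y) ** 2).sum())


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: d_a = (dab + dac - dbc)/2 etc.
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        ))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        # additive matrix for ((a:1,b:2):1,(c:3,d:4)): oracle = exhaustive
        # least-squares fit over the 3 unrooted topologies
        labels = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        dm = DistanceMatrix(labels, D)
        tree = nj_tree(dm)
        splits = bipartitions(tree)
        assert len(splits) == 1
        # brute-force oracle: the generating topology has zero residual
        topologies = [("a", "b", "c", "d"), ("a", "c", "b", "d"), ("a", "d", "b", "c")]
        residuals = {t: _star_least_squares(dm, t) for t in topologies}
        best = min(residuals, key=residuals.get)
        assert residuals[best] == pytest.approx(0.0, abs=1e-12)
        want = frozenset({best[2], best[3]})
        got = next(iter(splits))
        assert got in (want, frozenset({best[0], best[1]}))
        # branch lengths reproduce the generating values
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["d"] == pytest.approx(4.0)

    def test_matches_skbio_nj_topology(self):
        # independent implementation cross-check on a random metric
        rng = np.random.default_rng(5)
        import skbio

        n = 7
        labels = [f"t{i}" for i in range(n)]
        coords = rng.random((n, 4))
        D = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(labels, D)
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(dm.to_skbio())
        assert rf_distance(ours, theirs)[0] == 0

    def test_label_permutation_invariance(self, small_clade):
        genomes, _ = small_clade
        markers = {
            g.genome_id: g.feature_seq(g.features_of_kind("marker_rRNA")[0])
            for g in genomes
        }
        t1 = nj_tree(jc_matrix(markers))
        shuffled = dict(reversed(list(markers.items())))
        t2 = nj_tree(jc_matrix(shuffled))
        assert rf_distance(t1, t2)[0] == 0

    def test_clade_marker_tree_matches_truth(self, small_clade):
        genomes, truth = small_clade
        markers = {
            g.genome_id: g.feature_seq(g.features_of_kind("marker_rRNA")[0])
            for g in genomes
        }
        tree = nj_tree(jc_matrix(markers))
        assert rf_distance(tree, tree_from_newick(truth.true_topology))[0] == 0


class TestRF:
    def test_identical_trees(self):
        t = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, t) == (0, 0.0)

    def test_conflicting_four_taxon_trees(self):
        t1 = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = tree_from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert rf_distance(t1, t2) == (2, 1.0)

    def test_equals_dendropy_on_random_pairs(self):
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(6)
        labels = [f"t{i}" for i in range(8)]
        for rep in range(5):
            trees = []
            for _ in range(2):
                coords = rng.random((8, 3))
                D = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
                trees.append(nj_tree(DistanceMatrix(labels, D)))
            ours = rf_distance(trees[0], trees[1])[0]
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=newick_str(trees[0]), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=newick_str(trees[1]), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert ours == treecompare.symmetric_difference(d1, d2)

    def test_leaf_set_mismatch_rejected(self):
        t1 = tree_from_newick("((a:1,b:1):1,c:1);")
        t2 = tree_from_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestBootstrap:
    def test_identical_sequences_no_supported_bipartitions(self):
        aln = {f"t{i}": "ACGTACGTAC" * 5 for i in range(4)}
        st = bootstrap_support(aln, n_replicates=10, seed=0)
        assert st.supports == {}

    def test_structured_alignment_gets_high_central_support(self):
        # 150 diagnostic columns splitting {a,b} | {c,d} among 450 constant
        # ones: a binomial argument says nearly every resampling keeps >= 1
        # diagnostic column, so the central split survives
        aln = {}
        for name in ["a", "b", "c", "d"]:
            diag = ("A" if name in "ab" else "C") * 150
            aln[name] = diag + "G" * 450
        st = bootstrap_support(aln, n_replicates=200, seed=1)
        assert st.supports[frozenset({"c", "d"})] >= 99.0

    def test_single_replicate_support_is_binary_and_reproducible(self, small_clade):
        genomes, _ = small_clade
        markers = {
            g.genome_id: g.feature_seq(g.features_of_kind("marker_rRNA")[0])
            for g in genomes
        }
        a = bootstrap_support(markers, n_replicates=1, seed=3)
        b = bootstrap_support(markers, n_replicates=1, seed=3)
        assert a.supports == b.supports
        assert set(a.supports.values()) <= {0.0, 100.0}


class TestConcatenate:
    def test_blocks_in_stable_order_and_length_sums(self):
        blocks = {
            "og2": {"A": "MK", "B": "MR"},
            "og1": {"A": "VLL", "B": "VLI"},
        }
        matrix, parts = concatenate_core(blocks)
        assert matrix["A"] == "VLLMK"  # og1 before og2
        assert parts == [("og1", 0, 3), ("og2", 3, 5)]

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError, match="single-copy"):
            concatenate_core({"og1": {"A": "MK", "B": "MR"}, "og2": {"A": "VV"}})

    def test_unaligned_block_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            concatenate_core({"og1": {"A": "MK", "B": "MRR"}})
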