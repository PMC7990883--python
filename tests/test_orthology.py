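"""Orthology: alignment vs a textbook dynamic-programming oracle, RBH
prefilter equivalence with brute force, group construction, pan-genome
accounting, accumulation curves."""

import numpy as np
import pytest

from taxobgc import orthology
from taxobgc.orthology import (
    OrthologGroup,
    accumulation_curves,
    align_proteins_global,
    all_pairs_rbh,
    build_ortholog_groups,
    partition_pangenome,
    reciprocal_best_hits,
)


def nw_score_oracle(a, b, match=2.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    """Independent affine-gap Needleman-Wunsch (Gotoh) scoring oracle."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


class TestAlign:
    def test_identical_sequences(self):
        res = align_proteins_global("MKV", "MKV")
        assert res.identity == 1.0 and res.aligned_length == 3

    def test_single_substitution(self):
        res = align_proteins_global("MKV", "MRV")
        assert res.identity == pytest.approx(2 / 3)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = random_protein(rng, 60), random_protein(rng, 55)
        assert align_proteins_global(a, b).score == align_proteins_global(b, a).score

    def test_score_equals_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = random_protein(rng, 80)
            b = list(a)
            for pos in rng.integers(0, 80, size=10):
                b[pos] = "A"
            b = "".join(b)[:70]
            assert align_proteins_global(a, b).score == pytest.approx(
                nw_score_oracle(a, b)
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins_global("", "MKV")


def _mutate(rng, seq, n_subs):
    out = list(seq)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = alphabet[(alphabet.index(out[pos]) + 1) % 20]
    return "".join(out)


class TestRBH:
    def test_self_comparison_rejected(self):
        p = {"a": "MKVL"}
        with pytest.raises(ValueError, match="same genome"):
            reciprocal_best_hits(p, p)

    def test_planted_ortholog_recovered_among_decoys(self):
        rng = np.random.default_rng(2)
        planted = random_protein(rng, 100)
        a = {"target": planted}
        a.update({f"da{i}": random_protein(rng, 100) for i in range(30)})
        b = {"hit": _mutate(rng, planted, 5)}  # 95% identity
        b.update({f"db{i}": random_protein(rng, 100) for i in range(30)})
        assert ("target", "hit") in reciprocal_best_hits(a, b)

    def test_prefilter_equals_no_prefilter(self):
        # oracle equivalence: k-mer candidate restriction must not change
        # the result on fixtures of <= 50 genes per genome
        rng = np.random.default_rng(3)
        base = [random_protein(rng, 90) for _ in range(25)]
        a = {f"a{i}": s for i, s in enumerate(base)}
        b = {f"b{i}": _mutate(rng, s, 8) for i, s in enumerate(base)}
        b.update({f"x{i}": random_protein(rng, 90) for i in range(10)})
        with_filter = reciprocal_best_hits(a, b, kmer_prefilter=5)
        brute = reciprocal_best_hits(a, b, kmer_prefilter=None)
        assert with_filter == brute
        assert len(with_filter) == 25

    def test_duplicate_paralogs_tie_dropped(self):
        rng = np.random.default_rng(4)
        s = random_protein(rng, 80)
        a = {"p1": s, "p2": s}  # identical paralogs
        b = {"q": _mutate(rng, s, 4)}
        assert reciprocal_best_hits(a, b) == []


class TestGroups:
    def test_three_way_single_copy_core(self):
        rbh = {
            ("A", "B"): [("a1", "b1")],
            ("A", "C"): [("a1", "c1")],
            ("B", "C"): [("b1", "c1")],
        }
        groups = build_ortholog_groups(rbh, {"A": ["a1"], "B": ["b1"], "C": ["c1"]})
        assert len(groups) == 1
        assert groups[0].is_single_copy_core

    def test_chain_forms_one_group_by_transitive_closure(self):
        rbh = {("A", "B"): [("a1", "b1")], ("B", "C"): [("b1", "c1")]}
        groups = build_ortholog_groups(rbh, {"A": ["a1"], "B": ["b1"], "C": ["c1"]})
        assert len(groups) == 1 and groups[0].is_core

    def test_recovers_planted_groups_on_clade(self, small_clade):
        genomes, truth = small_clade
        proteomes = {
            g.genome_id: {f.feature_id: g.cds_protein(f)
                          for f in g.features_of_kind("CDS")}
            for g in genomes
        }
        rbh = all_pairs_rbh(proteomes)
        groups = build_ortholog_groups(rbh, {g: list(p) for g, p in proteomes.items()})
        recovered = {}
        for grp in groups:
            genes = frozenset(x for v in grp.members.values() for x in v)
            recovered[genes] = grp
        planted = {}
        for gene, og in truth.ortholog_membership.items():
            planted.setdefault(og, set()).add(gene)
        assert {frozenset(v) for v in planted.values()} == set(recovered)

    def test_gene_in_two_genomes_rejected(self):
        with pytest.raises(ValueError, match="more than one genome"):
            build_ortholog_groups({}, {"A": ["x"], "B": ["x"]})


class TestPartition:
    def test_identical_genomes_all_core(self):
        rbh = {}
        genomes = {f"G{k}": [f"G{k}_g{i}" for i in range(10)] for k in range(3)}
        for a in genomes:
            for b in genomes:
                if a < b:
                    rbh[(a, b)] = [(f"{a}_g{i}", f"{b}_g{i}") for i in range(10)]
        part = partition_pangenome(build_ortholog_groups(rbh, genomes))
        assert (part.n_core, part.n_singleton, part.n_pan) == (10, 0, 10)

    def test_partition_equals_truth_on_clade(self, small_clade):
        genomes, truth = small_clade
        proteomes = {
            g.genome_id: {f.feature_id: g.cds_protein(f)
                          for f in g.features_of_kind("CDS")}
            for g in genomes
        }
        rbh = all_pairs_rbh(proteomes)
        groups = build_ortholog_groups(rbh, {g: list(p) for g, p in proteomes.items()})
        part = partition_pangenome(groups)
        classes = list(truth.group_class.values())
        assert part.n_core == classes.count("core")
        assert part.n_dispensable == classes.count("dispensable")
        assert part.n_singleton == classes.count("singleton")
        assert part.n_pan == part.n_core + part.n_dispensable + part.n_singleton

    def test_published_accounting_relation(self):
        # the printed pan-genome structure obeys the partition identity
        assert 978 + 7489 + 3808 == 12275


def _toy_groups(n_genomes, n_core, n_singletons_per):
    groups = []
    genomes = [f"G{i}" for i in range(n_genomes)]
    for c in range(n_core):
        groups.append(
            OrthologGroup(f"core{c}", {g: [f"{g}_c{c}"] for g in genomes},
                          is_core=True, is_single_copy_core=True)
        )
    k = 0
    for g in genomes:
        for _ in range(n_singletons_per):
            groups.append(
                OrthologGroup(f"s{k}", {g: [f"{g}_s{k}"]}, is_singleton=True)
            )
            k += 1
    return groups, genomes


class TestAccumulation:
    def test_identical_genomes_flat_pan(self):
        groups, genomes = _toy_groups(5, 20, 0)
        curve = accumulation_curves(groups, genomes, n_permutations=10, seed=0)
        assert np.allclose(curve.mean_pan, 20)
        assert np.allclose(curve.mean_core, 20)

    def test_open_pan_strictly_increasing_and_matches_recount(self):
        groups, genomes = _toy_groups(6, 10, 4)
        curve = accumulation_curves(groups, genomes, n_permutations=20, seed=1)
        assert (np.diff(curve.mean_pan) > 0).all()
        # direct recount oracle: pan(n) = 10 core + 4n singletons;
        # core(1) includes the first genome's own 4 singletons
        assert np.allclose(curve.mean_pan, 10 + 4 * curve.n_values)
        assert np.allclose(curve.mean_core, [14, 10, 10, 10, 10, 10])

    def test_order_invariance_of_final_point(self, small_clade):
        genomes, _ = small_clade
        proteomes = {
            g.genome_id: {f.feature_id: g.cds_protein(f)
                          for f in g.features_of_kind("CDS")}
            for g in genomes
        }
        rbh = all_pairs_rbh(proteomes)
        groups = build_ortholog_groups(rbh, {g: list(p) for g, p in proteomes.items()})
        c1 = accumulation_curves(groups, sorted(proteomes), n_permutations=5, seed=2)
        c2 = accumulation_curves(groups, sorted(proteomes, reverse=True),
                                 n_permutations=5, seed=3)
        assert c1.mean_pan[-1] == c2.mean_pan[-1]
        assert c1.mean_core[-1] == c2.mean_core[-1]
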