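"""Ortholog detection and pan-genome structure.

All-vs-all global protein alignment (Needleman-Wunsch via Biopython's
PairwiseAligner) with an exact k-mer prefilter, reciprocal best hits (RBH),
ortholog groups as connected components of the RBH graph, core /
dispensable / singleton partitioning, and permutation-based gene
accumulation curves with least-squares fits (power law for the pan-genome,
exponential decay for the core-genome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import curve_fit

logger = logging.getLogger("taxobgc")


@dataclass
class AlignmentResult:
    identity: float  # over aligned columns (internal gaps counted, end gaps not)
    aligned_length: int
    score: float


@dataclass
class OrthologGroup:
    og_id: str
    members: dict[str, list[str]]  # genome id -> gene ids

    is_core: bool = False
    is_single_copy_core: bool = False
    is_singleton: bool = False

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class PanGenomePartition:
    n_core: int
    n_dispensable: int
    n_singleton: int
    membership: dict[str, str]  # gene id -> og_id

    @property
    def n_pan(self) -> int:
        return self.n_core + self.n_dispensable + self.n_singleton


@dataclass
class AccumulationCurve:
    n_values: np.ndarray
    mean_pan: np.ndarray
    mean_core: np.ndarray
    pan_fit: tuple[float, float, float]  # a, b, c in a*n^b + c
    core_fit: tuple[float, float, float]  # a, b, c in a*exp(-n/b) + c
    n_permutations: int
    seed: int


def _make_aligner(match: float = 2.0, mismatch: float = -1.0,
                  gap_open: float = -4.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def align_proteins_global(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Global alignment; identity over aligned columns excluding end gaps."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = aligner or _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = al.align(a, b)[0]
    counts = alignment.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    identity = counts.identities / cols if cols else 0.0
    return AlignmentResult(identity=identity, aligned_length=cols, score=alignment.score)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_hits(
    query: Mapping[str, str],
    target: Mapping[str, str],
    min_identity: float,
    min_coverage: float,
    k: int,
    aligner: Align.PairwiseAligner,
) -> dict[str, str]:
    """Unique best hit per query gene; score ties drop the query (logged).

    Candidates are ranked by alignment score (score-only mode, cheap); the
    identity/coverage thresholds are then checked on the best-scoring hit,
    which is dropped if it fails them.
    """
    index: dict[str, set[str]] = {}
    if k:
        for tid, tseq in target.items():
            for kmer in _kmer_set(tseq, k):
                index.setdefault(kmer, set()).add(tid)
    best: dict[str, str] = {}
    for qid, qseq in query.items():
        if k:
            cands: set[str] = set()
            for kmer in _kmer_set(qseq, k):
                cands |= index.get(kmer, set())
        else:
            cands = set(target)
        top_score, top_ids = None, []
        for tid in sorted(cands):
            score = aligner.score(qseq, target[tid])
            if top_score is None or score > top_score:
                top_score, top_ids = score, [tid]
            elif score == top_score:
                top_ids.append(tid)
        if len(top_ids) > 1:
            logger.debug("best-hit tie for %s (%s); dropped", qid, ",".join(top_ids))
            continue
        if not top_ids:
            continue
        tid = top_ids[0]
        res = align_proteins_global(qseq, target[tid], aligner=aligner)
        cov = res.aligned_length / min(len(qseq), len(target[tid]))
        if res.identity >= min_identity and cov >= min_coverage:
            best[qid] = tid
    return best


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    kmer_prefilter: int | None = 5,
    aligner: Align.PairwiseAligner | None = None,
) -> list[tuple[str, str]]:
    """Mutual unique best-scoring matches between two proteomes.

    ``kmer_prefilter=None`` (or 0) disables the exact-k-mer candidate
    restriction and scores every pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    if proteome_a is proteome_b or set(proteome_a) == set(proteome_b):
        raise ValueError("same genome: self comparison is excluded by contract")
    al = aligner or _make_aligner()
    k = kmer_prefilter or 0
    ab = _best_hits(proteome_a, proteome_b, min_identity, min_coverage, k, al)
    ba = _best_hits(proteome_b, proteome_a, min_identity, min_coverage, k, al)
    return sorted((qa, tb) for qa, tb in ab.items() if ba.get(tb) == qa)


def build_ortholog_groups(
    rbh_by_pair: Mapping[tuple[str, str], Sequence[tuple[str, str]]],
    genes_by_genome: Mapping[str, Iterable[str]],
) -> list[OrthologGroup]:
    """Connected components of the RBH graph; unmatched genes are singletons."""
    gene_genome: dict[str, str] = {}
    graph = nx.Graph()
    for genome, genes in genes_by_genome.items():
        for gid in genes:
            if gid in gene_genome:
                raise ValueError(f"gene id {gid} appears in more than one genome")
            gene_genome[gid] = genome
            graph.add_node(gid)
    for (ga, gb), pairs in rbh_by_pair.items():
        for a, b in pairs:
            graph.add_edge(a, b)
    n_genomes = len(genes_by_genome)
    groups: list[OrthologGroup] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for i, comp in enumerate(components):
        members: dict[str, list[str]] = {}
        for gid in sorted(comp):
            members.setdefault(gene_genome[gid], []).append(gid)
        total = sum(len(v) for v in members.values())
        is_core = len(members) == n_genomes
        groups.append(
            OrthologGroup(
                og_id=f"OG{i:06d}",
                members=members,
                is_core=is_core,
                is_single_copy_core=is_core and all(len(v) == 1 for v in members.values()),
                is_singleton=total == 1,
            )
        )
    return groups


def partition_pangenome(groups: Sequence[OrthologGroup]) -> PanGenomePartition:
    n_core = n_disp = n_single = 0
    membership: dict[str, str] = {}
    for g in groups:
        if g.is_singleton:
            n_single += 1
        elif g.is_core:
            n_core += 1
        else:
            n_disp += 1
        for genes in g.members.values():
            for gid in genes:
                if gid in membership:
                    raise ValueError(f"gene {gid} assigned to more than one group")
                membership[gid] = g.og_id
    return PanGenomePartition(n_core, n_disp, n_single, membership)


def _pan_core_counts(groups: Sequence[OrthologGroup], order: Sequence[str]) -> tuple[list[int], list[int]]:
    pan, core = [], []
    genome_sets = [set(g.members) for g in groups]
    for n in range(1, len(order) + 1):
        prefix = set(order[:n])
        pan.append(sum(1 for s in genome_sets if s & prefix))
        core.append(sum(1 for s in genome_sets if prefix <= s))
    return pan, core


def accumulation_curves(
    groups: Sequence[OrthologGroup],
    genomes: Sequence[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Mean pan/core cluster counts over random genome orderings, with
    least-squares fits y = a*n^b + c (pan) and y = a*exp(-n/b) + c (core)."""
    rng = np.random.default_rng(seed)
    genomes = list(genomes)
    pans, cores = [], []
    for _ in range(n_permutations):
        order = list(rng.permutation(genomes))
        pan, core = _pan_core_counts(groups, order)
        if any(np.diff(pan) < 0) or any(np.diff(core) > 0):
            raise AssertionError("accumulation monotonicity violated")
        pans.append(pan)
        cores.append(core)
    n_values = np.arange(1, len(genomes) + 1)
    mean_pan = np.asarray(pans, dtype=float).mean(axis=0)
    mean_core = np.asarray(cores, dtype=float).mean(axis=0)

    def power(n, a, b, c):
        return a * np.power(n, b) + c

    def expdecay(n, a, b, c):
        return a * np.exp(-n / b) + c

    try:
        pan_fit, _ = curve_fit(
            power, n_values, mean_pan, p0=(mean_pan[0], 0.5, 0.0), maxfev=20_000
        )
    except RuntimeError:
        pan_fit = (float("nan"),) * 3
    try:
        core_fit, _ = curve_fit(
            expdecay,
            n_values,
            mean_core,
            p0=(max(mean_core[0] - mean_core[-1], 1.0), 1.0, mean_core[-1]),
            maxfev=20_000,
        )
    except RuntimeError:
        core_fit = (float("nan"),) * 3
    return AccumulationCurve(
        n_values=n_values,
        mean_pan=mean_pan,
        mean_core=mean_core,
        pan_fit=tuple(float(x) for x in pan_fit),
        core_fit=tuple(float(x) for x in core_fit),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Convenience: full pan-genome analysis from per-genome proteomes

def all_pairs_rbh(
    proteomes: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    kmer_prefilter: int | None = 5,
) -> dict[tuple[str, str], list[tuple[str, str]]]:
    aligner = _make_aligner()
    names = sorted(proteomes)
    out: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = reciprocal_best_hits(
                proteomes[a],
                proteomes[b],
                min_identity=min_identity,
                min_coverage=min_coverage,
                kmer_prefilter=kmer_prefilter,
                aligner=aligner,
            )
    return out


def groups_table(groups: Sequence[OrthologGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for genome, genes in sorted(g.members.items()):
            for gid in genes:
                rows.append(
                    {
                        "og_id": g.og_id,
                        "genome": genome,
                        "gene": gid,
                        "is_core": g.is_core,
                        "is_single_copy_core": g.is_single_copy_core,
                        "is_singleton": g.is_singleton,
                    }
                )
    return pd.DataFrame(rows)
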