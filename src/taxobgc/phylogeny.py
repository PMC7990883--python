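"""Distance-based phylogenetics: Jukes-Cantor distances, neighbor-joining,
bootstrap supports, core-gene supermatrix concatenation and Robinson-Foulds
topology comparison.

The neighbor-joining implementation is deterministic: ties in the
Q-criterion are broken by the smallest label-index pair and negative branch
lengths are clamped to zero (the clamped deficit is logged).  An
independent NJ (scikit-bio) is used as a cross-check in the test-suite, and
a brute-force least-squares topology search serves as the oracle for small
additive matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import skbio

from .genome_io import newick_str, tree_from_newick

logger = logging.getLogger("taxobgc")

GAP_CHARS = set("-.")


class SaturationError(ValueError):
    """Jukes-Cantor correction undefined at mismatch fraction >= 0.75."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.data < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.data), 0):
            raise ValueError("diagonal must be zero")

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.labels)


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    total = mismatch = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        total += 1
        mismatch += x != y
    if total == 0:
        raise ValueError("no ungapped columns shared")
    return mismatch / total


def jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"mismatch fraction {p} >= 0.75: JC distance saturates")
    if p == 0:
        return 0.0
    return -0.75 * np.log(1 - 4 * p / 3)


def jc_distance(a: str, b: str) -> float:
    """JC69-corrected distance of an aligned pair (gapped columns excluded)."""
    return float(jc_correct(p_distance(a, b)))


def _p_matrix(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise mismatch fractions (gap columns excluded), vectorized."""
    labels = sorted(alignment)
    n = len(labels)
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    arr = np.vstack(
        [np.frombuffer(alignment[l].encode("ascii"), dtype=np.uint8) for l in labels]
    )
    gap = np.isin(arr, np.frombuffer("-.".encode(), dtype=np.uint8))
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError("no ungapped columns shared")
            p = float((arr[i, ok] != arr[j, ok]).sum() / total)
            mat[i, j] = mat[j, i] = p
    return labels, mat


def jc_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    labels, p = _p_matrix(alignment)
    if (p >= 0.75).any():
        raise SaturationError("a pair reaches mismatch fraction >= 0.75")
    d = np.where(p > 0, -0.75 * np.log(np.clip(1 - 4 * p / 3, 1e-12, None)), 0.0)
    return DistanceMatrix(labels, d)


def pdist_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected p-distance matrix (default for protein supermatrices)."""
    labels, p = _p_matrix(alignment)
    return DistanceMatrix(labels, p)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> skbio.TreeNode:
    """Classic neighbor joining; returns an unrooted-style tree (the final
    join leaves a bifurcating root whose placement carries no information)."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[skbio.TreeNode] = [skbio.TreeNode(name=l) for l in labels]
    d = dm.data.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties broken by smallest (i, j) index pair
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = d[ai, aj]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        for name, val in (("left", li), ("right", lj)):
            if val < 0:
                logger.debug("nj_tree: clamped negative branch length %.4g", val)
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length, child_j.length = float(li), float(lj)
        parent = skbio.TreeNode(children=[child_i, child_j])
        # distances from the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for k in active:
            if k in (ai, aj):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (ai, aj)] + [new_idx]

    ai, aj = active
    final = d[ai, aj]
    left, right = nodes[ai], nodes[aj]
    # split the remaining edge evenly; the root is arbitrary on this edge
    if left.length is None:
        left.length = 0.0
    if right.length is None:
        right.length = 0.0
    if left.is_tip() and right.is_tip():
        left.length = float(max(final, 0.0))
        right.length = 0.0
        return skbio.TreeNode(children=[left, right])
    # attach the last taxon onto the internal node with the full edge length
    if right.is_tip():
        left, right = right, left
    left.length = float(max(final, 0.0))
    right.append(left)
    right.length = None
    right.parent = None
    return right


# ---------------------------------------------------------------------------
# Bipartitions, Robinson-Foulds, bootstrap

def bipartitions(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the smaller/canonical tip-name side.

    An internal edge of length exactly zero is treated as an unresolved
    polytomy and contributes no bipartition (a star tree from identical
    sequences has none)."""
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)  # canonical side: the one NOT containing the reference tip
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        if node.length == 0.0:
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        canonical = tips - side if ref in side else side
        parts.add(canonical)
    return parts


def rf_distance(tree1: skbio.TreeNode, tree2: skbio.TreeNode) -> tuple[int, float]:
    """Symmetric-difference count of non-trivial bipartitions and the same
    normalized by 2(n-3)."""
    tips1 = {t.name for t in tree1.tips()}
    tips2 = {t.name for t in tree2.tips()}
    if tips1 != tips2:
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = bipartitions(tree1), bipartitions(tree2)
    rf = len(b1 ^ b2)
    n = len(tips1)
    norm = rf / (2 * (n - 3)) if n > 3 else 0.0
    return rf, norm


@dataclass
class SupportedTree:
    tree: skbio.TreeNode
    supports: dict[frozenset[str], float]  # bipartition -> support %

    def newick(self) -> str:
        annotated = self.tree.copy()
        tips = frozenset(t.name for t in annotated.tips())
        ref = min(tips)
        for node in annotated.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canonical = tips - side if ref in side else side
            if canonical in self.supports:
                node.name = f"{self.supports[canonical]:.0f}"
        return newick_str(annotated)


def bootstrap_support(
    alignment: Mapping[str, str],
    tree_builder: Callable[[Mapping[str, str]], skbio.TreeNode] | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
    distance: str = "jc",
) -> SupportedTree:
    """Column-resampling bootstrap; support = % of replicates containing each
    bipartition of the original tree.  Deterministic for a fixed seed."""
    if tree_builder is None:
        matrix_fn = jc_matrix if distance == "jc" else pdist_matrix
        tree_builder = lambda aln: nj_tree(matrix_fn(aln))  # noqa: E731
    names = sorted(alignment)
    length = len(alignment[names[0]])
    if any(len(alignment[n]) != length for n in names):
        raise ValueError("alignment rows must have equal length")
    original = tree_builder(alignment)
    target = bipartitions(original)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    arrs = {n: np.frombuffer(alignment[n].encode(), dtype=np.uint8) for n in names}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {n: arrs[n][cols].tobytes().decode() for n in names}
        try:
            rep = tree_builder(resampled)
        except (SaturationError, ValueError):
            continue
        rep_bps = bipartitions(rep)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    return SupportedTree(tree=original, supports=supports)


# ---------------------------------------------------------------------------
# Supermatrix

def concatenate_core(
    group_alignments: Mapping[str, Mapping[str, str]],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-gene blocks in stable group-id order.

    ``group_alignments`` maps og_id -> {genome -> aligned sequence}; every
    block must contain exactly the same genome set (single-copy core) and
    equal-length rows.  Returns the supermatrix rows and a partition map of
    (og_id, start, end) column spans.
    """
    og_ids = sorted(group_alignments)
    if not og_ids:
        raise ValueError("no groups to concatenate")
    genomes = sorted(group_alignments[og_ids[0]])
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    partition: list[tuple[str, int, int]] = []
    pos = 0
    for og in og_ids:
        block = group_alignments[og]
        if sorted(block) != genomes:
            raise ValueError(f"group {og} is not single-copy across all genomes")
        lengths = {len(s) for s in block.values()}
        if len(lengths) != 1:
            raise ValueError(f"group {og}: member sequences not aligned to equal length")
        (bl,) = lengths
        for g in genomes:
            parts[g].append(block[g])
        partition.append((og, pos, pos + bl))
        pos += bl
    return {g: "".join(p) for g, p in parts.items()}, partition
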