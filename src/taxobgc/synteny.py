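"""Anchor-based synteny between genome pairs.

Exact k-mer seeds are extended ungapped with an x-drop rule on each
diagonal, filtered by the display thresholds used throughout the field's
synteny figures (>= 500 bp and >= 90% identity by default), chained into
locally collinear blocks (monotone on both genomes, bounded gaps) and
summarized as per-genome coverage and length-weighted identity.  An
approximate e-value per anchor is reported for information only; filtering
is by the deterministic length/identity pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, reverse_complement

DEFAULT_SEED_K = 15
DEFAULT_MIN_LENGTH = 500
DEFAULT_MIN_IDENTITY = 90.0
XDROP = 50.0
MATCH_SCORE = 1.0
MISMATCH_SCORE = -3.0


@dataclass
class SyntenyAnchor:
    contig_a: str
    contig_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    strand: str  # same | inverted
    length: int
    identity: float  # %

    @property
    def evalue(self) -> float:
        """Karlin-Altschul-style rough e-value (informational only)."""
        bits = self.length * (self.identity / 100.0 * 2 - (1 - self.identity / 100.0) * 3)
        return self.length * 2 ** (-max(bits, 0.0))


@dataclass
class SyntenyBlock:
    anchors: list[SyntenyAnchor]
    contig_a: str
    contig_b: str
    strand: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    mean_identity: float  # length-weighted %

    @property
    def total_anchor_length(self) -> int:
        return sum(a.length for a in self.anchors)


@dataclass
class SyntenySummary:
    genome_pair: tuple[str, str]
    coverage_a: float
    coverage_b: float
    weighted_mean_identity: float | None
    n_blocks: int


def _seed_diagonals(seq_a: str, seq_b: str, k: int) -> dict[int, set[int]]:
    """diagonal (posA - posB) -> set of seed positions on A."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(seq_b) - k + 1):
        index.setdefault(seq_b[i : i + k], []).append(i)
    diags: dict[int, set[int]] = {}
    for i in range(0, len(seq_a) - k + 1):
        for j in index.get(seq_a[i : i + k], ()):
            diags.setdefault(i - j, set()).add(i)
    return diags


def _xdrop_end(score: np.ndarray, seed: int, direction: int) -> int:
    """Farthest best-scoring position of an ungapped x-drop walk (vectorized:
    cumulative score with a running-maximum drop test)."""
    if direction > 0:
        arr = score[seed + 1 :]
    else:
        arr = score[:seed][::-1]
    if arr.size == 0:
        return seed
    cs = np.cumsum(arr)
    cm = np.maximum.accumulate(cs)
    viol = (cm - cs) > XDROP
    t = int(np.argmax(viol)) if viol.any() else arr.size - 1
    prefix = cs[: t + 1]
    if prefix.max() <= 0:
        return seed
    off = int(np.argmax(prefix))
    return seed + 1 + off if direction > 0 else seed - 1 - off


def _extend_on_diagonal(
    score: np.ndarray, match: np.ndarray, seed: int, min_identity: float
) -> tuple[int, int, bool]:
    """Extend from a seed; returns (start, end, passed_identity_filter)."""
    lo = _xdrop_end(score, seed, -1)
    hi = _xdrop_end(score, seed, +1)
    seg = match[lo : hi + 1]
    ident = 100.0 * seg.mean()
    return lo, hi + 1, bool(ident >= min_identity)


def find_anchors(
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    seed_k: int = DEFAULT_SEED_K,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[SyntenyAnchor]:
    anchors: list[SyntenyAnchor] = []
    for ca, seq_a in genome_a.contigs:
        for cb, seq_b_fwd in genome_b.contigs:
            for strand, seq_b in (("same", seq_b_fwd), ("inverted", reverse_complement(seq_b_fwd))):
                diags = _seed_diagonals(seq_a, seq_b, seed_k)
                found: set[tuple[int, int]] = set()
                cand: list[tuple[int, int]] = []
                for diag, seeds in sorted(diags.items()):
                    lo_a = max(0, diag)
                    hi_a = min(len(seq_a), len(seq_b) + diag)
                    if hi_a - lo_a < min_length:
                        continue
                    sub_a = np.frombuffer(
                        seq_a[lo_a:hi_a].encode(), dtype=np.uint8
                    )
                    sub_b = np.frombuffer(
                        seq_b[lo_a - diag : hi_a - diag].encode(), dtype=np.uint8
                    )
                    match = sub_a == sub_b
                    score = np.where(match, MATCH_SCORE, MISMATCH_SCORE)
                    for seed in sorted(seeds):
                        rel = seed - lo_a
                        if any(s <= rel < e for s, e in found):
                            continue
                        s, e, passed = _extend_on_diagonal(score, match, rel, min_identity)
                        found.add((s, e))  # cache rejected spans too
                        if not passed or e - s < min_length:
                            continue
                        a0, a1 = lo_a + s, lo_a + e
                        b0, b1 = a0 - diag, a1 - diag
                        if strand == "inverted":
                            b0, b1 = len(seq_b_fwd) - b1, len(seq_b_fwd) - b0
                        cand.append(
                            (
                                a1 - a0,
                                SyntenyAnchor(
                                    ca, cb, a0, a1, b0, b1, strand,
                                    a1 - a0, 100.0 * float(match[s:e].mean()),
                                ),
                            )
                        )
                    found.clear()
                # overlapping anchors on A: keep the longer
                kept: list[SyntenyAnchor] = []
                for _, anchor in sorted(cand, key=lambda t: (-t[0], t[1].start_a)):
                    if all(
                        anchor.end_a <= k2.start_a or anchor.start_a >= k2.end_a
                        for k2 in kept
                    ):
                        kept.append(anchor)
                anchors.extend(kept)
    return sorted(anchors, key=lambda a: (a.contig_a, a.contig_b, a.strand, a.start_a))


def chain_blocks(
    anchors: Sequence[SyntenyAnchor], max_gap: int = 25_000
) -> list[SyntenyBlock]:
    """Longest chains (by total anchor length, dynamic programming) of
    anchors monotone on both genomes with gaps <= max_gap, per contig pair
    and strand relation."""
    blocks: list[SyntenyBlock] = []
    groups: dict[tuple[str, str, str], list[SyntenyAnchor]] = {}
    for a in anchors:
        groups.setdefault((a.contig_a, a.contig_b, a.strand), []).append(a)
    for (ca, cb, strand), group in sorted(groups.items()):
        remaining = sorted(group, key=lambda a: a.start_a)
        while remaining:
            n = len(remaining)
            best_len = [a.length for a in remaining]
            prev = [-1] * n
            for i in range(n):
                for j in range(i):
                    aj, ai = remaining[j], remaining[i]
                    if aj.end_a > ai.start_a or ai.start_a - aj.end_a > max_gap:
                        continue
                    if strand == "same":
                        ok = aj.end_b <= ai.start_b and ai.start_b - aj.end_b <= max_gap
                    else:
                        ok = ai.end_b <= aj.start_b and aj.start_b - ai.end_b <= max_gap
                    if ok and best_len[j] + ai.length > best_len[i]:
                        best_len[i] = best_len[j] + ai.length
                        prev[i] = j
            end = int(np.argmax(best_len))
            chain_idx = []
            while end != -1:
                chain_idx.append(end)
                end = prev[end]
            chain_idx.reverse()
            chain = [remaining[i] for i in chain_idx]
            used = set(chain_idx)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
            for piece in _split_at_foreign_anchors(chain, anchors, strand):
                total = sum(a.length for a in piece)
                blocks.append(
                    SyntenyBlock(
                        anchors=piece,
                        contig_a=ca,
                        contig_b=cb,
                        strand=strand,
                        span_a=(min(a.start_a for a in piece),
                                max(a.end_a for a in piece)),
                        span_b=(min(a.start_b for a in piece),
                                max(a.end_b for a in piece)),
                        mean_identity=sum(a.length * a.identity for a in piece) / total,
                    )
                )
    return blocks


def _split_at_foreign_anchors(
    chain: list[SyntenyAnchor],
    all_anchors: Sequence[SyntenyAnchor],
    strand: str,
) -> list[list[SyntenyAnchor]]:
    """Break a chain wherever the gap between consecutive anchors contains
    another anchor (e.g. an inverted segment sits between two collinear
    runs: the runs are separate blocks, not one block spanning it)."""
    chain_set = {id(a) for a in chain}
    others = [a for a in all_anchors if id(a) not in chain_set]
    pieces: list[list[SyntenyAnchor]] = [[chain[0]]]
    for prev_a, next_a in zip(chain, chain[1:]):
        gap_a = (prev_a.end_a, next_a.start_a)
        if strand == "same":
            gap_b = (prev_a.end_b, next_a.start_b)
        else:
            gap_b = (next_a.end_b, prev_a.start_b)
        foreign = any(
            (x.start_a < gap_a[1] and x.end_a > gap_a[0])
            or (x.start_b < gap_b[1] and x.end_b > gap_b[0])
            for x in others
        )
        if foreign:
            pieces.append([])
        pieces[-1].append(next_a)
    return pieces


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def synteny_summary(
    blocks: Sequence[SyntenyBlock],
    genome_pair: tuple[str, str],
    length_a: int,
    length_b: int,
) -> SyntenySummary:
    if not blocks:
        return SyntenySummary(genome_pair, 0.0, 0.0, None, 0)
    cov_a = _union_length([b.span_a for b in blocks]) / length_a
    cov_b = _union_length([b.span_b for b in blocks]) / length_b
    anchors = [a for b in blocks for a in b.anchors]
    total = sum(a.length for a in anchors)
    ident = sum(a.length * a.identity for a in anchors) / total
    return SyntenySummary(genome_pair, min(cov_a, 1.0), min(cov_b, 1.0), ident, len(blocks))


def anchors_table(anchors: Sequence[SyntenyAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_a": a.contig_a,
                "contig_b": a.contig_b,
                "start_a": a.start_a,
                "end_a": a.end_a,
                "start_b": a.start_b,
                "end_b": a.end_b,
                "strand": a.strand,
                "length": a.length,
                "identity": a.identity,
                "approx_evalue": a.evalue,
            }
            for a in anchors
        ]
    )
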