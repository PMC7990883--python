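"""Biosynthetic gene cluster post-processing.

The stages mirror how draft-genome BGC surveys are curated by hand:

1. detect KS (ketosynthase, PKS-derived) and C (condensation,
   NRPS-derived) domains by log-odds scoring against position weight
   matrices built from seed alignments, on both strands;
2. chain nearby domain hits into candidate cluster regions and classify
   each region *complete* (sequence exists before and after it on its
   contig) or *partial* (it touches a contig end);
3. build neighbor-joining trees of the domain sequences per domain type
   and merge partial regions on different contigs whose domains are sister
   leaves (a cherry) — fragments of one cluster clade together because the
   domains carry the cluster's phylogenetic signature;
4. estimate the expected cluster count per category as
   (sum of all cluster lengths) / (mean complete-cluster length);
5. census merged clusters, measure how much of each cluster is spanned by
   core vs accessory genes, and correlate counts with genome size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import phylogeny
from .genome_io import GeneFeature, GenomeAssembly, reverse_complement
from .orthology import OrthologGroup, PanGenomePartition

logger = logging.getLogger("taxobgc")

DEFAULT_MAX_GAP = 20_000
DEFAULT_FLANK = 5_000
DEFAULT_SCORE_THRESHOLD = 100.0  # bits
#: a clade-mode merge group must be this much tighter than its surroundings
CLADE_SEPARATION_MARGIN = 0.5

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# Domain detection

@dataclass
class DomainProfile:
    """Log-odds position weight matrix for one domain type."""

    domain_type: str
    log_odds: np.ndarray  # (width, 4) in bits

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_seed_alignment(
        cls,
        domain_type: str,
        seeds: Sequence[str],
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 1.0,
    ) -> "DomainProfile":
        width = len(seeds[0])
        if any(len(s) != width for s in seeds):
            raise ValueError("seed alignment rows must have equal length")
        counts = np.full((width, 4), pseudocount)
        for s in seeds:
            for j, ch in enumerate(s):
                counts[j, _BASE_IDX[ch]] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        lo = np.log2(probs / np.asarray(background))
        return cls(domain_type=domain_type, log_odds=lo)


@dataclass
class DomainHit:
    hit_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    domain_type: str
    score: float
    sequence: str  # in profile orientation


def _scan_scores(seq: str, profile: DomainProfile) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for b, i in _BASE_IDX.items():
        idx[arr == ord(b)] = i
    idx[idx < 0] = 0  # ambiguous bases scored as A; negligible for our data
    w = profile.width
    n = len(seq) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(w):
        scores += profile.log_odds[j, idx[j : j + n]]
    return scores


def detect_domains(
    genome_id: str,
    contig_id: str,
    contig_seq: str,
    profiles: Mapping[str, DomainProfile],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[DomainHit]:
    """Scan both strands; overlapping hits of one type keep the best score."""
    hits: list[DomainHit] = []
    length = len(contig_seq)
    for dtype, profile in sorted(profiles.items()):
        if profile.width > length:
            continue
        candidates: list[tuple[float, int, str]] = []
        for strand, seq in (("+", contig_seq), ("-", reverse_complement(contig_seq))):
            scores = _scan_scores(seq, profile)
            for pos in np.nonzero(scores >= threshold)[0]:
                candidates.append((float(scores[pos]), int(pos), strand))
        chosen: list[tuple[int, int]] = []
        for score, pos, strand in sorted(candidates, key=lambda t: (-t[0], t[1])):
            if strand == "+":
                start, end = pos, pos + profile.width
            else:
                start, end = length - pos - profile.width, length - pos
            if any(start < e and s < end for s, e in chosen):
                continue
            chosen.append((start, end))
            segment = contig_seq[start:end]
            hits.append(
                DomainHit(
                    hit_id=f"{contig_id}:{start}-{end}:{dtype}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    domain_type=dtype,
                    score=score,
                    sequence=reverse_complement(segment) if strand == "-" else segment,
                )
            )
    return sorted(hits, key=lambda h: (h.contig_id, h.start))


def hits_from_features(genome: GenomeAssembly) -> list[DomainHit]:
    """Domain hits taken directly from BGC_domain annotation (user-supplied
    or generated), bypassing profile scanning."""
    hits = []
    for f in genome.features:
        if f.kind != "BGC_domain":
            continue
        hits.append(
            DomainHit(
                hit_id=f.feature_id,
                genome_id=genome.genome_id,
                contig_id=f.contig_id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                domain_type=f.attributes.get("domain_type", "KS"),
                score=float("inf"),
                sequence=genome.feature_seq(f),
            )
        )
    return sorted(hits, key=lambda h: (h.contig_id, h.start))


def hits_from_table(df: pd.DataFrame, genome: GenomeAssembly) -> list[DomainHit]:
    """Domain hits from a user-supplied table with columns genome, contig,
    start, end, strand, domain_type and optionally score (e.g. an exported
    domain-scan result); sequences are extracted from the assembly."""
    hits = []
    for row in df.itertuples():
        if row.genome != genome.genome_id:
            continue
        feature = GeneFeature(
            feature_id=f"{row.contig}:{row.start}-{row.end}:{row.domain_type}",
            contig_id=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            kind="BGC_domain",
            attributes={"domain_type": row.domain_type},
        )
        hits.append(
            DomainHit(
                hit_id=feature.feature_id,
                genome_id=genome.genome_id,
                contig_id=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                domain_type=row.domain_type,
                score=float(getattr(row, "score", float("inf"))),
                sequence=genome.feature_seq(feature),
            )
        )
    return sorted(hits, key=lambda h: (h.contig_id, h.start))


# ---------------------------------------------------------------------------
# Region calling

@dataclass
class BGCRegion:
    region_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    category: str  # PKS | NRPS | hybrid
    completeness: str  # complete | partial
    domains: list[DomainHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def category_from_domains(domain_types: Sequence[str]) -> str:
    kinds = set(domain_types)
    if kinds == {"KS"}:
        return "PKS"
    if kinds == {"C"}:
        return "NRPS"
    return "hybrid"


def classify_completeness(
    start: int, end: int, contig_length: int, tolerance: int = 0
) -> str:
    """Complete iff sequence exists strictly before and after the region."""
    if start > tolerance and end < contig_length - tolerance:
        return "complete"
    return "partial"


def call_regions(
    hits: Sequence[DomainHit],
    contig_lengths: Mapping[str, int],
    max_gap: int = DEFAULT_MAX_GAP,
    flank: int = DEFAULT_FLANK,
    boundary_tolerance: int = 0,
) -> list[BGCRegion]:
    """Chain same-contig hits within max_gap; region = hull of its hits
    +/- flank, clipped to the contig."""
    regions: list[BGCRegion] = []
    by_contig: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    counter = itertools.count(1)
    for contig, contig_hits in sorted(by_contig.items()):
        contig_hits = sorted(contig_hits, key=lambda h: h.start)
        chains: list[list[DomainHit]] = [[contig_hits[0]]]
        for h in contig_hits[1:]:
            if h.start - chains[-1][-1].end <= max_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        clen = contig_lengths[contig]
        for chain in chains:
            start = max(0, min(h.start for h in chain) - flank)
            end = min(clen, max(h.end for h in chain) + flank)
            genome = chain[0].genome_id
            regions.append(
                BGCRegion(
                    region_id=f"{genome}_region{next(counter):03d}",
                    genome_id=genome,
                    contig_id=contig,
                    start=start,
                    end=end,
                    category=category_from_domains([h.domain_type for h in chain]),
                    completeness=classify_completeness(start, end, clen, boundary_tolerance),
                    domains=list(chain),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# Domain trees and sister-pair merging

def domain_distances(domains: Sequence[DomainHit]) -> phylogeny.DistanceMatrix:
    """JC-corrected pairwise distances of domain sequences.

    Equal-length (indel-free) domain sets are compared positionally;
    otherwise each pair is globally aligned first (edlib)."""
    seqs = {d.hit_id: d.sequence for d in domains}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return phylogeny.jc_matrix(seqs)
    ids_sorted = sorted(seqs)
    n = len(ids_sorted)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = edlib.align(
                seqs[ids_sorted[i]], seqs[ids_sorted[j]], task="path", mode="NW"
            )
            alen = matches = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                else:
                    alen += int(num)
                    if ch == "=":
                        matches += int(num)
                    num = ""
            p = 1 - matches / alen
            d = phylogeny.jc_correct(min(p, 0.7499))
            mat[i, j] = mat[j, i] = d
    return phylogeny.DistanceMatrix(ids_sorted, mat)


def domain_tree(domains: Sequence[DomainHit]):
    """NJ tree over domain ids; two domains are declared sisters without a
    tree, one domain yields no tree."""
    if len(domains) < 3:
        return None
    return phylogeny.nj_tree(domain_distances(domains))


def _sister_pairs(domains: Sequence[DomainHit]) -> set[frozenset[str]]:
    """Hit-id pairs that are cherries (strict two-leaf clades) in the
    type's domain tree.

    Two domains alone are sisters by definition; for exactly three the
    unrooted tree is a star, so the distance-closest pair is the cherry.
    """
    if len(domains) == 1:
        return set()
    if len(domains) == 2:
        return {frozenset(d.hit_id for d in domains)}
    if len(domains) == 3:
        dm = domain_distances(domains)
        best = None
        for i in range(3):
            for j in range(i + 1, 3):
                if best is None or dm.data[i, j] < best[0]:
                    best = (dm.data[i, j], i, j)
        return {frozenset((dm.labels[best[1]], dm.labels[best[2]]))}
    tree = domain_tree(domains)
    pairs: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=True):
        kids = node.children
        if len(kids) == 2 and all(k.is_tip() for k in kids):
            pairs.add(frozenset(k.name for k in kids))
    return pairs


def _clade_groups(
    domains: Sequence[DomainHit],
    region_of_hit: Mapping[str, str],
    region_by_id: Mapping[str, "BGCRegion"],
) -> list[list[str]]:
    """Groups of region ids whose domains clade together exclusively.

    A minimal clade is accepted when its tips are exactly the domains (of
    this type) of >= 2 regions that are all partial and lie on pairwise
    distinct contigs — the looser reading of the sister-taxa rule needed
    when a cluster is split so that some fragment keeps a single domain
    (a three-leaf tree has only one cherry).  Ancestors of an accepted
    clade are skipped so two separate clusters are never co-merged.
    """
    hits_of_region: dict[str, set[str]] = {}
    for d in domains:
        hits_of_region.setdefault(region_of_hit[d.hit_id], set()).add(d.hit_id)

    def acceptable(tips: frozenset[str]) -> list[str] | None:
        regions = {region_of_hit[t] for t in tips}
        if len(regions) < 2:
            return None
        if set().union(*(hits_of_region[r] for r in regions)) != tips:
            return None  # some region's domains straddle the clade boundary
        regs = [region_by_id[r] for r in regions]
        if any(r.completeness == "complete" for r in regs):
            return None
        contigs = [r.contig_id for r in regs]
        if len(set(contigs)) != len(contigs):
            return None
        return sorted(regions)

    if len(domains) < 3:
        if len(domains) == 2:
            group = acceptable(frozenset(d.hit_id for d in domains))
            return [group] if group else []
        return []
    dm = domain_distances(domains)
    idx = {label: i for i, label in enumerate(dm.labels)}
    tree = phylogeny.nj_tree(dm)
    all_tips = frozenset(d.hit_id for d in domains)

    def well_separated(side: frozenset[str]) -> bool:
        """Max within-side distance below half the min side-to-rest
        distance — the regime the merging heuristic assumes (fragments of
        one cluster are near-identical relative to other clusters)."""
        inside = [idx[t] for t in side]
        outside = [idx[t] for t in all_tips - side]
        intra = max(dm.data[i, j] for i in inside for j in inside)
        sep = min(dm.data[i, j] for i in inside for j in outside)
        return intra < CLADE_SEPARATION_MARGIN * sep

    # unrooted clades: both sides of every edge (NJ roots arbitrarily)
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = (
            frozenset(t.name for t in node.tips())
            if not node.is_tip()
            else frozenset([node.name])
        )
        sides.add(side)
        sides.add(all_tips - side)
    groups: list[list[str]] = []
    used_regions: set[str] = set()
    for side in sorted(sides, key=lambda s: (-len(s), sorted(s))):
        if len(side) < 2 or side == all_tips:
            continue
        group = acceptable(side)
        if group is None or not well_separated(side):
            continue
        if any(r in used_regions for r in group):
            continue
        used_regions.update(group)
        groups.append(group)
    return groups


@dataclass
class MergedCluster:
    cluster_id: str
    genome_id: str
    category: str
    member_region_ids: list[str]
    total_length: int
    merge_evidence: list[tuple[str, str]] = field(default_factory=list)


def merge_fragmented(
    regions: Sequence[BGCRegion],
    sister_mode: str = "cherry",
) -> list[MergedCluster]:
    """Merge partial regions of one genome lying on different contigs whose
    domains are sister taxa in the per-type domain trees; merging is
    transitively closed.  Complete regions always stay singleton clusters;
    a sister link between a complete and a partial region is logged as an
    anomaly and ignored.
    """
    genomes = {r.genome_id for r in regions}
    if len(genomes) > 1:
        raise ValueError("merge_fragmented operates on regions of one genome")
    by_type: dict[str, list[DomainHit]] = {}
    for r in regions:
        for d in r.domains:
            by_type.setdefault(d.domain_type, []).append(d)
    region_of_hit = {d.hit_id: r.region_id for r in regions for d in r.domains}
    region_by_id = {r.region_id: r for r in regions}

    if sister_mode not in ("cherry", "clade"):
        raise ValueError(f"unknown sister mode {sister_mode!r}")
    graph = nx.Graph()
    graph.add_nodes_from(region_by_id)
    evidence: dict[frozenset[str], list[tuple[str, str]]] = {}
    for dtype, hits in sorted(by_type.items()):
        # cherry pairs apply in both modes; 'clade' additionally accepts
        # exclusive multi-region clades (needed when a fragment keeps a
        # single domain and the tree has no cross-contig cherry)
        for pair in _sister_pairs(hits):
            ha, hb = sorted(pair)
            ra, rb = region_of_hit[ha], region_of_hit[hb]
            if ra == rb:
                continue
            rega, regb = region_by_id[ra], region_by_id[rb]
            if rega.contig_id == regb.contig_id:
                continue
            if rega.completeness == "complete" or regb.completeness == "complete":
                logger.info(
                    "merge anomaly: sister domains %s/%s link a complete region; "
                    "not merged",
                    ha, hb,
                )
                continue
            graph.add_edge(ra, rb)
            evidence.setdefault(frozenset((ra, rb)), []).append((ha, hb))
        if sister_mode == "clade":
            hits_of_region: dict[str, list[str]] = {}
            for d in hits:
                hits_of_region.setdefault(region_of_hit[d.hit_id], []).append(d.hit_id)
            for group in _clade_groups(hits, region_of_hit, region_by_id):
                for ra, rb in itertools.combinations(group, 2):
                    graph.add_edge(ra, rb)
                    evidence.setdefault(frozenset((ra, rb)), []).append(
                        (min(hits_of_region[ra]), min(hits_of_region[rb]))
                    )

    clusters: list[MergedCluster] = []
    comps = sorted(nx.connected_components(graph), key=min)
    for i, comp in enumerate(comps, start=1):
        members = sorted(comp)
        regs = [region_by_id[m] for m in members]
        dtypes = [d.domain_type for r in regs for d in r.domains]
        ev = [
            e
            for key, pairs in evidence.items()
            if key <= set(members)
            for e in pairs
        ]
        clusters.append(
            MergedCluster(
                cluster_id=f"{regs[0].genome_id}_cluster{i:03d}",
                genome_id=regs[0].genome_id,
                category=category_from_domains(dtypes),
                member_region_ids=members,
                total_length=sum(r.length for r in regs),
                merge_evidence=sorted(ev),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Expected counts, census, enrichment, correlation

@dataclass
class ClusterCountEstimate:
    genome_id: str
    category: str
    n_regions: int
    n_complete: int
    n_merged: int
    expected_count: float | None

    @property
    def expected_count_rounded(self) -> int | None:
        return None if self.expected_count is None else round(self.expected_count)

    @property
    def defined(self) -> bool:
        return self.expected_count is not None


def expected_cluster_count(
    regions: Sequence[BGCRegion],
    category: str,
    merged: Sequence[MergedCluster] | None = None,
) -> ClusterCountEstimate:
    """Sum of all (partial and complete) region lengths in the category
    divided by the mean complete-region length; undefined (flagged) when
    the category has no complete region."""
    cat_regions = [r for r in regions if r.category == category]
    genome = cat_regions[0].genome_id if cat_regions else "NA"
    complete = [r for r in cat_regions if r.completeness == "complete"]
    n_merged = (
        sum(1 for m in merged if m.category == category) if merged is not None else 0
    )
    if not complete:
        return ClusterCountEstimate(
            genome, category, len(cat_regions), 0, n_merged, None
        )
    mean_complete = float(np.mean([r.length for r in complete]))
    total = float(sum(r.length for r in cat_regions))
    return ClusterCountEstimate(
        genome,
        category,
        len(cat_regions),
        len(complete),
        n_merged,
        total / mean_complete,
    )


def bgc_census(
    merged_by_genome: Mapping[str, Sequence[MergedCluster]]
) -> tuple[pd.DataFrame, int]:
    """Per-genome, per-category merged cluster counts and the tally of
    distinct categories observed across the genome set."""
    rows = []
    categories: set[str] = set()
    for genome in sorted(merged_by_genome):
        counts: dict[str, int] = {}
        for m in merged_by_genome[genome]:
            counts[m.category] = counts.get(m.category, 0) + 1
            categories.add(m.category)
        for cat in sorted(counts):
            rows.append({"genome": genome, "category": cat, "n_clusters": counts[cat]})
        if not counts:
            rows.append({"genome": genome, "category": "none", "n_clusters": 0})
    return pd.DataFrame(rows), len(categories)


@dataclass
class EnrichmentResult:
    genome_id: str
    frac_core: float
    frac_accessory: float
    per_cluster: list[dict]


def _interval_union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for s, e in sorted(intervals):
        s = max(s, last)
        if e > s:
            total += e - s
            last = e
        last = max(last, e)
    return total


def _og_classes(groups: Sequence[OrthologGroup]) -> dict[str, str]:
    out = {}
    for g in groups:
        if g.is_singleton:
            out[g.og_id] = "singleton"
        elif g.is_core:
            out[g.og_id] = "core"
        else:
            out[g.og_id] = "dispensable"
    return out


def core_accessory_span(
    genome: GenomeAssembly,
    merged_clusters: Sequence[MergedCluster],
    regions: Sequence[BGCRegion],
    partition: PanGenomePartition,
    groups: Sequence[OrthologGroup],
) -> EnrichmentResult:
    """Per cluster, the fraction of cluster length covered by the union of
    core-gene CDS positions, and separately by accessory (dispensable +
    singleton) genes; genome value = mean over its clusters.  Matching is
    by annotated coordinates."""
    og_class = _og_classes(groups)
    region_by_id = {r.region_id: r for r in regions}
    cds = genome.features_of_kind("CDS")
    per_cluster = []
    for m in merged_clusters:
        ivals: dict[str, list[tuple[int, int]]] = {"core": [], "accessory": []}
        total_len = 0
        for rid in m.member_region_ids:
            r = region_by_id[rid]
            total_len += r.length
            for f in cds:
                if f.contig_id != r.contig_id:
                    continue
                s, e = max(f.start, r.start), min(f.end, r.end)
                if e <= s:
                    continue
                og = partition.membership.get(f.feature_id)
                if og is None:
                    continue
                cls = og_class.get(og)
                key = "core" if cls == "core" else "accessory"
                # offset by region to keep multi-contig unions disjoint
                ivals[key].append((rid, s, e))
        cov = {
            key: sum(
                _interval_union_length([(s, e) for rid2, s, e in vals if rid2 == rid])
                for rid in m.member_region_ids
            )
            for key, vals in ivals.items()
        }
        per_cluster.append(
            {
                "cluster_id": m.cluster_id,
                "length": total_len,
                "frac_core": cov["core"] / total_len if total_len else 0.0,
                "frac_accessory": cov["accessory"] / total_len if total_len else 0.0,
            }
        )
    if per_cluster:
        frac_core = float(np.mean([c["frac_core"] for c in per_cluster]))
        frac_acc = float(np.mean([c["frac_accessory"] for c in per_cluster]))
    else:
        frac_core = frac_acc = 0.0
    return EnrichmentResult(genome.genome_id, frac_core, frac_acc, per_cluster)


def count_size_correlation(
    counts: Mapping[str, int], sizes: Mapping[str, int]
) -> float | None:
    """Pearson r of (genome size, merged BGC count); None (flagged) for
    fewer than 3 genomes or zero variance."""
    genomes = sorted(set(counts) & set(sizes))
    if len(genomes) < 3:
        return None
    x = np.array([sizes[g] for g in genomes], dtype=float)
    y = np.array([counts[g] for g in genomes], dtype=float)
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        return None
    return float(stats.pearsonr(x, y).statistic)
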