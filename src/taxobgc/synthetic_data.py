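"""Synthetic clade generator with ground truth.

Emulates a small clade of draft bacterial genome assemblies: core,
dispensable and strain-specific (singleton) genes, one slowly-evolving
rRNA-like marker gene per genome, planted PKS/NRPS/hybrid biosynthetic gene
clusters carrying KS/C domain genes, and deliberate assembly fragmentation
that can cut a planted cluster across contigs.  Every planted fact is
recorded in a :class:`TruthTable` so each downstream stage of the pipeline
has an exact oracle.

Evolution is Jukes-Cantor compatible and indel-free by default: every site
mutates independently to one of the three alternative bases with probability
``(3/4)(1 - exp(-4d/3))`` for branch divergence ``d`` (expected
substitutions per site), so homologous sequences stay positionally aligned
and the generator's realized identities can be compared directly against
fragment-based ANI and tree estimates.

Seeding: one master seed; every stochastic sub-operation derives a child
``numpy.random.SeedSequence(master, spawn_key=(crc32(key), ...))`` from
stable string keys (segment/ortholog-group id plus tree-node index), so any
genome or segment can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GeneFeature, GenomeAssembly, newick_str, tree_from_newick

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: nt length of one synthetic KS/C domain gene (multiple of 3)
DOMAIN_LENGTH = 450
#: default master seed of the shared KS/C domain sequence families; kept
#: separate from the clade seed so detection profiles built from the family
#: share ancestry with planted domains regardless of the clade being drawn
DOMAIN_FAMILY_SEED = 777


# ---------------------------------------------------------------------------
# Configuration types

@dataclass
class FragmentationPolicy:
    """How to break each genome into contigs.

    breakpoints: 'none', 'uniform_random' (anywhere outside gene/domain
    features) or 'at_planted_split_positions' (inside the inter-domain
    spacers that templates marked via ``split_in``).
    """

    n_contigs_per_genome: int | tuple[int, int] = 1
    breakpoints: str = "none"

    def __post_init__(self) -> None:
        if self.breakpoints not in ("none", "uniform_random", "at_planted_split_positions"):
            raise ValueError(f"unknown breakpoint policy {self.breakpoints!r}")


@dataclass
class BGCTemplate:
    """Blueprint of one planted biosynthetic gene cluster.

    ``split_in`` maps genome id -> split policy ('midpoint' or an integer
    inter-domain gap index); a genome listed there gets the cluster cut at
    that gap when fragmentation uses planted split positions.
    ``n_filler_genes``/``n_core_genes_inside`` let clusters carry additional
    accessory and core CDSs so core/accessory span fractions are controllable.
    """

    category: str  # PKS | NRPS | hybrid
    n_domains: int = 2
    domain_types: tuple[str, ...] | None = None
    cluster_length: int = 12_000
    inter_domain_spacer: int = 900
    carrier_genomes: tuple[str, ...] | None = None  # None = all genomes
    split_in: Mapping[str, str | int] = field(default_factory=dict)
    intra_cluster_divergence: float = 0.01
    inter_cluster_divergence: float = 0.15
    domain_length: int = DOMAIN_LENGTH
    n_filler_genes: int = 0
    filler_gene_length: int = 600
    n_core_genes_inside: int = 0
    core_inside_gene_length: int = 600

    def __post_init__(self) -> None:
        if self.category not in ("PKS", "NRPS", "hybrid"):
            raise ValueError(f"unknown BGC category {self.category!r}")
        if self.domain_types is None:
            if self.category == "PKS":
                self.domain_types = ("KS",) * self.n_domains
            elif self.category == "NRPS":
                self.domain_types = ("C",) * self.n_domains
            else:
                half = max(1, self.n_domains // 2)
                self.domain_types = ("KS",) * half + ("C",) * (self.n_domains - half)
        self.domain_types = tuple(self.domain_types)
        if self.carrier_genomes is not None:
            self.carrier_genomes = tuple(self.carrier_genomes)
        self.split_in = dict(self.split_in)
        if len(self.domain_types) != self.n_domains:
            raise ValueError("domain_types length must equal n_domains")
        kinds = set(self.domain_types)
        if self.category == "PKS" and kinds != {"KS"}:
            raise ValueError("PKS templates contain only KS domains")
        if self.category == "NRPS" and kinds != {"C"}:
            raise ValueError("NRPS templates contain only C domains")
        if self.category == "hybrid" and not {"KS", "C"} <= kinds:
            raise ValueError("hybrid templates need at least one KS and one C domain")


@dataclass
class CladeConfig:
    n_genomes: int = 5
    tree_shape: str = "balanced"  # balanced | caterpillar | explicit newick
    branch_divergences: float = 0.02
    n_core_genes: int = 120
    n_dispensable_genes: int = 60
    dispensable_presence_prob: float = 0.5
    n_singletons_per_genome: int = 8
    gene_length_range: tuple[int, int] = (300, 900)
    marker_gene_length: int = 1500
    marker_rate_multiplier: float = 0.5
    intergenic_length: int = 120
    #: background sequence inserted before every planted cluster so that
    #: separate clusters can never be chained into one region (> max_gap)
    bgc_separation_nt: int = 25_000
    gc_fraction: float = 0.68
    bgc_templates: tuple[BGCTemplate, ...] = ()
    fragmentation: FragmentationPolicy = field(default_factory=FragmentationPolicy)
    indels_enabled: bool = False
    species_labels: Mapping[str, str] | None = None
    domain_family_seed: int = DOMAIN_FAMILY_SEED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if not 0.0 <= self.dispensable_presence_prob <= 1.0:
            raise ValueError("dispensable_presence_prob must be in [0, 1]")
        if self.branch_divergences < 0:
            raise ValueError("branch divergences must be >= 0")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3:
            raise ValueError("gene lengths must be divisible by 3")
        if self.marker_gene_length <= 0:
            raise ValueError("marker_gene_length must be positive")


@dataclass
class TruthTable:
    """Generator ground truth used as the acceptance oracle downstream."""

    ortholog_membership: dict[str, str]  # gene id -> planted group id
    group_class: dict[str, str]  # group id -> core | dispensable | singleton
    realized_pairwise_identity: dict[tuple[str, str], float]
    true_clusters: dict[str, dict]  # cluster instance id -> metadata
    fragmentation_map: dict[str, str]  # region id -> cluster instance id
    species_labels: dict[str, str]
    true_topology: str  # newick

    def identity(self, a: str, b: str) -> float:
        return self.realized_pairwise_identity[tuple(sorted((a, b)))]


# ---------------------------------------------------------------------------
# Seed derivation & random sequence primitives

def child_seed(master: int, *keys: str | int) -> np.random.SeedSequence:
    spawn = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    )
    return np.random.SeedSequence(master, spawn_key=spawn)


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.68) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def random_gene(length: int, rng: np.random.Generator, gc: float = 0.68) -> str:
    """Random protein-coding sequence (no in-frame stop codons at the root)."""
    if length % 3:
        raise ValueError("gene length must be divisible by 3")
    codons: list[str] = []
    while len(codons) < length // 3:
        c = random_dna(3, rng, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def evolve_sequence(
    seq: str,
    divergence: float,
    seed: int | np.random.SeedSequence,
) -> tuple[str, float]:
    """Substitute each site independently under the Jukes-Cantor model.

    Each site mutates with probability ``(3/4)(1 - exp(-4d/3))`` to one of
    the three alternative bases chosen uniformly.  Returns the evolved
    sequence and the realized identity (matching sites / length) relative to
    the input.  Deterministic for a fixed seed.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if not seq:
        raise ValueError("sequence must be non-empty")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_TO_INT.items():
        idx[arr == ord(base)] = i
    bad = np.nonzero(idx < 0)[0]
    if bad.size:
        raise ValueError(
            f"non-ACGT character {seq[bad[0]]!r} at position {int(bad[0])}"
        )
    if divergence == 0:
        return seq, 1.0
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * divergence / 3.0))
    rng = np.random.default_rng(seed)
    hit = rng.random(idx.size) < p_sub
    offsets = rng.integers(1, 4, size=idx.size)
    new_idx = np.where(hit, (idx + offsets) % 4, idx)
    out = "".join(BASES[i] for i in new_idx)
    realized = 1.0 - hit.mean()
    return out, float(realized)


# ---------------------------------------------------------------------------
# Clade tree construction

def build_clade_tree(config: CladeConfig):
    """skbio TreeNode with branch lengths = expected substitutions/site."""
    import skbio

    names = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    d = config.branch_divergences
    if "(" in config.tree_shape:
        tree = tree_from_newick(config.tree_shape)
        tips = [t.name for t in tree.tips()]
        if len(tips) != config.n_genomes:
            raise ValueError("explicit newick tip count != n_genomes")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = d
        return tree
    if config.tree_shape == "caterpillar":
        nwk = names[0] + f":{d}"
        for name in names[1:-1]:
            nwk = f"({nwk},{name}:{d}):{d}"
        nwk = f"({nwk},{names[-1]}:{d});"
        return tree_from_newick(nwk)
    if config.tree_shape == "balanced":
        nodes = [f"{n}:{d}" for n in names]
        while len(nodes) > 1:
            merged = []
            for i in range(0, len(nodes) - 1, 2):
                merged.append(f"({nodes[i]},{nodes[i + 1]}):{d}")
            if len(nodes) % 2:
                merged.append(nodes[-1])
            nodes = merged
        return tree_from_newick(nodes[0].rsplit(":", 1)[0] + ";")
    raise ValueError(f"unknown tree_shape {config.tree_shape!r}")


# ---------------------------------------------------------------------------
# Internal genome blueprint

@dataclass
class _Segment:
    seg_id: str
    kind: str  # spacer | gene | marker
    root_seq: str
    presence: frozenset[str] | None = None  # None = all genomes
    group_id: str | None = None
    gene_role: str | None = None  # core | dispensable | singleton | bgc_domain | bgc_filler | bgc_core
    cluster_id: str | None = None
    domain_type: str | None = None
    rate: float = 1.0
    evolves: bool = True

    def present_in(self, genome: str) -> bool:
        return self.presence is None or genome in self.presence

    @property
    def evolution_key(self) -> str:
        return self.group_id or self.seg_id


def domain_consensus(domain_type: str, family_seed: int = DOMAIN_FAMILY_SEED,
                     length: int = DOMAIN_LENGTH) -> str:
    rng = np.random.default_rng(child_seed(family_seed, "consensus", domain_type))
    return random_gene(length, rng)


def domain_seed_alignment(
    domain_type: str,
    n_seeds: int = 8,
    divergence: float = 0.10,
    family_seed: int = DOMAIN_FAMILY_SEED,
    length: int = DOMAIN_LENGTH,
) -> list[str]:
    """Positionally aligned family members used to build detection profiles."""
    consensus = domain_consensus(domain_type, family_seed, length)
    out = []
    for i in range(n_seeds):
        seq, _ = evolve_sequence(
            consensus, divergence, child_seed(family_seed, "seedaln", domain_type, i)
        )
        out.append(seq)
    return out


def _build_segments(config: CladeConfig, genome_ids: list[str]) -> list[_Segment]:
    segs: list[_Segment] = []
    master = config.seed
    lo, hi = config.gene_length_range
    spacer_count = 0

    def spacer(length: int, presence=None, cluster_id=None) -> None:
        nonlocal spacer_count
        rng = np.random.default_rng(child_seed(master, "spacer", spacer_count))
        segs.append(
            _Segment(
                seg_id=f"sp{spacer_count:05d}",
                kind="spacer",
                root_seq=random_dna(length, rng, config.gc_fraction),
                presence=presence,
                cluster_id=cluster_id,
            )
        )
        spacer_count += 1

    def gene_length(rng: np.random.Generator) -> int:
        return int(rng.integers(lo // 3, hi // 3 + 1)) * 3

    # --- core genes
    for i in range(config.n_core_genes):
        rng = np.random.default_rng(child_seed(master, "core", i))
        spacer(config.intergenic_length)
        segs.append(
            _Segment(
                seg_id=f"core{i:05d}",
                kind="gene",
                root_seq=random_gene(gene_length(rng), rng, config.gc_fraction),
                group_id=f"OG_core{i:05d}",
                gene_role="core",
            )
        )

    # --- dispensable genes (presence decided up front; empty draws dropped)
    presence_rng = np.random.default_rng(child_seed(master, "dispensable_presence"))
    for i in range(config.n_dispensable_genes):
        carriers = frozenset(
            g
            for g in genome_ids
            if presence_rng.random() < config.dispensable_presence_prob
        )
        if not carriers:
            continue
        rng = np.random.default_rng(child_seed(master, "disp", i))
        spacer(config.intergenic_length)
        segs.append(
            _Segment(
                seg_id=f"disp{i:05d}",
                kind="gene",
                root_seq=random_gene(gene_length(rng), rng, config.gc_fraction),
                presence=carriers,
                group_id=f"OG_disp{i:05d}",
                gene_role="dispensable",
            )
        )

    # --- planted BGC clusters
    for j, tpl in enumerate(config.bgc_templates):
        carriers = frozenset(tpl.carrier_genomes or genome_ids)
        unknown = carriers - set(genome_ids)
        if unknown:
            raise ValueError(f"BGC template {j}: unknown carrier genomes {sorted(unknown)}")
        cluster_id = f"bgc{j:02d}"
        parts = 2 * 2000  # two 2 kb flanks
        parts += tpl.n_domains * tpl.domain_length
        parts += (tpl.n_domains - 1) * tpl.inter_domain_spacer
        parts += tpl.n_filler_genes * (tpl.filler_gene_length + tpl.inter_domain_spacer)
        parts += tpl.n_core_genes_inside * (tpl.core_inside_gene_length + tpl.inter_domain_spacer)
        if parts > tpl.cluster_length:
            raise ValueError(
                f"BGC template {j}: components ({parts} nt) exceed cluster_length "
                f"({tpl.cluster_length} nt)"
            )
        spacer(config.bgc_separation_nt)
        spacer(2000, presence=carriers, cluster_id=cluster_id)  # leading flank

        def domain_segment(k: int) -> _Segment:
            dtype = tpl.domain_types[k]
            consensus = domain_consensus(dtype, config.domain_family_seed, tpl.domain_length)
            variant, _ = evolve_sequence(
                consensus,
                tpl.inter_cluster_divergence,
                child_seed(master, "bgcvariant", cluster_id, dtype),
            )
            dom_seq, _ = evolve_sequence(
                variant,
                tpl.intra_cluster_divergence,
                child_seed(master, "bgcdomain", cluster_id, k),
            )
            return _Segment(
                seg_id=f"{cluster_id}_dom{k}",
                kind="gene",
                root_seq=dom_seq,
                presence=carriers,
                group_id=f"OG_{cluster_id}_dom{k}",
                gene_role="bgc_domain",
                cluster_id=cluster_id,
                domain_type=dtype,
            )

        # first domain, then interior accessory/core genes (kept between the
        # bracketing domains so the called region spans them), then the rest
        segs.append(domain_segment(0))
        for k in range(tpl.n_filler_genes):
            rng = np.random.default_rng(child_seed(master, "bgcfill", cluster_id, k))
            spacer(tpl.inter_domain_spacer, presence=carriers, cluster_id=cluster_id)
            segs.append(
                _Segment(
                    seg_id=f"{cluster_id}_fill{k}",
                    kind="gene",
                    root_seq=random_gene(tpl.filler_gene_length, rng, config.gc_fraction),
                    presence=carriers,
                    group_id=f"OG_{cluster_id}_fill{k}",
                    gene_role="bgc_filler",
                    cluster_id=cluster_id,
                )
            )
        for k in range(tpl.n_core_genes_inside):
            rng = np.random.default_rng(child_seed(master, "bgccore", cluster_id, k))
            core_seq = random_gene(tpl.core_inside_gene_length, rng, config.gc_fraction)
            group = f"OG_{cluster_id}_incore{k}"
            spacer(tpl.inter_domain_spacer, presence=carriers, cluster_id=cluster_id)
            segs.append(
                _Segment(
                    seg_id=f"{cluster_id}_incore{k}",
                    kind="gene",
                    root_seq=core_seq,
                    presence=carriers,
                    group_id=group,
                    gene_role="bgc_core",
                    cluster_id=cluster_id,
                )
            )
            # twin copy outside the cluster for non-carrier genomes keeps the
            # group core across the whole clade (same group key => identical
            # evolved sequence at every tree node)
            non_carriers = frozenset(genome_ids) - carriers
            if non_carriers:
                segs.append(
                    _Segment(
                        seg_id=f"{cluster_id}_incore{k}_twin",
                        kind="gene",
                        root_seq=core_seq,
                        presence=non_carriers,
                        group_id=group,
                        gene_role="bgc_core",
                    )
                )
        for k in range(1, tpl.n_domains):
            spacer(tpl.inter_domain_spacer, presence=carriers, cluster_id=cluster_id)
            segs.append(domain_segment(k))
        pad = tpl.cluster_length - parts
        spacer(2000 + pad, presence=carriers, cluster_id=cluster_id)  # trailing flank

    # --- marker gene (16S-like, slower rate)
    rng = np.random.default_rng(child_seed(master, "marker"))
    spacer(config.intergenic_length)
    segs.append(
        _Segment(
            seg_id="marker",
            kind="marker",
            root_seq=random_dna(config.marker_gene_length, rng, 0.55),
            rate=config.marker_rate_multiplier,
        )
    )

    # --- singletons: i.i.d. random sequence per genome, never homologous
    for g_i, g in enumerate(genome_ids):
        for i in range(config.n_singletons_per_genome):
            rng = np.random.default_rng(child_seed(master, "singleton", g_i, i))
            spacer(config.intergenic_length, presence=frozenset([g]))
            segs.append(
                _Segment(
                    seg_id=f"sing_{g}_{i:03d}",
                    kind="gene",
                    root_seq=random_gene(gene_length(rng), rng, config.gc_fraction),
                    presence=frozenset([g]),
                    group_id=f"OG_sing_{g}_{i:03d}",
                    gene_role="singleton",
                    evolves=False,
                )
            )
    spacer(config.intergenic_length)
    return segs


# ---------------------------------------------------------------------------
# Clade generation

def generate_clade(config: CladeConfig) -> tuple[list[GenomeAssembly], TruthTable]:
    """Simulate the clade and return assemblies plus the truth table.

    Applies ``config.fragmentation`` to every genome; with the default
    policy each genome stays a single contig.
    """
    tree = build_clade_tree(config)
    genome_ids = sorted(t.name for t in tree.tips())
    node_index = {id(n): i for i, n in enumerate(tree.traverse(include_self=True))}
    segments = _build_segments(config, genome_ids)

    # Evolve every segment down the tree once per ortholog-group key.
    leaf_seqs: dict[str, dict[str, str]] = {g: {} for g in genome_ids}
    for seg in segments:
        if not seg.evolves:
            for g in genome_ids:
                if seg.present_in(g):
                    leaf_seqs[g][seg.seg_id] = seg.root_seq
            continue
        seqs_at = {id(tree): seg.root_seq}
        for node in tree.preorder(include_self=False):
            parent_seq = seqs_at[id(node.parent)]
            bl = (node.length or 0.0) * seg.rate
            evolved, _ = evolve_sequence(
                parent_seq,
                bl,
                child_seed(config.seed, "evolve", seg.evolution_key, node_index[id(node)]),
            )
            seqs_at[id(node)] = evolved
            if node.is_tip() and seg.present_in(node.name):
                leaf_seqs[node.name][seg.seg_id] = evolved
        # tips that are also the root (never happens for n>=2) ignored

    # Assemble genomes and features.
    genomes: list[GenomeAssembly] = []
    ortholog_membership: dict[str, str] = {}
    group_presence: dict[str, dict[str, int]] = {}
    true_clusters: dict[str, dict] = {}
    fragmentation_map: dict[str, str] = {}
    cluster_templates = {f"bgc{j:02d}": tpl for j, tpl in enumerate(config.bgc_templates)}

    for g in genome_ids:
        contig_id = f"{g}_ctg1"
        parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 0
        open_cluster: str | None = None
        cluster_span: dict[str, list[int]] = {}
        cluster_members: dict[str, list[tuple[str, str, int, int]]] = {}
        for seg in segments:
            if not seg.present_in(g):
                continue
            seq = leaf_seqs[g][seg.seg_id] if seg.seg_id in leaf_seqs[g] else seg.root_seq
            start, end = pos, pos + len(seq)
            if seg.cluster_id is not None:
                span = cluster_span.setdefault(seg.cluster_id, [start, end])
                span[1] = end
            if seg.kind == "gene":
                gene_id = f"{g}_{seg.seg_id}"
                ortholog_membership[gene_id] = seg.group_id
                counts = group_presence.setdefault(seg.group_id, {})
                counts[g] = counts.get(g, 0) + 1
                attrs = {"category": seg.gene_role}
                features.append(
                    GeneFeature(gene_id, contig_id, start, end, "+", "CDS", attrs)
                )
                if seg.gene_role == "bgc_domain":
                    features.append(
                        GeneFeature(
                            f"{gene_id}_dom",
                            contig_id,
                            start,
                            end,
                            "+",
                            "BGC_domain",
                            {
                                "domain_type": seg.domain_type,
                                "cluster": f"{g}_{seg.cluster_id}",
                            },
                        )
                    )
                if seg.cluster_id is not None:
                    cluster_members.setdefault(seg.cluster_id, []).append(
                        (gene_id, seg.gene_role, start, end)
                    )
            elif seg.kind == "marker":
                features.append(
                    GeneFeature(f"{g}_marker", contig_id, start, end, "+", "marker_rRNA", {})
                )
            parts.append(seq)
            pos = end
        full = "".join(parts)

        # region features + truth clusters
        for cid, (cstart, cend) in sorted(cluster_span.items()):
            tpl = cluster_templates[cid]
            instance = f"{g}_{cid}"
            region_id = f"{instance}_region"
            # candidate split points: midpoints of the gaps between
            # consecutive cluster CDSs (always inside spacers, never domains)
            members = cluster_members.get(cid, [])
            gaps = [
                (members[i][3] + members[i + 1][2]) // 2
                for i in range(len(members) - 1)
            ]
            attrs = {
                "category": tpl.category,
                "cluster": instance,
                "split_points": ",".join(str(x) for x in gaps),
            }
            if g in tpl.split_in:
                attrs["split_policy"] = str(tpl.split_in[g])
            features.append(
                GeneFeature(region_id, contig_id, cstart, cend, "+", "BGC_region", attrs)
            )
            true_clusters[instance] = {
                "genome": g,
                "cluster_id": cid,
                "category": tpl.category,
                "member_region_ids": [region_id],
                "total_length": cend - cstart,
                "member_genes": [m[0] for m in members],
            }
            fragmentation_map[region_id] = instance

        features.sort(key=lambda f: (f.start, f.feature_id))
        genomes.append(GenomeAssembly(g, [(contig_id, full)], features))

    # realized pairwise identities over shared segments (deduplicated by
    # ortholog-group key so twin placements count once)
    realized: dict[tuple[str, str], float] = {}
    for i, a in enumerate(genome_ids):
        for b in genome_ids[i + 1 :]:
            match = total = 0
            seen_keys: set[str] = set()
            for seg in segments:
                if not (seg.present_in(a) and seg.present_in(b)):
                    continue
                if seg.evolution_key in seen_keys:
                    continue
                seen_keys.add(seg.evolution_key)
                sa = leaf_seqs[a][seg.seg_id]
                sb = leaf_seqs[b][seg.seg_id]
                total += len(sa)
                match += sum(1 for x, y in zip(sa, sb) if x == y)
            realized[(a, b)] = match / total if total else 1.0

    group_class = {}
    for group, counts in group_presence.items():
        total_copies = sum(counts.values())
        if total_copies == 1:
            group_class[group] = "singleton"
        elif len(counts) == len(genome_ids):
            group_class[group] = "core"
        else:
            group_class[group] = "dispensable"

    species = dict(config.species_labels or {g: "sp1" for g in genome_ids})
    truth = TruthTable(
        ortholog_membership=ortholog_membership,
        group_class=group_class,
        realized_pairwise_identity=realized,
        true_clusters=true_clusters,
        fragmentation_map=fragmentation_map,
        species_labels=species,
        true_topology=newick_str(tree),
    )

    if config.fragmentation.breakpoints != "none" or (
        isinstance(config.fragmentation.n_contigs_per_genome, int)
        and config.fragmentation.n_contigs_per_genome > 1
    ):
        genomes = [
            fragment_assembly(
                gnm, config.fragmentation, child_seed(config.seed, "frag", gi), truth
            )
            for gi, gnm in enumerate(genomes)
        ]
    return genomes, truth


# ---------------------------------------------------------------------------
# Fragmentation

def _allowed_breakpoints(genome: GenomeAssembly) -> np.ndarray:
    """Positions where a cut touches no gene/marker/domain feature."""
    length = genome.total_length
    blocked = np.zeros(length + 1, dtype=bool)
    blocked[0] = blocked[length] = True
    for f in genome.features:
        if f.kind in ("CDS", "marker_rRNA", "BGC_domain"):
            blocked[f.start + 1 : f.end] = True  # cut at pos splits [pos-1|pos]
            blocked[f.start] = blocked[f.end] = True
    return np.nonzero(~blocked)[0]


def fragment_assembly(
    genome: GenomeAssembly,
    policy: FragmentationPolicy,
    seed: int | np.random.SeedSequence,
    truth: TruthTable | None = None,
) -> GenomeAssembly:
    """Cut a single-contig assembly into contigs per the policy.

    Features are re-mapped to contig-local coordinates; BGC_region features
    spanning a cut are split into boundary-touching pieces and the truth
    table's fragmentation_map (when given) is updated to send every piece to
    its planted cluster instance.  Concatenating the output contigs in order
    reconstructs the input sequence exactly.
    """
    if len(genome.contigs) != 1:
        raise ValueError("fragment_assembly expects a single-contig assembly")
    contig_id, seq = genome.contigs[0]
    length = len(seq)
    rng = np.random.default_rng(seed)

    cuts: list[int] = []
    if policy.breakpoints == "uniform_random":
        n = policy.n_contigs_per_genome
        if isinstance(n, tuple):
            n = int(rng.integers(n[0], n[1] + 1))
        allowed = _allowed_breakpoints(genome)
        if len(allowed) < n - 1:
            raise ValueError("not enough breakpoint positions for requested contigs")
        if n > 1:
            cuts = sorted(int(x) for x in rng.choice(allowed, size=n - 1, replace=False))
    elif policy.breakpoints == "at_planted_split_positions":
        for f in genome.features:
            if f.kind != "BGC_region" or "split_policy" not in f.attributes:
                continue
            pts = [int(x) for x in f.attributes["split_points"].split(",") if x]
            if not pts:
                raise ValueError(f"region {f.feature_id} has no plantable split gap")
            pol = f.attributes["split_policy"]
            if pol == "midpoint":
                mid = (f.start + f.end) // 2
                cuts.append(min(pts, key=lambda x: abs(x - mid)))
            elif pol == "all":  # one cut in every inter-domain gap
                cuts.extend(pts)
            else:
                cuts.append(pts[int(pol)])
        cuts = sorted(set(cuts))
    if not cuts:
        return genome

    bounds = [0] + cuts + [length]
    new_contigs = [
        (f"{contig_id}_c{i + 1}", seq[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    assert "".join(s for _, s in new_contigs) == seq

    def locate(pos: int) -> int:
        """Index of the piece containing global position pos (pos < cut boundary)."""
        for i in range(len(bounds) - 1):
            if bounds[i] <= pos < bounds[i + 1]:
                return i
        return len(bounds) - 2

    new_features: list[GeneFeature] = []
    for f in genome.features:
        i0, i1 = locate(f.start), locate(f.end - 1)
        if i0 == i1:
            new_features.append(
                replace(
                    f,
                    contig_id=new_contigs[i0][0],
                    start=f.start - bounds[i0],
                    end=f.end - bounds[i0],
                )
            )
            continue
        # a cut runs through the feature: only permitted for region features
        assert f.kind == "BGC_region", (
            f"breakpoint inside {f.kind} feature {f.feature_id}"
        )
        cluster = truth.fragmentation_map.get(f.feature_id) if truth else None
        for part, i in enumerate(range(i0, i1 + 1), start=1):
            pstart = max(f.start, bounds[i]) - bounds[i]
            pend = min(f.end, bounds[i + 1]) - bounds[i]
            piece = replace(
                f,
                feature_id=f"{f.feature_id}.p{part}",
                contig_id=new_contigs[i][0],
                start=pstart,
                end=pend,
                attributes=dict(f.attributes),
            )
            new_features.append(piece)
            if truth is not None and cluster is not None:
                truth.fragmentation_map[piece.feature_id] = cluster
        if truth is not None and cluster is not None:
            del truth.fragmentation_map[f.feature_id]
            true = truth.true_clusters.get(cluster)
            if true is not None:
                true["member_region_ids"] = [
                    rid
                    for rid, c in truth.fragmentation_map.items()
                    if c == cluster
                ]
    return GenomeAssembly(genome.genome_id, new_contigs, new_features)
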