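"""End-to-end orchestration: simulate -> orthology -> OGRI -> classify ->
phylogeny -> BGC -> synteny -> report.

Each stage is a function that takes in-memory inputs and writes its TSV
outputs before returning, so a failing stage leaves all completed outputs
intact and is named in the raised :class:`StageError`.  Configuration is
plain YAML mirroring the per-module defaults; the whole run is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import glob
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bgc, genome_io, ogri, orthology, phylogeny, synteny, taxonomy
from .genome_io import GenomeAssembly, write_json, write_tsv
from .synthetic_data import (
    BGCTemplate,
    CladeConfig,
    FragmentationPolicy,
    TruthTable,
    child_seed,
    generate_clade,
)

logger = logging.getLogger("taxobgc")


class ConfigError(ValueError):
    """Invalid run configuration (caught before any compute)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "orthology": {
        "min_identity": 0.4,
        "min_coverage": 0.5,
        "kmer_prefilter": 5,
        "n_permutations": 100,
    },
    "ogri": {"fragment_length": 1020, "min_fragment_coverage": 0.35},
    "phylogeny": {"n_bootstrap": 1000},
    "bgc": {
        "max_gap": 20000,
        "flank": 5000,
        "score_threshold": 100.0,
        "sister_mode": "cherry",
        "boundary_tolerance": 0,
    },
    "synteny": {"seed_k": 15, "min_length": 500, "min_identity": 90.0, "max_gap": 25000},
    "taxonomy": {},
}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    genomes_dir: str | None = None  # read assemblies instead of simulating
    clade: CladeConfig | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        merged = {k: dict(v) for k, v in _DEFAULT_PARAMS.items()}
        for block, values in self.params.items():
            if block not in merged:
                raise ConfigError(f"unknown parameter block {block!r}")
            for key, val in values.items():
                if key not in merged[block]:
                    raise ConfigError(f"unknown parameter {block}.{key}")
                merged[block][key] = val
        self.params = merged
        if self.genomes_dir is None and self.clade is None:
            self.clade = CladeConfig(seed=self.seed)

    def to_yaml(self) -> str:
        out: dict[str, Any] = {
            "outdir": self.outdir,
            "seed": self.seed,
            "verbosity": self.verbosity,
            "params": self.params,
        }
        if self.genomes_dir:
            out["genomes_dir"] = self.genomes_dir
        if self.clade is not None:
            clade = dataclasses.asdict(self.clade)
            clade["fragmentation"] = dataclasses.asdict(self.clade.fragmentation)
            clade["bgc_templates"] = [dataclasses.asdict(t) for t in self.clade.bgc_templates]
            out["clade"] = clade
        return yaml.safe_dump(out, sort_keys=True)


def validate_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration; raises ConfigError
    listing every problem found."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = {"outdir", "seed", "genomes_dir", "clade", "params", "verbosity"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    gdir = raw.get("genomes_dir")
    if gdir is not None and not os.path.isdir(gdir):
        errors.append(f"genomes_dir {gdir!r} does not exist")
    for block, values in (raw.get("params") or {}).items():
        if block not in _DEFAULT_PARAMS:
            errors.append(f"unknown parameter block {block!r}")
            continue
        for key in values or {}:
            if key not in _DEFAULT_PARAMS[block]:
                errors.append(f"unknown parameter {block}.{key}")
    mi = (raw.get("params") or {}).get("orthology", {}).get("min_identity")
    if mi is not None and not 0 <= mi <= 1:
        errors.append("orthology.min_identity must be in [0, 1]")
    if errors:
        raise ConfigError("; ".join(errors))
    clade = None
    if raw.get("clade") is not None:
        craw = dict(raw["clade"])
        if "fragmentation" in craw:
            craw["fragmentation"] = FragmentationPolicy(**craw["fragmentation"])
        if "bgc_templates" in craw:
            craw["bgc_templates"] = tuple(BGCTemplate(**t) for t in craw["bgc_templates"])
        if isinstance(craw.get("gene_length_range"), list):
            craw["gene_length_range"] = tuple(craw["gene_length_range"])
        try:
            clade = CladeConfig(**craw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid clade config: {exc}") from exc
    return RunConfig(
        outdir=raw["outdir"],
        seed=int(raw.get("seed", 0)),
        genomes_dir=gdir,
        clade=clade,
        params=raw.get("params") or {},
        verbosity=raw.get("verbosity", "INFO"),
    )


@dataclass
class RunReport:
    manifest: dict[str, str]
    provenance: dict[str, Any]
    headline: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "provenance": self.provenance,
            "headline": self.headline,
        }


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """Small worked example: 5 genomes, 2 planted species, one PKS cluster
    split across contigs in one genome."""
    clade = CladeConfig(
        n_genomes=5,
        tree_shape="(((G01:0.005,G02:0.005):0.01,G03:0.015):0.04,(G04:0.01,G05:0.01):0.04);",
        n_core_genes=100,
        n_dispensable_genes=40,
        dispensable_presence_prob=0.5,
        n_singletons_per_genome=6,
        bgc_templates=(
            BGCTemplate(
                category="PKS",
                n_domains=2,
                cluster_length=15_000,
                carrier_genomes=("G01", "G02", "G03"),
                split_in={"G01": "midpoint"},
            ),
        ),
        fragmentation=FragmentationPolicy(breakpoints="at_planted_split_positions"),
        species_labels={"G01": "sp1", "G02": "sp1", "G03": "sp1", "G04": "sp2", "G05": "sp2"},
        seed=seed,
    )
    return RunConfig(outdir=outdir, seed=seed, clade=clade)


# ---------------------------------------------------------------------------
# I/O helpers

def load_genomes(genomes_dir: str) -> list[GenomeAssembly]:
    genomes = []
    for fna in sorted(glob.glob(os.path.join(genomes_dir, "*.fna"))):
        gid = os.path.splitext(os.path.basename(fna))[0]
        genomes.append(genome_io.read_assembly(gid, genomes_dir))
    if not genomes:
        raise ConfigError(f"no *.fna assemblies found in {genomes_dir}")
    return genomes


def compute_proteomes(genomes: Sequence[GenomeAssembly]) -> dict[str, dict[str, str]]:
    return {
        g.genome_id: {f.feature_id: g.cds_protein(f) for f in g.features_of_kind("CDS")}
        for g in genomes
    }


def write_truth(truth: TruthTable, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_tsv(
        pd.DataFrame(
            [{"gene": g, "group": og} for g, og in sorted(truth.ortholog_membership.items())]
        ),
        os.path.join(outdir, "ortholog_membership.tsv"),
    )
    write_tsv(
        pd.DataFrame([{"group": g, "class": c} for g, c in sorted(truth.group_class.items())]),
        os.path.join(outdir, "group_class.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            [
                {"genome_a": a, "genome_b": b, "identity": v}
                for (a, b), v in sorted(truth.realized_pairwise_identity.items())
            ]
        ),
        os.path.join(outdir, "realized_identity.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "cluster": cid,
                    "genome": meta["genome"],
                    "category": meta["category"],
                    "total_length": meta["total_length"],
                    "regions": ",".join(meta["member_region_ids"]),
                }
                for cid, meta in sorted(truth.true_clusters.items())
            ]
        ),
        os.path.join(outdir, "true_clusters.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            [{"region": r, "cluster": c} for r, c in sorted(truth.fragmentation_map.items())]
        ),
        os.path.join(outdir, "fragmentation_map.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            [{"genome": g, "species": s} for g, s in sorted(truth.species_labels.items())]
        ),
        os.path.join(outdir, "species_labels.tsv"),
    )
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(truth.true_topology + "\n")


# ---------------------------------------------------------------------------
# Stages (each writes its outputs and returns its in-memory results)

def stage_simulate(config: RunConfig) -> tuple[list[GenomeAssembly], TruthTable | None]:
    if config.genomes_dir:
        return load_genomes(config.genomes_dir), None
    genomes, truth = generate_clade(config.clade)
    gdir = os.path.join(config.outdir, "genomes")
    for g in genomes:
        genome_io.write_assembly(g, gdir)
    write_truth(truth, os.path.join(config.outdir, "truth"))
    return genomes, truth


@dataclass
class OrthologyResult:
    rbh: dict[tuple[str, str], list[tuple[str, str]]]
    groups: list[orthology.OrthologGroup]
    partition: orthology.PanGenomePartition
    curve: orthology.AccumulationCurve


def stage_orthology(
    genomes: Sequence[GenomeAssembly],
    proteomes: Mapping[str, Mapping[str, str]],
    params: Mapping[str, Any],
    outdir: str,
    seed: int = 0,
) -> OrthologyResult:
    rbh = orthology.all_pairs_rbh(
        proteomes,
        min_identity=params["min_identity"],
        min_coverage=params["min_coverage"],
        kmer_prefilter=params["kmer_prefilter"],
    )
    groups = orthology.build_ortholog_groups(rbh, {g: list(p) for g, p in proteomes.items()})
    partition = orthology.partition_pangenome(groups)
    curve = orthology.accumulation_curves(
        groups,
        sorted(proteomes),
        n_permutations=params["n_permutations"],
        seed=int(np.random.default_rng(child_seed(seed, "curves")).integers(2**31)),
    )
    write_tsv(
        pd.DataFrame(
            [
                {"genome_a": a, "genome_b": b, "gene_a": x, "gene_b": y}
                for (a, b), pairs in rbh.items()
                for x, y in pairs
            ]
        ),
        os.path.join(outdir, "rbh_pairs.tsv"),
    )
    write_tsv(orthology.groups_table(groups), os.path.join(outdir, "ortholog_groups.tsv"))
    write_tsv(
        pd.DataFrame(
            [
                {
                    "n_core": partition.n_core,
                    "n_dispensable": partition.n_dispensable,
                    "n_singleton": partition.n_singleton,
                    "n_pan": partition.n_pan,
                }
            ]
        ),
        os.path.join(outdir, "pangenome_summary.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            {"n": curve.n_values, "mean_pan": curve.mean_pan, "mean_core": curve.mean_core}
        ),
        os.path.join(outdir, "accumulation_curve.tsv"),
    )
    return OrthologyResult(rbh, groups, partition, curve)


def stage_ogri(
    genomes: Sequence[GenomeAssembly],
    proteomes: Mapping[str, Mapping[str, str]],
    rbh: Mapping[tuple[str, str], Sequence[tuple[str, str]]] | None,
    params: Mapping[str, Any],
    outdir: str,
) -> list[ogri.PairwiseOGRI]:
    results, df = ogri.ogri_matrix(
        genomes, proteomes, fragment_length=params["fragment_length"], rbh_by_pair=rbh
    )
    write_tsv(df, os.path.join(outdir, "ogri_matrix.tsv"))
    return results


def stage_classify(
    results: Sequence[ogri.PairwiseOGRI],
    type_strains: Sequence[str],
    outdir: str,
) -> tuple[list[taxonomy.TaxonomicCall], dict[str, str]]:
    calls = [taxonomy.classify_pair(r) for r in results]
    ani_by_pair = {
        tuple(sorted(r.genome_pair)): r.ani for r in results if r.ani is not None
    }
    assignments = taxonomy.assign_strains(calls, ani_by_pair, type_strains)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "genome_a": c.genome_pair[0],
                    "genome_b": c.genome_pair[1],
                    "decision": c.decision,
                    "fuzzy": c.fuzzy,
                    "discordant": c.discordant,
                    **dict(c.evidence),
                }
                for c in calls
            ]
        ),
        os.path.join(outdir, "taxonomic_calls.tsv"),
    )
    write_tsv(
        pd.DataFrame([{"strain": s, "assignment": a} for s, a in sorted(assignments.items())]),
        os.path.join(outdir, "assignments.tsv"),
    )
    return calls, assignments


@dataclass
class PhylogenyResult:
    marker_tree: phylogeny.SupportedTree | None
    core_tree: phylogeny.SupportedTree
    n_single_copy_core: int


def stage_phylogeny(
    genomes: Sequence[GenomeAssembly],
    proteomes: Mapping[str, Mapping[str, str]],
    groups: Sequence[orthology.OrthologGroup],
    params: Mapping[str, Any],
    outdir: str,
    seed: int = 0,
) -> PhylogenyResult:
    boot_seed = int(np.random.default_rng(child_seed(seed, "boot")).integers(2**31))
    markers = {
        g.genome_id: g.feature_seq(g.features_of_kind("marker_rRNA")[0])
        for g in genomes
        if g.features_of_kind("marker_rRNA")
    }
    marker_tree = None
    if len(markers) >= 3:
        marker_tree = phylogeny.bootstrap_support(
            markers, n_replicates=params["n_bootstrap"], seed=boot_seed
        )
        with open(os.path.join(outdir, "marker_tree.nwk"), "w") as fh:
            fh.write(marker_tree.newick() + "\n")
    sc_groups = [g for g in groups if g.is_single_copy_core]
    block_alignments = {}
    for g in sc_groups:
        block = {
            genome: proteomes[genome][genes[0]] for genome, genes in g.members.items()
        }
        if len({len(s) for s in block.values()}) == 1:  # positionally aligned
            block_alignments[g.og_id] = block
    supermatrix, _parts = phylogeny.concatenate_core(block_alignments)
    core_tree = phylogeny.bootstrap_support(
        supermatrix, n_replicates=params["n_bootstrap"], seed=boot_seed + 1, distance="p"
    )
    with open(os.path.join(outdir, "core_tree.nwk"), "w") as fh:
        fh.write(core_tree.newick() + "\n")
    return PhylogenyResult(marker_tree, core_tree, len(sc_groups))


@dataclass
class BGCStageResult:
    regions_by_genome: dict[str, list[bgc.BGCRegion]]
    merged_by_genome: dict[str, list[bgc.MergedCluster]]
    n_categories: int
    pearson_r: float | None
    enrichment: list[dict]


def stage_bgc(
    genomes: Sequence[GenomeAssembly],
    partition: orthology.PanGenomePartition,
    groups: Sequence[orthology.OrthologGroup],
    params: Mapping[str, Any],
    outdir: str,
) -> BGCStageResult:
    regions_by_genome: dict[str, list[bgc.BGCRegion]] = {}
    merged_by_genome: dict[str, list[bgc.MergedCluster]] = {}
    region_rows, count_rows, enrich_rows, merged_rows = [], [], [], []
    for g in genomes:
        hits = bgc.hits_from_features(g)
        regions = bgc.call_regions(
            hits,
            g.contig_lengths(),
            max_gap=params["max_gap"],
            flank=params["flank"],
            boundary_tolerance=params["boundary_tolerance"],
        )
        merged = (
            bgc.merge_fragmented(regions, sister_mode=params["sister_mode"])
            if regions
            else []
        )
        regions_by_genome[g.genome_id] = regions
        merged_by_genome[g.genome_id] = merged
        for r in regions:
            region_rows.append(
                {
                    "genome": g.genome_id,
                    "region_id": r.region_id,
                    "contig": r.contig_id,
                    "start": r.start,
                    "end": r.end,
                    "category": r.category,
                    "completeness": r.completeness,
                    "n_domains": len(r.domains),
                }
            )
        for cat in sorted({r.category for r in regions}):
            est = bgc.expected_cluster_count(regions, cat, merged)
            count_rows.append(
                {
                    "genome": g.genome_id,
                    "category": cat,
                    "n_regions": est.n_regions,
                    "n_complete": est.n_complete,
                    "n_merged": est.n_merged,
                    "expected_count": est.expected_count,
                }
            )
        for m in merged:
            merged_rows.append(
                {
                    "genome": g.genome_id,
                    "cluster_id": m.cluster_id,
                    "category": m.category,
                    "n_members": len(m.member_region_ids),
                    "members": ",".join(m.member_region_ids),
                    "total_length": m.total_length,
                }
            )
        enr = bgc.core_accessory_span(g, merged, regions, partition, groups)
        enrich_rows.append(
            {
                "genome": g.genome_id,
                "frac_core": enr.frac_core,
                "frac_accessory": enr.frac_accessory,
                "n_clusters": len(enr.per_cluster),
            }
        )
    census_df, n_categories = bgc.bgc_census(merged_by_genome)
    counts = {g: len(m) for g, m in merged_by_genome.items()}
    sizes = {g.genome_id: g.total_length for g in genomes}
    pearson_r = bgc.count_size_correlation(counts, sizes)
    write_tsv(pd.DataFrame(region_rows), os.path.join(outdir, "regions.tsv"))
    write_tsv(pd.DataFrame(merged_rows), os.path.join(outdir, "merged_clusters.tsv"))
    write_tsv(pd.DataFrame(count_rows), os.path.join(outdir, "expected_counts.tsv"))
    write_tsv(census_df, os.path.join(outdir, "census.tsv"))
    write_tsv(pd.DataFrame(enrich_rows), os.path.join(outdir, "enrichment.tsv"))
    return BGCStageResult(
        regions_by_genome, merged_by_genome, n_categories, pearson_r, enrich_rows
    )


def stage_synteny(
    genomes: Sequence[GenomeAssembly], params: Mapping[str, Any], outdir: str
) -> pd.DataFrame:
    rows = []
    ordered = sorted(genomes, key=lambda g: g.genome_id)
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1 :]:
            anchors = synteny.find_anchors(
                ga,
                gb,
                seed_k=params["seed_k"],
                min_length=params["min_length"],
                min_identity=params["min_identity"],
            )
            blocks = synteny.chain_blocks(anchors, max_gap=params["max_gap"])
            s = synteny.synteny_summary(
                blocks, (ga.genome_id, gb.genome_id), ga.total_length, gb.total_length
            )
            rows.append(
                {
                    "genome_a": s.genome_pair[0],
                    "genome_b": s.genome_pair[1],
                    "coverage_a": s.coverage_a,
                    "coverage_b": s.coverage_b,
                    "weighted_mean_identity": s.weighted_mean_identity,
                    "n_blocks": s.n_blocks,
                }
            )
    df = pd.DataFrame(rows)
    write_tsv(df, os.path.join(outdir, "synteny_summary.tsv"))
    return df


# ---------------------------------------------------------------------------
# Full run

def run_full(config: RunConfig) -> RunReport:
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = config.outdir
    manifest: dict[str, str] = {}
    headline: dict[str, Any] = {}

    stage = "simulate"
    t0 = time.time()
    try:
        genomes, truth = stage_simulate(config)
        if truth is not None:
            manifest["genomes"] = os.path.join(out, "genomes")
            manifest["truth"] = os.path.join(out, "truth")
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "orthology"
        t0 = time.time()
        proteomes = compute_proteomes(genomes)
        orth = stage_orthology(
            genomes, proteomes, config.params["orthology"], out, seed=config.seed
        )
        for name in ("rbh_pairs", "ortholog_groups", "pangenome_summary", "accumulation_curve"):
            manifest[name] = os.path.join(out, f"{name}.tsv")
        headline["pangenome"] = {
            "n_core": orth.partition.n_core,
            "n_dispensable": orth.partition.n_dispensable,
            "n_singleton": orth.partition.n_singleton,
            "n_pan": orth.partition.n_pan,
        }
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "ogri"
        t0 = time.time()
        results = stage_ogri(genomes, proteomes, orth.rbh, config.params["ogri"], out)
        manifest["ogri_matrix"] = os.path.join(out, "ogri_matrix.tsv")
        defined = [r.ani for r in results if r.ani is not None]
        headline["ogri"] = {
            "n_pairs": len(results),
            "ani_min": min(defined) if defined else None,
            "ani_max": max(defined) if defined else None,
        }
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "classify"
        t0 = time.time()
        if truth is not None:
            species = truth.species_labels
            type_strains = sorted(
                {min(g for g in species if species[g] == s) for s in set(species.values())}
            )
        else:
            type_strains = sorted(g.genome_id for g in genomes)[:1]
        calls, assignments = stage_classify(results, type_strains, out)
        manifest["taxonomic_calls"] = os.path.join(out, "taxonomic_calls.tsv")
        manifest["assignments"] = os.path.join(out, "assignments.tsv")
        headline["taxonomy"] = {
            "decisions": sorted({c.decision for c in calls if c.decision}),
            "n_fuzzy": sum(c.fuzzy for c in calls),
            "assignments": assignments,
        }
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "phylogeny"
        t0 = time.time()
        phylo = stage_phylogeny(
            genomes, proteomes, orth.groups, config.params["phylogeny"], out, seed=config.seed
        )
        if phylo.marker_tree is not None:
            manifest["marker_tree"] = os.path.join(out, "marker_tree.nwk")
        manifest["core_tree"] = os.path.join(out, "core_tree.nwk")
        headline["phylogeny"] = {"n_single_copy_core": phylo.n_single_copy_core}
        if truth is not None:
            true_tree = genome_io.tree_from_newick(truth.true_topology)
            if phylo.marker_tree is not None:
                headline["phylogeny"]["rf_marker_vs_truth"] = phylogeny.rf_distance(
                    phylo.marker_tree.tree, true_tree
                )[0]
            headline["phylogeny"]["rf_core_vs_truth"] = phylogeny.rf_distance(
                phylo.core_tree.tree, true_tree
            )[0]
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "bgc"
        t0 = time.time()
        bgc_res = stage_bgc(genomes, orth.partition, orth.groups, config.params["bgc"], out)
        for name in ("regions", "merged_clusters", "expected_counts", "census", "enrichment"):
            manifest[name] = os.path.join(out, f"{name}.tsv")
        with_clusters = [e for e in bgc_res.enrichment if e["n_clusters"]]
        headline["bgc"] = {
            "census": {g: len(m) for g, m in bgc_res.merged_by_genome.items()},
            "n_categories": bgc_res.n_categories,
            "count_size_pearson_r": bgc_res.pearson_r,
            "enrichment_mean_core": float(np.mean([e["frac_core"] for e in with_clusters]))
            if with_clusters
            else None,
            "enrichment_mean_accessory": float(
                np.mean([e["frac_accessory"] for e in with_clusters])
            )
            if with_clusters
            else None,
        }
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)

        stage = "synteny"
        t0 = time.time()
        syn_df = stage_synteny(genomes, config.params["synteny"], out)
        manifest["synteny_summary"] = os.path.join(out, "synteny_summary.tsv")
        headline["synteny"] = {"n_pairs": len(syn_df)}
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    provenance = {
        "seed": config.seed,
        "params": config.params,
        "clade": None if config.clade is None else dataclasses.asdict(config.clade),
    }
    report = RunReport(manifest=manifest, provenance=provenance, headline=headline)
    write_json(report.to_dict(), os.path.join(out, "run_report.json"))
    for path in manifest.values():
        assert os.path.exists(path), f"manifest entry missing: {path}"
    return report
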