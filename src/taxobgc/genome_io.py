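"""Readers and writers for the pipeline's on-disk formats.

This module is the coordinate-convention guardian: every interval held in
memory is 0-based, half-open ``[start, end)``; the GFF3 convention (1-based,
inclusive) exists only at the file boundary.  FASTA, GFF3, newick and the
tab-separated result tables all round-trip losslessly after one
normalization pass (uppercasing of sequence text).
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import skbio
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("taxobgc")

FEATURE_KINDS = ("CDS", "marker_rRNA", "BGC_domain", "BGC_region")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneFeature:
    """One annotated interval on a contig (internal 0-based half-open)."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """A (possibly multi-contig) assembly plus its feature annotation."""

    genome_id: str
    contigs: list[tuple[str, str]]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        lengths = self.contig_lengths()
        for f in self.features:
            if f.contig_id not in lengths:
                raise ValueError(f"feature {f.feature_id} on unknown contig {f.contig_id}")
            if f.end > lengths[f.contig_id]:
                raise ValueError(
                    f"feature {f.feature_id} extends past end of contig {f.contig_id}"
                )

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def gc_fraction(self) -> float:
        gc = sum(seq.count("G") + seq.count("C") for _, seq in self.contigs)
        return gc / self.total_length if self.total_length else 0.0

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def feature_seq(self, feature: GeneFeature) -> str:
        """Strand-aware sequence extraction ('-' returns the reverse complement)."""
        seq = self.contig_seq(feature.contig_id)[feature.start : feature.end]
        return reverse_complement(seq) if feature.strand == "-" else seq

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def cds_protein(self, feature: GeneFeature) -> str:
        nt = self.feature_seq(feature)
        return str(Seq(nt).translate())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` with ids taken as the first
    whitespace-delimited token.  Lowercase input is uppercased (logged);
    duplicate ids and empty sequences are rejected."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq)
        if rid in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rid!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for id {rid!r}")
        if not seq.isupper():
            logger.info("read_fasta: normalized lowercase sequence for %s", rid)
            seq = seq.upper()
        seen.add(rid)
        records.append((rid, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 60) -> None:
    seen: set[str] = set()
    recs = []
    for rid, seq in records:
        if rid in seen:
            raise FormatError(f"duplicate FASTA id {rid!r}")
        if not seq:
            raise FormatError(f"empty sequence for id {rid!r}")
        seen.add(rid)
        recs.append(SeqRecord(Seq(seq.upper()), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def write_gff3(features: Sequence[GeneFeature], path: str | os.PathLike) -> None:
    """Write features 1-based inclusive.  Attribute maps are serialized as
    ``key=value`` pairs with ``ID`` first."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}"]
            attrs += [f"{k}={v}" for k, v in sorted(f.attributes.items())]
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "taxobgc",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise FormatError(f"{path}: missing ##gff-version header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, kind, start_s, end_s, _score, strand, _phase, attr_s = cols
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            attrs: dict[str, str] = {}
            for pair in attr_s.split(";"):
                if pair and "=" in pair:
                    k, v = pair.split("=", 1)
                    attrs[k] = v
            fid = attrs.pop("ID", f"feature_{lineno}")
            features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    kind=kind,
                    attributes=attrs,
                )
            )
    return features


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: skbio.TreeNode, path: str | os.PathLike) -> None:
    """Serialize a tree; support values ride as internal-node names and branch
    lengths are written at full float precision."""
    tree.write(str(path), format="newick")


def read_newick(path: str | os.PathLike) -> skbio.TreeNode:
    try:
        return skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises parse-specific subclasses
        raise FormatError(f"{path}: malformed newick ({exc})") from exc


def newick_str(tree: skbio.TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_from_newick(text: str) -> skbio.TreeNode:
    try:
        return skbio.TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise FormatError(f"malformed newick ({exc})") from exc


# ---------------------------------------------------------------------------
# Tables and run summaries

def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: Mapping, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Assembly-level convenience I/O used throughout the pipeline

def write_assembly(genome: GenomeAssembly, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(genome.contigs, os.path.join(outdir, f"{genome.genome_id}.fna"))
    write_gff3(genome.features, os.path.join(outdir, f"{genome.genome_id}.gff3"))
    prots = [
        (f.feature_id, genome.cds_protein(f))
        for f in genome.features_of_kind("CDS")
    ]
    if prots:
        write_fasta(prots, os.path.join(outdir, f"{genome.genome_id}.faa"))


def read_assembly(genome_id: str, indir: str | os.PathLike) -> GenomeAssembly:
    contigs = read_fasta(os.path.join(indir, f"{genome_id}.fna"))
    features = read_gff3(os.path.join(indir, f"{genome_id}.gff3"))
    return GenomeAssembly(genome_id=genome_id, contigs=contigs, features=features)
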