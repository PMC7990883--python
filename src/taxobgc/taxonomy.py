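"""Threshold-based taxonomic decision engine.

Encodes the standard whole-genome species/genus boundaries used in
prokaryotic taxogenomics: 95% ANI and 70% dDDH for the species rank (both
required jointly), a 79-80% dDDH band for subspecies, 65% AAI for the genus
boundary and 98.65% 16S identity for marker-level species circumscription.
Pairs falling inside the ANI 93-96% / dDDH 60-70% "fuzzy zone" are flagged
rather than forced to a rank, and a synteny-based tie-break can order two
candidate pairs of comparable block coverage by block identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .ogri import PairwiseOGRI

DECISIONS = (
    "same_strain",
    "same_species_same_subspecies",
    "same_species_different_subspecies",
    "different_species",
    "different_genus",
)


@dataclass
class TaxonomyThresholds:
    ssu_species: float = 98.65
    ani_species: float = 95.0
    ddh_species: float = 70.0
    ani_fuzzy: tuple[float, float] = (93.0, 96.0)
    ddh_fuzzy: tuple[float, float] = (60.0, 70.0)
    ddh_subspecies: tuple[float, float] = (79.0, 80.0)
    aai_genus: float = 65.0

    def __post_init__(self) -> None:
        for v in (self.ssu_species, self.ani_species, self.ddh_species, self.aai_genus):
            if not 0 < v <= 100:
                raise ValueError("thresholds must lie in (0, 100]")
        if not self.ani_fuzzy[0] <= self.ani_species <= self.ani_fuzzy[1]:
            raise ValueError("ANI fuzzy interval must contain the species threshold")
        if not self.ddh_fuzzy[0] <= self.ddh_species <= self.ddh_fuzzy[1]:
            raise ValueError("dDDH fuzzy interval must contain the species threshold")


@dataclass
class TaxonomicCall:
    genome_pair: tuple[str, str]
    decision: str | None
    fuzzy: bool
    evidence: dict[str, float | None]
    tiebreak_used: bool = False
    discordant: bool = False
    reduced_confidence: bool = False
    alternatives: tuple[str, ...] = ()


def classify_pair(
    ogri: PairwiseOGRI,
    thresholds: TaxonomyThresholds | None = None,
) -> TaxonomicCall:
    """Rank decision for one genome pair from its relatedness indexes.

    AAI below the genus cutoff wins over everything; otherwise species rank
    requires ANI and dDDH jointly above their thresholds, and within a
    species the dDDH subspecies band (lower bound) separates same- from
    different-subspecies pairs.  Wildly discordant ANI/dDDH (>=99 vs <30)
    yields no decision, only a flag.  A fuzzy-zone hit never changes the
    decision; it flags it and records both boundary readings.
    """
    th = thresholds or TaxonomyThresholds()
    pair = tuple(sorted(ogri.genome_pair))
    evidence = {"ani": ogri.ani, "ddh": ogri.ddh, "aai": ogri.aai}
    ani, ddh, aai = ogri.ani, ogri.ddh, ogri.aai

    if aai is not None and aai < th.aai_genus:
        return TaxonomicCall(pair, "different_genus", False, evidence)

    if ani is None or ddh is None:
        if aai is None:
            return TaxonomicCall(pair, None, False, evidence, discordant=True)
        decision = "different_species" if aai < th.ani_species else "same_species_same_subspecies"
        return TaxonomicCall(pair, decision, False, evidence, reduced_confidence=True)

    if ani >= 99.0 and ddh < 30.0:
        return TaxonomicCall(pair, None, False, evidence, discordant=True)

    fuzzy = (th.ani_fuzzy[0] <= ani <= th.ani_fuzzy[1]) or (
        th.ddh_fuzzy[0] <= ddh <= th.ddh_fuzzy[1]
    )

    if ani == 100.0 and ddh >= 100.0 * (1 - 1e-9):
        return TaxonomicCall(pair, "same_strain", False, evidence)

    if ani >= th.ani_species and ddh >= th.ddh_species:
        if ddh >= th.ddh_subspecies[0]:
            decision = "same_species_same_subspecies"
        else:
            decision = "same_species_different_subspecies"
    else:
        decision = "different_species"

    alternatives: tuple[str, ...] = ()
    if fuzzy:
        # both readings of the boundary: conspecific vs not
        alternatives = ("different_species", "same_species_different_subspecies")
    return TaxonomicCall(pair, decision, fuzzy, evidence, alternatives=alternatives)


def assign_strains(
    calls: Sequence[TaxonomicCall],
    ani_by_pair: Mapping[tuple[str, str], float],
    type_strains: Sequence[str],
    thresholds: TaxonomyThresholds | None = None,
) -> dict[str, str]:
    """Assign each strain to the type strain of maximal ANI among those
    passing the species rule; strains passing none become putative new taxa.
    Exact ANI ties report both labels joined by '|' and are flagged."""
    th = thresholds or TaxonomyThresholds()
    species_pairs = {
        tuple(sorted(c.genome_pair))
        for c in calls
        if c.decision
        in ("same_strain", "same_species_same_subspecies", "same_species_different_subspecies")
    }
    strains = sorted({g for c in calls for g in c.genome_pair})
    out: dict[str, str] = {}
    for s in strains:
        if s in type_strains:
            out[s] = s
            continue
        candidates = []
        for t in type_strains:
            pair = tuple(sorted((s, t)))
            if pair in species_pairs and pair in ani_by_pair:
                candidates.append((ani_by_pair[pair], t))
        if not candidates:
            out[s] = "putative new taxon"
            continue
        best_ani = max(a for a, _ in candidates)
        best = sorted(t for a, t in candidates if a == best_ani)
        out[s] = best[0] if len(best) == 1 else "|".join(best)
    return out


def marker_identity(marker_a: str, marker_b: str) -> float:
    """% identity of two marker (16S-like) genes by global alignment."""
    if not marker_a or not marker_b:
        raise ValueError("marker sequences must be non-empty")
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -4.0
    al.extend_gap_score = -1.0
    alignment = al.align(marker_a, marker_b)[0]
    counts = alignment.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    return 100.0 * counts.identities / cols if cols else 0.0


def synteny_tiebreak(
    fuzzy_pair: Mapping[str, float],
    reference_pair: Mapping[str, float],
    coverage_margin: float = 5.0,
) -> str:
    """Order two candidate pairs by length-weighted block identity.

    Each argument carries ``coverage`` (%, mean of both genome sides) and
    ``identity`` (%, length-weighted).  Coverages differing by more than the
    margin make the comparison invalid ('not comparable'); otherwise the
    higher-identity pair is the within-species/subspecies pair ('fuzzy' /
    'reference').
    """
    cov_f, cov_r = fuzzy_pair["coverage"], reference_pair["coverage"]
    if abs(cov_f - cov_r) > coverage_margin:
        return "not comparable"
    if fuzzy_pair["identity"] >= reference_pair["identity"]:
        return "fuzzy"
    return "reference"
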