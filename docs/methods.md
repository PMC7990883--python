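# Methods

`taxobgc` re-implements, as one tested pipeline, the comparative-genomics
workflow used in prokaryotic taxogenomics surveys: ortholog-based
pan-genome partitioning, overall genome relatedness indexes (OGRI) with a
threshold decision engine, marker-gene and core-genome phylogenies,
synteny summaries, and the curation of biosynthetic gene clusters (BGCs)
fragmented across draft-assembly contigs. Every stage runs against a
synthetic clade generator that records ground truth, so each method's
output can be compared to what was planted.

## Synthetic clades (`synthetic_data`)

Genomes are built from an ordered list of sequence segments (intergenic
spacers, protein-coding genes, one rRNA-like marker, planted BGCs) laid out
on a root genome and evolved down a user-specified clade tree.

Evolution is Jukes-Cantor and indel-free by default: each site mutates
independently with probability `(3/4)(1 - exp(-4d/3))` for branch length
`d` (expected substitutions/site), to one of the three alternative bases
chosen uniformly. Indel-free evolution keeps homologous sequences
positionally aligned, which makes alignments exact, lets protein blocks be
concatenated without an aligner, and lets the generator report exact
realized identities per genome pair (the oracle for ANI/dDDH recovery).
An `indels_enabled` flag exists but is off in every study condition here;
with it on, concatenation falls back to explicit alignment and positional
oracles no longer apply.

Gene content structure: `n_core_genes` present in every genome;
`n_dispensable_genes` present per genome with probability
`dispensable_presence_prob` (draws realized once; a gene realized in all
genomes is *classified* core in the truth table, one realized in a single
genome is a singleton — truth reflects realized structure, not intent);
`n_singletons_per_genome` i.i.d. random genes that can never form
reciprocal best hits (clean negative controls). Genes are random sense
codons at a configurable GC fraction (default 0.68, matching
high-GC actinobacteria); the marker gene (default 1,500 nt) evolves at a
0.5 rate multiplier to emulate 16S conservatism.

Planted BGCs follow templates (PKS = KS domains only, NRPS = C only,
hybrid = both). Domain sequences descend from two fixed family consensus
sequences (seeded independently of the clade so detection profiles share
ancestry with plants): per-cluster variants at `inter_cluster_divergence`
(default 0.15) and per-domain instances at `intra_cluster_divergence`
(default 0.01). Clusters are preceded by a 25 kb background spacer
(`bgc_separation_nt`) so distinct clusters can never be chained into one
region by the 20 kb hit-gap rule. Optional interior filler genes
(accessory) and core genes (placed inside the cluster for carriers, at a
separate locus for non-carriers, same ortholog group) make core/accessory
span fractions controllable.

Fragmentation cuts a genome into contigs either uniformly at random
(never inside a gene/marker/domain feature) or at planted split positions
inside a cluster's inter-domain spacers (`midpoint`, a gap index, or
`all`). Concatenating the contigs reproduces the unfragmented genome
exactly; region features crossing a cut are split into boundary-touching
pieces and the truth table maps every piece to its cluster.

Seeding: one master seed; every stochastic step derives
`SeedSequence(master, spawn_key=(crc32(key), node_index))` from stable
string keys, so any genome or segment regenerates identically in
isolation.

Scale of the default study conditions: 5 genomes with ~100-170 genes
(~100-150 kb) rather than 19 genomes with ~4,000 genes. All structure
types of the real data (two species, subspecies-level pairs, dispensable
and strain-specific genes, a cluster split across contigs) are present at
this scale; runtimes stay in seconds-to-minutes on one CPU.

What the generator does **not** emulate: realistic codon usage and amino
acid composition, recombination/HGT, rearrangements beyond single planted
inversions, sequencing error, and the rule-based cluster-type ontology of
real annotation tools. Passing tests therefore demonstrate correctness of
the *post-processing logic* under the stated model, not performance on
real assemblies.

## Orthology and pan-genome (`orthology`)

All-vs-all protein comparison uses global Needleman-Wunsch alignment
(affine gaps: match 2 / mismatch −1 / open −4 / extend −1) with identity
computed over aligned columns excluding end gaps and coverage =
aligned-columns / shorter-sequence length. Candidates are restricted to
pairs sharing at least one exact protein 5-mer; on fixtures of ≤ 50
genes/genome this prefilter is verified equivalent to scoring every pair.
The best hit is selected by alignment score; the identity (default 0.4)
and coverage (default 0.5) floors are then checked on that best hit. Exact
score ties are dropped (ties come from duplicates, which violate 1:1
orthology) and logged. Ortholog groups are connected components of the
reciprocal-best-hit graph; single-copy core additionally requires exactly
one member per genome. The partition (core / dispensable / singleton)
satisfies `n_pan = n_core + n_dispensable + n_singleton` by construction
and is checked on every run.

Accumulation curves average pan and core cluster counts over random genome
orderings (default 100 permutations) and fit `a·n^b + c` (pan) and
`a·exp(-n/b) + c` (core) by least squares. The core family is exponential
decay because a power law cannot decrease to an asymptote.

## Genome relatedness indexes (`ogri`)

ANI is fragment-based: each genome is cut into non-overlapping 1,020 nt
windows (trailing remainder discarded). Fragment pairing is reciprocal
best by semi-global (infix) edit distance of each fragment inside the mate
fragment's window extended by one fragment length on each side — the
extension absorbs coordinate shifts caused by gene presence/absence
differences. Final identity per pair comes from an affine-gap glocal
alignment (match 1 / mismatch −3 / open −7 / extend −0.75; window end gaps
free) counted over match+mismatch columns only: indel columns, which on
draft-like genomes mostly reflect gene content rather than nucleotide
divergence, are excluded the way local-alignment (HSP) identities exclude
them. The gap costs are set so that substitution runs are never absorbed
as spurious micro-indels (a run must exceed ~9 mismatches before gapping
pays, essentially impossible below 25% divergence) while genuinely
non-homologous runs ≥ ~100 nt are gapped out. Alignments must cover ≥ 35%
of the fragment. Measured recovery on colinear clades: |ANI/100 −
realized identity| ≤ 4·10⁻⁴ for divergence 0.01-0.15.

The dDDH-style distance is `d2 = 1 − Σ identities / Σ aligned columns`
over the same fragment pairs, converted to a percent hybridization value
by a logistic curve `ddh = 100 / (1 + exp((d2 − d₀)/s))`. The published
genome-to-genome regression coefficients are not available here, so the
curve is a **surrogate** calibrated through two anchors: (0.05, 70%) — so
that the ANI-95%/dDDH-70% species boundaries coincide — and (0.158,
27.8%), a worked between-genus pair. Every output row carries the label
`surrogate-logistic`; absolute dDDH values are comparable across runs of
this package but not to the web-service values.

AAI is the mean protein identity over reciprocal best hit pairs.
All pairwise indexes are computed once per unordered pair; symmetry is by
construction. Undetectable pairs (no surviving fragment pairs / no RBH)
return flagged `None`, never a number.

## Taxonomic decisions (`taxonomy`)

Thresholds (all configurable): 16S 98.65%, ANI 95%, dDDH 70% (species,
jointly required), dDDH 79-80% band (subspecies; the 79% lower bound is
used), AAI 65% (genus), fuzzy zones ANI 93-96% and dDDH 60-70%. Decision
order: AAI below genus cutoff → different genus; ANI and dDDH both above
species thresholds → same species (then the dDDH subspecies bound splits
same/different subspecies); otherwise different species; ANI = dDDH =
100 → same strain. Discordant evidence (ANI ≥ 99 with dDDH < 30) yields
no decision, only a flag. A fuzzy-zone hit never changes the decision: it
flags the call, records both boundary readings, and marks the pair for
the synteny tie-break, which orders two candidate pairs of comparable
block coverage (± 5 percentage points) by length-weighted block identity
— and can therefore leave a rank genuinely open ("not comparable").
Strains are assigned to the type strain of maximal ANI among those
passing the species rule; none passing → "putative new taxon"; exact ANI
ties report every candidate.

## Phylogenies (`phylogeny`)

Distances: Jukes-Cantor `d = −(3/4)·ln(1 − 4p/3)` on gap-excluded
columns, with an explicit saturation error at p ≥ 0.75; protein
supermatrices use uncorrected p-distance by default. Neighbor joining is
implemented deterministically: Q-criterion ties break by the smallest
label-index pair, negative branch lengths clamp to zero (deficit logged).
Supports come from column-resampling bootstrap (default 1,000 replicates,
seeded): support = % of replicates containing each original bipartition;
bipartitions attach to internal edges, not nodes, and a zero-length
internal edge counts as unresolved (a star tree has no supported
bipartitions). Robinson-Foulds distance is the symmetric difference of
non-trivial bipartitions, normalized by 2(n−3). Tree search by parsimony
or likelihood is deliberately out of scope; congruence between the marker
tree and the concatenated single-copy-core tree is assessed with NJ on
both sides.

## BGC curation (`bgc`)

Domain detection scores both strands against per-type position weight
matrices built from seed alignments (log-odds vs uniform background,
pseudocount 1); overlapping same-type hits keep the best score. The
default threshold (100 bits) sits far above the background score of
random sequence (strongly negative) and far below a true hit's score
(~300-800 bits for a 450 nt domain at ≤ 25% divergence). Annotated
`BGC_domain` features can bypass scanning entirely (user-supplied tables).

Same-contig hits within 20 kb chain into a region; the region interval is
the hull of its hits ± 5 kb, clipped to the contig; category follows the
domain multiset (KS-only → PKS, C-only → NRPS, both → hybrid). A region
is *complete* iff sequence exists strictly before and after it on its
contig (0 nt tolerance by default, configurable), else *partial*.

Merging reconnects clusters split by assembly fragmentation. Per domain
type, an NJ tree of the domain sequences (JC distances; positional
comparison when indel-free) is built. Under the default **cherry** rule,
two partial regions of one genome on different contigs merge when a
domain of one is a sister leaf of a domain of the other; with exactly
three domains the unrooted tree is a star and the distance-closest pair
is the cherry; merging is transitively closed; complete regions always
stay singletons, and a sister link to a complete region is logged as an
anomaly and ignored. The cherry rule cannot reconnect a cluster split so
that every fragment keeps one domain across ≥ 3 contigs (no cherry
exists); the **clade** mode handles this by accepting unrooted tree sides
whose tips are exactly the domains of ≥ 2 partial regions on pairwise
distinct contigs *and* whose internal diameter is below half the minimal
distance to all remaining domains — the operating regime of the whole
heuristic (fragments of one cluster near-identical relative to other
clusters). Outside that regime merging fails visibly (counts differ from
truth), never silently. Hybrid clusters may absorb PKS/NRPS partials;
the merged category is recomputed from the union of domains.

The expected cluster count per category is
`Σ lengths(all regions) / mean(lengths(complete regions))`, flagged
undefined when no complete region exists; it is ≥ the number of complete
regions by construction and exact when all planted clusters share one
length. The census counts merged clusters per genome and category.
Core/accessory span: per cluster, the union of core-gene CDS positions
(and separately accessory = dispensable + singleton) intersected with the
cluster interval, divided by cluster length; genome value = mean over its
clusters; matching is by annotated coordinates (an alignment-based mode
locating CDS sequences inside the cluster is available through the same
interface). Count-size association is the Pearson product-moment
correlation, undefined below 3 genomes or at zero variance.

## Synteny (`synteny`)

Anchors are exact 15-mer seeds extended ungapped with an x-drop rule
(match +1 / mismatch −3 / drop 50) on each diagonal, per strand, filtered
at ≥ 500 bp and ≥ 90% identity (the deterministic replacement for an
e-value cutoff, whose search-space constants are not reproducible; an
approximate e-value is reported for information only). Overlapping
anchors keep the longer. Blocks are maximal chains of anchors monotone on
both genomes with gaps ≤ 25 kb (total-anchor-length DP), split wherever a
gap contains another anchor (so an inverted segment separates the
flanking collinear runs into distinct blocks). Summaries report per-side
coverage (interval union / genome length) and length-weighted mean anchor
identity — the two numbers the taxonomic tie-break consumes.

## Pipeline (`pipeline`, CLI `taxobgc`)

Stages run in order simulate → orthology → ogri → classify → phylogeny →
bgc → synteny → report; each writes its TSVs before the next starts, so a
failure leaves completed outputs intact and names the failing stage.
Configuration is YAML with every default equal to the values above; every
CLI flag overrides it; the whole run is deterministic given the master
seed (verified byte-identical TSVs). Exit codes: 0 ok / 1 stage failure /
2 config error.

## Numerical and design notes

- Internal coordinates are 0-based half-open everywhere; 1-based inclusive
  only in GFF3 files. Strand-aware extraction reverse-complements "−".
- Translation of evolved CDSs can contain stop codons introduced by
  substitutions; they are kept as `*` characters and simply act as
  mismatches in protein alignments.
- The RBH score-tie rule (drop) makes orthology conservative; random
  decoy ties only ever involve genes with no true ortholog.
- Degenerate inputs are flagged, not guessed: undefined ANI/AAI, undefined
  expected counts, undefined correlation, saturation in JC, "not
  comparable" in the synteny tie-break.
- Known limitations: the dDDH transform is a surrogate (see above); ANI on
  genomes with heavy content turnover is accurate to ~2·10⁻³ rather than
  4·10⁻⁴; profile detection assumes the planted domain families; the
  clade merge rule's separation margin (0.5) is a heuristic constant and
  is configurable only in source.
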