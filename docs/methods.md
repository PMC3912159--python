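# Methods

## The model

A gene structure is an ordered list of exons over a named genomic sequence.
Coordinates are 0-based half-open; GFF3 I/O converts from 1-based closed.
Each exon carries two codon phases: `phase_in`, the offset of its first
base within its codon (0 = codon start), and
`phase_out = (phase_in + length) mod 3`.  This is the complement of the
GFF3 phase column (`phase_in = (3 - gff_phase) mod 3`), chosen so that the
phase chain across the reference transcript is a simple equality
(`phase_out(i) == phase_in(i+1)`).  Minus-strand genes are stored in
transcription order so exon index 0 is always 5'; genomic coordinates are
untouched.  MXE clusters are recorded in a YAML sidecar (GFF3 has no MXE
vocabulary): per cluster, the member exon indices, the annotated variant,
and per-variant similarity scores.

### Similarity score

The detector thresholds on a similarity fraction

    s(a, b) = pos(a, b) / max(|a|, |b|)

where `pos` is the number of aligned columns with a positive BLOSUM62
entry in a global alignment with affine gap costs (open 11, extend 1; a
gap of length k costs 11 + k).  Because several alignments can share the
optimal alignment score while differing in positive-column count, the DP
maximises the pair (alignment score, positive columns) lexicographically;
the score is therefore deterministic and symmetric.  The original survey's
detection tool defines its own score, which its publication does not
specify; this package's definition is a documented stand-in that keeps the
published parameter values (minimal score 15%, length difference 20 aa,
minimal exon length 10 aa) as defaults.

A property worth knowing: under optimal realignment even unrelated
exon-sized sequences score ~0.25 on average (≈86% of random 20-mer pairs
clear 15%; the test suite records this false-positive rate).  The 15%
threshold is therefore only meaningful in combination with the splice
context, frame, stop-freedom, and length constraints, which is exactly how
the detector applies it.

### Candidate enumeration

For each internal anchor exon, both flanking introns are scanned
(`internal_and_surrounding`; `internal_only` restricts to introns whose
other side is also internal — candidates upstream of exon 1 are never
considered).  Acceptor positions (`AG` ending at i, ≥4 nt of residual
intron 5' of it) are paired with donor positions (`GT` starting at j, ≥4 nt
residual 3') such that the enclosed length is frame-compatible with the
anchor; the enclosed window must translate stop-free — also across the
junction codons when substituted for the anchor in the full transcript —
and reach the similarity threshold.  Overlapping candidates are resolved
greedily by score; ties prefer the candidate whose length is closest to
the anchor's, then the more 5' one.  Deduplicated candidates merge with
their anchor into clusters ordered 5'→3'.

### Intron projection and conservation

Introns of the reference transcript (annotated variant per cluster) are
mapped to the MSA column of the codon they interrupt plus the within-codon
phase.  A phase-0 intron between codons is assigned to the *following*
column (the projection tool the survey used leaves this convention
undocumented; this package fixes and documents it).  Conservation groups
are exact (column, phase) equalities, so an intron shifted by 1 bp in one
lineage — the situation reported for the intron after cluster-6 in
arthropods — splits into two groups.  Ambiguously aligned regions are not
special-cased; a column mask can be applied by filtering the report.

### Canonical labelling

Canonical clusters are defined by anchor column intervals on a reference
alignment.  The original clusters are defined on a curated myosin
alignment that is not redistributable, so the packaged anchor fixture
(`synthetic_reference_anchors.yaml`, labelled synthetic) carries intervals
on the package's own reference architecture; real anchors can be swapped
in via the same YAML schema.  A cluster is labelled with the anchor of
maximal fractional overlap when that fraction reaches 0.5 (configurable);
each anchor claims at most one cluster per gene (highest overlap wins,
losers are flagged for review); everything else becomes `novel-k`, ordered
N→C.  Species presence is the union over the species' genes; a cell is
`unknown` only where an assembly-gap annotation covers the anchor and no
gene shows the cluster.

### Dollo parsimony

Per cluster: the gain is placed at the LCA of all `present` leaves
(present in two species ⇒ present in their last common ancestor); the
loss set is {edges (u, v) below the gain : u's subtree contains a carrier,
v's does not, and v's subtree contains at least one `absent` leaf}.  This
set is minimal — verified against exhaustive enumeration in the tests —
and treats `unknown` as missing data.  When an all-unknown subtree hangs
off a loss path, an equally small placement one edge lower exists; the
topmost edge is this package's deterministic convention (placement ties
are impossible only in matrices without unknowns).  `count_events`
reports events *at* a named node by default (the convention in which "five
clusters gained at the Protostomia LCA" is a statement about one node),
with an `include_descendants` option for clade totals.

## Synthetic data: what it emulates, and what not

The generators stand in for the 116 genome assemblies behind the original
survey, which require manual curation and are not reproducible at desk
scale.

**Gene architecture defaults** (chosen once, as the study conditions):
9 exons of 15–30 aa, introns 20–36 nt, variant-hosting pad introns
8–14 nt, 2-variant clusters at similarity 0.6 (3-variant at 0.8 in the
benchmark mix), matching the compact invertebrate gene architecture of the
arthropod and lophotrochozoan *Mhc* genes and the high conservation of
real MXE pairs.  A plain 36-nt intron cannot host a ≥10-aa reading frame
between splice dinucleotides, so the planted variants are the only true
positives by construction and the recall/precision suite measures the
thresholds, not background noise.

**Planted-truth identifiability.**  Three generator choices ensure the
planted coordinates are the unique correct answer rather than one of
several equally good readings: (i) intron sequence inside a variant-hosting
gap is drawn without G, so the designed `GT`/`AG` are its only splice
contexts; (ii) a variant's edge residues stay identical to the anchor; and
(iii) each variant is verified to outscore every alternative
splice-context sub-window of itself, redrawing mutations/codons otherwise.
Without (iii), roughly 1 in 400 plants at similarity 0.6 admits an
in-frame truncation that realigns to a strictly higher score — a real
property of the score's alignment background, documented rather than
hidden: near the 15% threshold (similarity ≲ 0.35) detection boundaries
and anchor association become genuinely ambiguous, and exact-coordinate
recovery claims are not made there.

**Divergence control.**  Variants are derived from the anchor by replacing
interior residues with non-positive BLOSUM62 partners, re-measuring after
each step until the score enters the ±0.05 band around the target; targets
below the ~0.25 alignment background fall back to rejection-sampling
random sequences.  Requested-vs-measured mean absolute error is ≤0.05
over 100 genes (tested).  Targets above `L_a / (L_a + Δ)` for a large
positive length delta Δ are infeasible and raise an error.

**Homolog families** evolve an ancestor gene down a tree with per-branch
residue substitution (default 0.02/site), Bernoulli intron loss, and
optional ±1-nt intron shifts.  Exon interiors accumulate substitutions
only — no indels — so the true MSA is ungapped and no aligner is involved.

**Not emulated:** realistic codon usage and GC content, branch-point and
poly-pyrimidine splice signals, indels in exons, alignment uncertainty,
multi-gene families per species (except as separate inputs), assembly
errors.  Passing tests therefore demonstrate correctness of the
computational chain on identifiable inputs, not detection performance on
real genomes, where near-threshold ambiguity, exon fusion, and annotation
error dominate.

## The packaged survey fixture

`mhc_cluster_inventory.tsv` encodes only per-species cluster sets stated
in the survey's Results text (25 species); `metazoa_mhc_tree.nwk` follows
the clade structure named there (Lophotrochozoa with Platyhelminthes
sister to Annelida+Mollusca; Ecdysozoa with the nematode sister to the
arthropods; chelicerate, myriapod, crustacean and insect branches).  Both
are data, swappable via TSV/Newick inputs.  On this fixture the
reconstruction places cluster-8 at the bilaterian root, clusters 2, 5, 6,
9, 11 at the Protostomia LCA, clusters 1, 7, 10 at the arthropod LCA,
cluster-3 at the annelid+mollusc LCA, cluster-4 on the *Capitella* branch
and cluster-0 on the ctenophore branch — the numbers the acceptance script
recomputes.

## Numerical and procedural choices

- Alignment DP packs (score, positives) into one integer
  (`score * 4096 + positives`); exact for the integer BLOSUM62/gap costs
  and positive counts < 4096.
- Adjacent insertion/deletion gaps are not allowed to abut (standard
  Gotoh); with BLOSUM62's minimum of −4 against a gap-pair cost of −24
  this never changes the optimum.
- Splice dialect defaults to GT–AG; GC–AG and AT–AC can be enabled.
- Detection output ordering, cluster numbering, and report rendering are
  deterministic; pipeline tables embed the package version, a
  configuration hash (excluding the output directory), and the seed, and
  identical configurations reproduce byte-identical reports.
- Degenerate inputs: genes need ≥1 exon (intronless genes map zero intron
  positions); clusters with zero carriers are skipped with a warning;
  all-unknown matrices reconstruct to nothing; empty GFF3 yields an empty
  gene list.

## Problem sizes

The test suite and acceptance script run the detection benchmark on 200
genes (600 planted variants), the Dollo-vs-oracle comparison on 500
scenario clusters over trees of ≤12 leaves (the exhaustive oracle's
practical range), 100 similarity oracle pairs, 20 homolog families, and
~100 planted event histories; together they complete in well under five
minutes on a single CPU.
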