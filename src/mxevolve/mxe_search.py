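"""Detection of mutually exclusive exon (MXE) candidates and clusters.

Candidate MXEs are unannotated exons hidden in the introns flanking an
annotated exon (the *anchor*).  A candidate must

* be bounded by an acceptor dinucleotide immediately 5' and a donor
  dinucleotide immediately 3' (GT..AG dialect by default), leaving at least
  4 nt of residual intron on each side;
* share both codon phases with its anchor (reading-frame conservation);
* translate without internal stop codons, also across the junction codons
  when substituted for the anchor;
* be at least ``min_exon_length_aa`` long and within
  ``max_length_difference_aa`` of the anchor's length;
* score at least ``min_score`` against the anchor's translation.

Defaults mirror the search settings used for the myosin heavy chain survey:
length difference 20 aa, minimal score 15%, minimal exon length 10 aa,
search over internal anchors and their surrounding introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import SearchError
from .gene_model import (
    DEFAULT_DIALECT,
    ExonLocus,
    GeneStructure,
    MXECluster,
    SequenceRecord,
    exon_nt,
    genomic_slice,
    translate_cds,
)
from .similarity import score_exon_similarity

MIN_RESIDUAL_INTRON_NT = 4  # splice sites need at least a donor + acceptor


@dataclass(frozen=True)
class SearchParameters:
    min_exon_length_aa: int = 10
    max_length_difference_aa: int = 20
    min_score: float = 0.15
    search_scope: str = "internal_and_surrounding"  # or "internal_only"
    splice_dialect: frozenset = DEFAULT_DIALECT

    def __post_init__(self):
        if self.min_exon_length_aa < 1:
            raise SearchError("min_exon_length_aa must be >= 1")
        if not (0 < self.min_score <= 1):
            raise SearchError("min_score must be in (0, 1]")
        if self.search_scope not in ("internal_only", "internal_and_surrounding"):
            raise SearchError(f"unknown search_scope {self.search_scope!r}")


@dataclass(frozen=True)
class MXECandidate:
    anchor_exon_index: int
    start: int
    end: int
    score: float
    length_aa: int
    phase_in: int
    phase_out: int
    side: str  # upstream_intron | downstream_intron

    def as_locus(self) -> ExonLocus:
        return ExonLocus(start=self.start, end=self.end, phase_in=self.phase_in,
                         phase_out=self.phase_out, role="mxe_variant")


@dataclass
class TranscriptEvidence:
    transcript_id: str
    #: exon indices (into the gene's exon list) covered by this transcript
    exon_indices: list[int] = field(default_factory=list)


def _translate(core: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(core).translate())


def exon_translation(gene: GeneStructure, genome: SequenceRecord,
                     exon: ExonLocus) -> str:
    """Translation of the complete codons inside one exon."""
    nt = exon_nt(genome, gene, exon)
    core = nt[exon.lead_nt: exon.lead_nt + 3 * exon.aa_len]
    return _translate(core.upper()) if core else ""


def _substituted_translation_ok(gene: GeneStructure, genome: SequenceRecord,
                                anchor_idx: int, cand_nt: str) -> bool:
    """True iff replacing the anchor exon's sequence by ``cand_nt`` yields a
    stop-free transcript translation (terminal stop allowed)."""
    idx = gene.reference_exon_indices()
    parts = []
    for i in idx:
        parts.append(cand_nt if i == anchor_idx else
                     exon_nt(genome, gene, gene.exons[i]))
    cds = "".join(parts)
    if len(cds) % 3 != 0:
        return False
    res = translate_cds(cds, seq_id="probe")
    return not res.internal_stop_codons


def find_mxe_candidates(
    gene: GeneStructure,
    genome: SequenceRecord,
    params: SearchParameters = SearchParameters(),
) -> list[MXECandidate]:
    """Scan the introns flanking each in-scope anchor exon for MXE candidates.

    Output is deterministic, ordered by genomic start then end.
    """
    if genome.id != gene.sequence_id:
        raise SearchError(
            f"gene {gene.gene_id} is on {gene.sequence_id!r}, genome is "
            f"{genome.id!r}"
        )
    donors = {d for d, _ in params.splice_dialect}
    acceptors = {a for _, a in params.splice_dialect}
    n = len(gene.exons)
    existing_variants = gene.variant_exon_set()
    candidates: list[MXECandidate] = []

    for anchor_idx in range(1, n - 1):
        anchor = gene.exons[anchor_idx]
        if anchor.role != "constitutive" or anchor_idx in existing_variants:
            continue
        anchor_aa = exon_translation(gene, genome, anchor)
        if not anchor_aa or "*" in anchor_aa:
            continue
        for side, nbr in (("upstream_intron", anchor_idx - 1),
                          ("downstream_intron", anchor_idx + 1)):
            nbr_internal = 0 < nbr < n - 1
            if params.search_scope == "internal_only" and not nbr_internal:
                continue
            # intron between anchor and neighbour, transcription orientation
            first, second = (nbr, anchor_idx) if side == "upstream_intron" \
                else (anchor_idx, nbr)
            e5, e3 = gene.exons[first], gene.exons[second]
            if gene.strand == "+":
                lo, hi = e5.end, e3.start
            else:
                lo, hi = e3.end, e5.start
            if hi - lo < 2 * MIN_RESIDUAL_INTRON_NT + 3 * params.min_exon_length_aa:
                continue
            intron = genomic_slice(genome, gene, lo, hi).upper()
            found = _scan_intron(intron, anchor, anchor_aa, params,
                                 donors, acceptors)
            for (i, j, score, aa_len) in found:
                # map intron-local [i, j) back to genomic coordinates
                if gene.strand == "+":
                    g_start, g_end = lo + i, lo + j
                else:
                    g_start, g_end = hi - j, hi - i
                cand_nt = intron[i:j]
                if not _substituted_translation_ok(gene, genome, anchor_idx,
                                                   cand_nt):
                    continue
                candidates.append(MXECandidate(
                    anchor_exon_index=anchor_idx, start=g_start, end=g_end,
                    score=score, length_aa=aa_len,
                    phase_in=anchor.phase_in, phase_out=anchor.phase_out,
                    side=side,
                ))
    candidates.sort(key=lambda c: (c.start, c.end, c.anchor_exon_index))
    return candidates


def _scan_intron(intron: str, anchor: ExonLocus, anchor_aa: str,
                 params: SearchParameters,
                 donors: set[str], acceptors: set[str]) -> list[tuple]:
    """Enumerate acceptor..donor-bounded windows in ``intron`` compatible
    with the anchor's frame and the length constraints."""
    lead, trail = anchor.lead_nt, anchor.phase_out
    lo_aa = max(params.min_exon_length_aa,
                anchor.aa_len - params.max_length_difference_aa)
    hi_aa = anchor.aa_len + params.max_length_difference_aa
    L = len(intron)
    acceptor_pos = [i for i in range(MIN_RESIDUAL_INTRON_NT, L)
                    if intron[i - 2:i] in acceptors]
    donor_pos = {j for j in range(0, L - MIN_RESIDUAL_INTRON_NT + 1)
                 if intron[j:j + 2] in donors}
    out = []
    for i in acceptor_pos:
        for aa_len in range(lo_aa, hi_aa + 1):
            cand_len = lead + 3 * aa_len + trail
            j = i + cand_len
            if j > L - MIN_RESIDUAL_INTRON_NT:
                break
            if j not in donor_pos:
                continue
            core = intron[i + lead: i + lead + 3 * aa_len]
            aa = _translate(core)
            if "*" in aa:
                continue
            score = score_exon_similarity(aa, anchor_aa)
            if score < params.min_score:
                continue
            out.append((i, j, score, aa_len))
    return out


@dataclass
class DetectedCluster:
    """Grouped MXE cluster prior to integration into a GeneStructure."""

    anchor_exon_index: int
    variants: list[ExonLocus]       # 5'->3', including the anchor exon
    scores: list[float]             # vs the annotated (anchor) variant
    flanking: tuple[int, int]       # constitutive exon indices in the input gene


def group_into_clusters(
    candidates: list[MXECandidate],
    gene: GeneStructure,
) -> list[DetectedCluster]:
    """Merge candidates with their anchor exons into MXE clusters.

    Candidates sharing an anchor's inter-constitutive interval join that
    anchor; overlapping candidates are resolved greedily by score (ties to
    the more 5' candidate).  Variants are returned 5'->3'.
    """
    for c in candidates:
        a = gene.exons[c.anchor_exon_index]
        if (c.phase_in, c.phase_out) != (a.phase_in, a.phase_out):
            raise SearchError(
                f"candidate [{c.start},{c.end}) phases differ from anchor "
                f"exon {c.anchor_exon_index}; rejected"
            )

    # deduplicate identical genomic windows across anchors: keep best score
    by_coord: dict[tuple[int, int], MXECandidate] = {}
    for c in candidates:
        key = (c.start, c.end)
        if key not in by_coord or c.score > by_coord[key].score:
            by_coord[key] = c
    pool = sorted(by_coord.values(), key=lambda c: (c.start, c.end))

    # greedy overlap resolution: by descending score; ties prefer the
    # length closest to the anchor, then the more 5' candidate
    def five_prime_rank(c: MXECandidate) -> int:
        return c.start if gene.strand == "+" else -c.end

    def tie_key(c: MXECandidate):
        anchor_aa = gene.exons[c.anchor_exon_index].aa_len
        return (-c.score, abs(c.length_aa - anchor_aa), five_prime_rank(c),
                c.end - c.start)

    kept: list[MXECandidate] = []
    for c in sorted(pool, key=tie_key):
        if all(c.end <= k.start or c.start >= k.end for k in kept):
            kept.append(c)

    by_anchor: dict[int, list[MXECandidate]] = {}
    for c in kept:
        by_anchor.setdefault(c.anchor_exon_index, []).append(c)

    clusters = []
    for anchor_idx in sorted(by_anchor):
        group = by_anchor[anchor_idx]
        anchor = gene.exons[anchor_idx]
        loci = [(anchor, 1.0)] + [(c.as_locus(), c.score) for c in group]
        # transcription order 5'->3'
        loci.sort(key=lambda t: t[0].start, reverse=(gene.strand == "-"))
        flank_lo = anchor_idx - 1
        flank_hi = anchor_idx + 1
        clusters.append(DetectedCluster(
            anchor_exon_index=anchor_idx,
            variants=[l for l, _ in loci],
            scores=[s for _, s in loci],
            flanking=(flank_lo, flank_hi),
        ))
    clusters.sort(key=lambda cl: cl.anchor_exon_index)
    return clusters


def annotate_clusters(gene: GeneStructure,
                      clusters: list[DetectedCluster]) -> GeneStructure:
    """Return a new GeneStructure with detected variants inserted as exons
    and ``clusters`` populated (annotated variant = the original anchor)."""
    loci: list[tuple[ExonLocus, int | None, float]] = [
        (e, None, 1.0) for e in gene.exons
    ]
    for k, cl in enumerate(clusters):
        anchor = gene.exons[cl.anchor_exon_index]
        for v, s in zip(cl.variants, cl.scores):
            if (v.start, v.end) == (anchor.start, anchor.end):
                continue
            loci.append((v, k, s))
    # transcription order
    loci.sort(key=lambda t: t[0].start, reverse=(gene.strand == "-"))
    new_exons = []
    membership: dict[int, list[int]] = {k: [] for k in range(len(clusters))}
    anchors_new: dict[int, int] = {}
    scores: dict[int, list[float]] = {k: [] for k in range(len(clusters))}
    anchor_coords = {
        (gene.exons[cl.anchor_exon_index].start,
         gene.exons[cl.anchor_exon_index].end): k
        for k, cl in enumerate(clusters)
    }
    for new_idx, (locus, k, s) in enumerate(loci):
        coord = (locus.start, locus.end)
        if coord in anchor_coords:
            k = anchor_coords[coord]
            anchors_new[k] = new_idx
            locus = replace(locus, role="mxe_variant")
        if k is not None:
            membership[k].append(new_idx)
            scores[k].append(s)
        new_exons.append(locus)
    new_clusters = []
    for k in sorted(membership):
        if len(membership[k]) < 2:
            continue
        new_clusters.append(MXECluster(
            cluster_index_in_gene=len(new_clusters),
            variant_indices=membership[k],
            annotated_index=anchors_new[k],
            scores=scores[k],
            flanking=(min(membership[k]) - 1, max(membership[k]) + 1),
        ))
    return GeneStructure(
        gene_id=gene.gene_id, species=gene.species,
        sequence_id=gene.sequence_id, strand=gene.strand,
        exons=new_exons, clusters=new_clusters,
    )


def check_transcript_consistency(
    gene: GeneStructure,
    evidence: list[TranscriptEvidence],
) -> dict[int, dict]:
    """Per-cluster confirmation status from transcript/EST evidence.

    A cluster is ``confirmed`` iff every transcript covering it includes
    exactly one of its variants; transcripts containing two or more variants
    are listed as violations; clusters with no covering evidence are
    ``unconfirmed``.
    """
    n = len(gene.exons)
    status: dict[int, dict] = {}
    for cl in gene.clusters:
        vset = set(cl.variant_indices)
        covering = 0
        violations = []
        errors = []
        for ev in evidence:
            bad = [i for i in ev.exon_indices if not (0 <= i < n)]
            if bad:
                errors.append(f"transcript {ev.transcript_id}: unknown exon "
                              f"indices {bad}")
                continue
            hit = vset & set(ev.exon_indices)
            if not hit:
                continue
            covering += 1
            if len(hit) > 1:
                violations.append(
                    {"transcript": ev.transcript_id,
                     "variants": sorted(hit)})
        if violations:
            state = "violated"
        elif covering >= 2:
            state = "confirmed"
        elif covering == 1:
            state = "partially_confirmed"
        else:
            state = "unconfirmed"
        status[cl.cluster_index_in_gene] = {
            "status": state, "covering_transcripts": covering,
            "violations": violations, "errors": errors,
        }
    return status
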