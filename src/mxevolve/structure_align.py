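"""Gene-structure alignment: project intron positions onto a protein MSA.

Two introns from different genes are *conserved at the nucleotide level*
when they interrupt homologous codons at the same within-codon offset,
i.e. when their (MSA column, phase) pairs are equal.  Phase 0 means the
intron falls between codons; such an intron is assigned to the column of
the *following* codon.  Comparing phase explicitly (rather than rounding
to amino-acid positions) is what distinguishes a truly shared intron from
one shifted by a single base, which splits into two (column, phase) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import AlignmentError
from .gene_model import GeneStructure, SequenceRecord, translate_gene

GAP = "-"


@dataclass(frozen=True)
class IntronPosition:
    gene_id: str
    alignment_column: int
    phase: int
    intron_index: int


@dataclass
class GeneStructureAlignment:
    """Per-gene intron marks over the columns of a shared protein MSA."""

    msa: dict[str, str]                       # gene_id -> aligned row
    positions: dict[str, list[IntronPosition]]
    rows: dict[str, str]                      # "-" coding / "|" intron marks
    cluster_spans: dict[str, list[tuple[int, int, int]]] = field(
        default_factory=dict)                 # gene -> (cluster_idx, c0, c1)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.msa.values()))) if self.msa else 0


@dataclass
class ConservationReport:
    #: (column, phase) -> sorted gene ids sharing that intron position
    groups: dict[tuple[int, int], list[str]]
    total_introns: int
    min_sharing: int


def _residue_columns(msa_row: str) -> list[int]:
    return [i for i, ch in enumerate(msa_row) if ch != GAP]


def map_intron_positions(
    gene: GeneStructure,
    genome: SequenceRecord,
    msa_row: str,
) -> list[IntronPosition]:
    """Assign each reference-transcript intron an MSA (column, phase).

    The reference transcript uses the annotated variant of every MXE
    cluster; its translation must equal the ungapped MSA row.
    """
    translation = translate_gene(gene, genome).protein.residues
    ungapped = msa_row.replace(GAP, "")
    if translation != ungapped:
        diff = next((k for k, (x, y) in enumerate(zip(translation, ungapped))
                     if x != y), min(len(translation), len(ungapped)))
        raise AlignmentError(
            f"gene {gene.gene_id}: MSA row does not match reference "
            f"translation (first difference at residue {diff})"
        )
    cols = _residue_columns(msa_row)
    ref = gene.reference_exon_indices()
    out = []
    cum = 0
    for k, i in enumerate(ref[:-1]):
        cum += len(gene.exons[i])
        aa_index, phase = cum // 3, cum % 3
        if aa_index >= len(cols):
            raise AlignmentError(
                f"gene {gene.gene_id}: intron {k} beyond the aligned protein"
            )
        out.append(IntronPosition(
            gene_id=gene.gene_id, alignment_column=cols[aa_index],
            phase=phase, intron_index=k,
        ))
    return out


def _cluster_spans(gene: GeneStructure, msa_row: str) -> list[tuple[int, int, int]]:
    """Project each cluster's annotated variant to a half-open column span."""
    cols = _residue_columns(msa_row)
    ref = gene.reference_exon_indices()
    spans = []
    cum = 0
    nt_span_of_exon: dict[int, tuple[int, int]] = {}
    for i in ref:
        e = gene.exons[i]
        nt_span_of_exon[i] = (cum, cum + len(e))
        cum += len(e)
    for cl in gene.clusters:
        nt0, nt1 = nt_span_of_exon[cl.annotated_index]
        a0, a1 = nt0 // 3, (nt1 + 2) // 3  # codons touched by the variant
        a1 = min(a1, len(cols))
        if a0 >= a1:
            continue
        spans.append((cl.cluster_index_in_gene, cols[a0], cols[a1 - 1] + 1))
    return spans


def align_gene_structures(
    genes: list[GeneStructure],
    genomes: dict[str, SequenceRecord],
    msa: dict[str, str],
) -> GeneStructureAlignment:
    """Build the full gene-structure alignment for a set of genes sharing
    one protein MSA (keyed by gene id)."""
    if not genes:
        raise AlignmentError("no genes to align")
    ncol = {len(row) for row in msa.values()}
    if len(ncol) != 1:
        raise AlignmentError("MSA rows have differing lengths")
    ncol = ncol.pop()
    positions: dict[str, list[IntronPosition]] = {}
    rows: dict[str, str] = {}
    spans: dict[str, list[tuple[int, int, int]]] = {}
    for g in genes:
        if g.gene_id not in msa:
            raise AlignmentError(f"gene {g.gene_id} missing from the MSA")
        row = msa[g.gene_id]
        pos = map_intron_positions(g, genomes[g.sequence_id], row)
        positions[g.gene_id] = pos
        marks = [GAP] * ncol
        for p in pos:
            marks[p.alignment_column] = "|"
        rows[g.gene_id] = "".join(marks)
        spans[g.gene_id] = _cluster_spans(g, row)
    return GeneStructureAlignment(
        msa={g.gene_id: msa[g.gene_id] for g in genes},
        positions=positions, rows=rows, cluster_spans=spans,
    )


def conservation_report(
    alignment: GeneStructureAlignment,
    min_sharing: int = 1,
) -> ConservationReport:
    """Group intron positions by (column, phase); keep groups shared by at
    least ``min_sharing`` genes."""
    groups: dict[tuple[int, int], list[str]] = {}
    total = 0
    for gid, plist in sorted(alignment.positions.items()):
        for p in plist:
            groups.setdefault((p.alignment_column, p.phase), []).append(gid)
            total += 1
    kept = {key: sorted(v) for key, v in groups.items()
            if len(v) >= min_sharing}
    return ConservationReport(groups=dict(sorted(kept.items())),
                              total_introns=total, min_sharing=min_sharing)


def render_text(alignment: GeneStructureAlignment) -> str:
    """Fixed-width text rendering: one mark row per gene, '|' = intron."""
    width = max(len(g) for g in alignment.rows) + 2
    lines = []
    for gid in sorted(alignment.rows):
        lines.append(f"{gid:<{width}}{alignment.rows[gid]}")
    return "\n".join(lines) + "\n"


def write_conservation_tsv(report: ConservationReport, path: str | Path,
                           header_lines: list[str] | None = None) -> None:
    lines = list(header_lines or [])
    lines.append("column\tphase\tn_genes\tgenes")
    for (col, phase), genes in report.groups.items():
        lines.append(f"{col}\t{phase}\t{len(genes)}\t{','.join(genes)}")
    Path(path).write_text("\n".join(lines) + "\n")
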