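"""Data model and I/O for exon/intron gene structures.

Conventions used throughout the package:

* Coordinates are 0-based half-open on the genomic (plus) strand; GFF3 I/O
  converts to/from 1-based closed coordinates.
* ``phase_in`` of an exon is the offset of its first base within its codon
  (0 = the base starts a codon).  This equals ``(3 - gff_phase) % 3`` for the
  GFF3 phase column, which counts bases to skip to reach the next codon start.
* Minus-strand genes are stored with their exon list in transcription order,
  so exon index 0 is always the 5' exon.  Genomic coordinates are untouched.

Mutually exclusive exon (MXE) clusters have no native GFF3 vocabulary; they
live in a YAML sidecar mapping each cluster to the indices of its member
exons within the gene's exon list (the annotated variant first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import GeneModelError, PhaseError

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

#: splice-site dialects: (donor dinucleotide, acceptor dinucleotide)
GT_AG = ("GT", "AG")
GC_AG = ("GC", "AG")
AT_AC = ("AT", "AC")
DEFAULT_DIALECT = frozenset({GT_AG})


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    alphabet: str  # "dna" | "protein"

    def __post_init__(self):
        if not self.residues:
            raise GeneModelError(f"sequence {self.id!r}: empty residues")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise GeneModelError(
                f"sequence {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonLocus:
    """One exon: genomic interval plus codon phases at both ends."""

    start: int
    end: int
    phase_in: int
    phase_out: int
    role: str = "constitutive"  # constitutive | mxe_variant | alt_terminal

    def __post_init__(self):
        if self.end <= self.start:
            raise GeneModelError(f"exon [{self.start},{self.end}): end <= start")
        if self.phase_in not in (0, 1, 2) or self.phase_out not in (0, 1, 2):
            raise PhaseError(f"exon [{self.start},{self.end}): phase outside 0..2")
        if (self.phase_in + len(self)) % 3 != self.phase_out:
            raise PhaseError(
                f"exon [{self.start},{self.end}): phase_out {self.phase_out} "
                f"inconsistent with phase_in {self.phase_in} and length {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def lead_nt(self) -> int:
        """Bases completing the codon begun in the previous exon."""
        return (3 - self.phase_in) % 3

    @property
    def aa_len(self) -> int:
        """Number of complete codons entirely inside this exon."""
        return (len(self) - self.lead_nt - self.phase_out) // 3


@dataclass
class MXECluster:
    """A run of mutually exclusive exon variants between two constitutive exons.

    ``variant_indices`` index into the owning gene's exon list, ordered
    5'->3'.  ``annotated_index`` is the exon index of the originally annotated
    variant (score 1.0 against itself); ``scores`` align with
    ``variant_indices`` and hold each variant's similarity to the annotated
    one.
    """

    cluster_index_in_gene: int
    variant_indices: list[int]
    annotated_index: int
    scores: list[float] = field(default_factory=list)
    flanking: tuple[int, int] | None = None  # constitutive exon indices

    def __post_init__(self):
        if len(self.variant_indices) < 2:
            raise GeneModelError(
                f"cluster {self.cluster_index_in_gene}: needs >= 2 variants"
            )
        if self.annotated_index not in self.variant_indices:
            raise GeneModelError(
                f"cluster {self.cluster_index_in_gene}: annotated variant "
                f"{self.annotated_index} not among variants"
            )


@dataclass
class GeneStructure:
    """Ordered exons of one gene over a named genomic sequence.

    Exons are kept in transcription order (index 0 = 5') and include every
    MXE variant; ``clusters`` says which exon indices are mutually exclusive.
    """

    gene_id: str
    species: str
    sequence_id: str
    strand: str
    exons: list[ExonLocus]
    clusters: list[MXECluster] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise GeneModelError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise GeneModelError(f"gene {self.gene_id}: no exons")
        genomic = self.exons if self.strand == "+" else list(reversed(self.exons))
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise GeneModelError(
                    f"gene {self.gene_id}: exons overlap or are out of order: "
                    f"[{a.start},{a.end}) then [{b.start},{b.end})"
                )
            if b.start - a.end < 1:
                raise GeneModelError(
                    f"gene {self.gene_id}: zero-length intron between exons"
                )
        path = self.reference_exon_indices()
        first = self.exons[path[0]]
        if first.phase_in != 0:
            raise PhaseError(f"gene {self.gene_id}: first exon phase_in != 0")
        for i, j in zip(path, path[1:]):
            if self.exons[i].phase_out != self.exons[j].phase_in:
                raise PhaseError(
                    f"gene {self.gene_id}: phase chain broken between exon "
                    f"{i} (out {self.exons[i].phase_out}) and exon "
                    f"{j} (in {self.exons[j].phase_in})"
                )

    # -- transcript paths -------------------------------------------------

    def variant_exon_set(self) -> set[int]:
        out: set[int] = set()
        for c in self.clusters:
            out.update(c.variant_indices)
        return out

    def reference_exon_indices(self) -> list[int]:
        """Exon indices of the reference transcript: constitutive exons plus
        the annotated variant of each cluster, in transcription order."""
        variants = self.variant_exon_set()
        annotated = {c.annotated_index for c in self.clusters}
        return [
            i
            for i, e in enumerate(self.exons)
            if i not in variants or i in annotated
        ]

    def transcript_exon_indices(
        self, variant_choice: dict[int, int] | None = None
    ) -> list[int]:
        """Exon indices for one transcript.

        ``variant_choice`` maps cluster_index_in_gene -> chosen exon index;
        clusters not mentioned fall back to their annotated variant.
        """
        choice = dict(variant_choice or {})
        chosen: set[int] = set()
        for c in self.clusters:
            pick = choice.pop(c.cluster_index_in_gene, c.annotated_index)
            if pick not in c.variant_indices:
                raise GeneModelError(
                    f"gene {self.gene_id}: exon {pick} is not a variant of "
                    f"cluster {c.cluster_index_in_gene}"
                )
            chosen.add(pick)
        if choice:
            raise GeneModelError(
                f"gene {self.gene_id}: unknown cluster(s) in variant choice: "
                f"{sorted(choice)}"
            )
        variants = self.variant_exon_set()
        picked = [
            i for i, _ in enumerate(self.exons) if i not in variants or i in chosen
        ]
        # guard: exactly one variant per cluster on the path
        for c in self.clusters:
            n = sum(1 for i in c.variant_indices if i in chosen)
            if n != 1:
                raise GeneModelError(
                    f"gene {self.gene_id}: cluster {c.cluster_index_in_gene} "
                    f"has {n} variants selected (need exactly 1)"
                )
        return picked

    def introns(
        self, exon_indices: Sequence[int] | None = None
    ) -> list[tuple[int, int]]:
        """Genomic intervals of the gaps between consecutive exons of a
        transcript path (reference path by default), in transcription order."""
        idx = list(exon_indices) if exon_indices is not None else self.reference_exon_indices()
        out = []
        for i, j in zip(idx, idx[1:]):
            a, b = self.exons[i], self.exons[j]
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return out


@dataclass
class SpliceSiteReport:
    """Donor/acceptor dinucleotides per intron of a gene."""

    gene_id: str
    entries: list[dict]  # intron_index, donor, acceptor, canonical, error


# -- sequence helpers ------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def exon_nt(genome: SequenceRecord, gene: GeneStructure, exon: ExonLocus) -> str:
    """Exon sequence in transcription orientation."""
    s = genome.residues[exon.start:exon.end]
    return s if gene.strand == "+" else reverse_complement(s)


def genomic_slice(genome: SequenceRecord, gene: GeneStructure,
                  start: int, end: int) -> str:
    """Arbitrary genomic interval in the gene's transcription orientation."""
    s = genome.residues[start:end]
    return s if gene.strand == "+" else reverse_complement(s)


# -- core operations -------------------------------------------------------

def coding_sequence(
    gene: GeneStructure,
    genome: SequenceRecord,
    variant_choice: dict[int, int] | None = None,
) -> SequenceRecord:
    """Concatenated exon sequence of one transcript, 5'->3'."""
    if genome.id != gene.sequence_id:
        raise GeneModelError(
            f"gene {gene.gene_id} references sequence {gene.sequence_id!r}, "
            f"got {genome.id!r}"
        )
    idx = gene.transcript_exon_indices(variant_choice)
    cds = "".join(exon_nt(genome, gene, gene.exons[i]) for i in idx)
    return SequenceRecord(id=f"{gene.gene_id}_cds", residues=cds, alphabet="dna")


@dataclass
class TranslationResult:
    protein: SequenceRecord
    internal_stop_codons: list[int]
    terminal_stop: bool


def translate_cds(cds: str, seq_id: str = "cds") -> TranslationResult:
    """Standard-code translation; internal stops are reported, not dropped."""
    if len(cds) < 3:
        raise GeneModelError(f"{seq_id}: coding sequence shorter than one codon")
    if len(cds) % 3 != 0:
        raise PhaseError(
            f"{seq_id}: coding length {len(cds)} not divisible by 3 "
            f"(trailing phase {len(cds) % 3})"
        )
    aa = str(Seq(cds).translate())
    terminal = aa.endswith("*")
    body = aa[:-1] if terminal else aa
    internal = [i for i, r in enumerate(body) if r == "*"]
    return TranslationResult(
        protein=SequenceRecord(id=f"{seq_id}_aa", residues=aa.rstrip("*") or aa,
                               alphabet="protein"),
        internal_stop_codons=internal,
        terminal_stop=terminal,
    )


def translate_gene(
    gene: GeneStructure,
    genome: SequenceRecord,
    variant_choice: dict[int, int] | None = None,
) -> TranslationResult:
    cds = coding_sequence(gene, genome, variant_choice)
    return translate_cds(cds.residues, seq_id=gene.gene_id)


def splice_site_report(
    gene: GeneStructure,
    genome: SequenceRecord,
    dialect: frozenset[tuple[str, str]] = DEFAULT_DIALECT,
) -> SpliceSiteReport:
    """Donor/acceptor dinucleotides for every gap between consecutive exons
    of the stored exon list (variant-to-variant gaps included)."""
    entries = []
    all_idx = list(range(len(gene.exons)))
    for k, (lo, hi) in enumerate(gene.introns(all_idx)):
        length = hi - lo
        if length < 4:
            entries.append({"intron_index": k, "donor": None, "acceptor": None,
                            "canonical": False,
                            "error": f"intron shorter than 4 nt ({length})"})
            continue
        s = genomic_slice(genome, gene, lo, hi)
        donor, acceptor = s[:2].upper(), s[-2:].upper()
        entries.append({
            "intron_index": k, "donor": donor, "acceptor": acceptor,
            "canonical": (donor, acceptor) in dialect, "error": None,
        })
    return SpliceSiteReport(gene_id=gene.gene_id, entries=entries)


# -- GFF3 + sidecar I/O ----------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "dna") -> dict[str, SequenceRecord]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = SequenceRecord(id=rec.id, residues=str(rec.seq).upper(),
                                     alphabet=alphabet)
    return out


def _parse_attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_structures(
    annotation_path: str | Path,
    sequence_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> list[GeneStructure]:
    """Read gene structures from GFF3 CDS rows plus a genome FASTA.

    Minus-strand genes come back with exons in transcription order.  An
    optional YAML sidecar attaches MXE clusters (exon indices per cluster).
    """
    genomes = read_fasta(sequence_path)
    raw: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(annotation_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GeneModelError(f"malformed GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, phase, attrs = cols
        if ftype != "CDS":
            continue
        a = _parse_attributes(attrs)
        gid = a.get("gene_id") or a.get("Parent") or a.get("ID")
        if gid is None:
            raise GeneModelError(f"CDS without Parent/gene_id: {line!r}")
        gid = gid.split(".")[0] if gid.endswith(".mrna") else gid
        if gid not in raw:
            raw[gid] = {"seqid": seqid, "strand": strand, "cds": [],
                        "species": a.get("species", "unknown")}
            order.append(gid)
        if seqid != raw[gid]["seqid"]:
            raise GeneModelError(f"gene {gid}: CDS on multiple sequences")
        raw[gid]["cds"].append((int(start) - 1, int(end), phase))

    sidecar = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        sidecar = yaml.safe_load(Path(sidecar_path).read_text()) or {}

    genes = []
    for gid in order:
        info = raw[gid]
        if info["seqid"] not in genomes:
            raise GeneModelError(
                f"gene {gid}: sequence id {info['seqid']!r} missing from FASTA"
            )
        cds = sorted(info["cds"])
        if info["strand"] == "-":
            cds = cds[::-1]  # transcription order: 5' exon first
        exons = []
        for start, end, phase in cds:
            if phase == ".":
                raise PhaseError(f"gene {gid}: CDS at {start + 1}-{end} lacks phase")
            gff_phase = int(phase)
            phase_in = (3 - gff_phase) % 3
            phase_out = (phase_in + (end - start)) % 3
            exons.append(ExonLocus(start=start, end=end, phase_in=phase_in,
                                   phase_out=phase_out))
        clusters = []
        for k, spec in enumerate(sidecar.get(gid, {}).get("clusters", [])):
            members = list(spec["variants"])
            for m in members:
                exons[m] = replace(exons[m], role="mxe_variant")
            clusters.append(MXECluster(
                cluster_index_in_gene=k,
                variant_indices=members,
                annotated_index=spec.get("annotated", members[0]),
                scores=list(spec.get("scores", [])),
                flanking=tuple(spec["flanking"]) if "flanking" in spec else None,
            ))
        genes.append(GeneStructure(
            gene_id=gid, species=info["species"], sequence_id=info["seqid"],
            strand=info["strand"], exons=exons, clusters=clusters,
        ))
    return genes


def write_gene_structures(
    genes: Iterable[GeneStructure],
    annotation_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write GFF3 (gene/mRNA/CDS rows) plus the MXE cluster sidecar."""
    lines = ["##gff-version 3"]
    sidecar: dict = {}
    for g in genes:
        genomic = g.exons if g.strand == "+" else list(reversed(g.exons))
        lo = min(e.start for e in g.exons) + 1
        hi = max(e.end for e in g.exons)
        lines.append("\t".join([
            g.sequence_id, "mxevolve", "gene", str(lo), str(hi), ".",
            g.strand, ".", f"ID={g.gene_id};species={g.species}"]))
        lines.append("\t".join([
            g.sequence_id, "mxevolve", "mRNA", str(lo), str(hi), ".",
            g.strand, ".", f"ID={g.gene_id}.mrna;Parent={g.gene_id}"]))
        for e in genomic:
            gff_phase = (3 - e.phase_in) % 3
            lines.append("\t".join([
                g.sequence_id, "mxevolve", "CDS", str(e.start + 1), str(e.end),
                ".", g.strand, str(gff_phase),
                f"Parent={g.gene_id}.mrna;gene_id={g.gene_id};"
                f"species={g.species};role={e.role}"]))
        if g.clusters:
            sidecar[g.gene_id] = {"clusters": [
                {"variants": list(c.variant_indices),
                 "annotated": c.annotated_index,
                 "scores": [float(s) for s in c.scores],
                 **({"flanking": list(c.flanking)} if c.flanking else {})}
                for c in g.clusters
            ]}
    Path(annotation_path).write_text("\n".join(lines) + "\n")
    if sidecar_path is not None:
        Path(sidecar_path).write_text(yaml.safe_dump(sidecar, sort_keys=True))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i:i + 70] + "\n")
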