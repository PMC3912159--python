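"""Gene structure model: coordinates, phases, strands, I/O round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from mxevolve.errors import GeneModelError, PhaseError
from mxevolve.gene_model import (
    DEFAULT_DIALECT,
    GC_AG,
    GT_AG,
    SequenceRecord,
    coding_sequence,
    read_gene_structures,
    splice_site_report,
    translate_cds,
    translate_gene,
    write_gene_structures,
)
from mxevolve.synthetic_data import (
    ClusterSpec,
    GeneSimSpec,
    flip_to_minus_strand,
    simulate_gene,
)

GFF = """##gff-version 3
chr1\ttest\tgene\t101\t460\t.\t{strand}\t.\tID=g1;species=sp
chr1\ttest\tmRNA\t101\t460\t.\t{strand}\t.\tID=g1.mrna;Parent=g1
chr1\ttest\tCDS\t101\t160\t.\t{strand}\t{p1}\tParent=g1.mrna;gene_id=g1
chr1\ttest\tCDS\t201\t280\t.\t{strand}\t{p2}\tParent=g1.mrna;gene_id=g1
chr1\ttest\tCDS\t401\t460\t.\t{strand}\t{p3}\tParent=g1.mrna;gene_id=g1
"""


def _write_inputs(tmp_path, gff_text, seq_len=600):
    gff = tmp_path / "g.gff3"
    gff.write_text(gff_text)
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">chr1\n" + "ACGT" * (seq_len // 4) + "\n")
    return gff, fasta


class TestReadGeneStructures:
    def test_plus_strand_coordinates_and_phase_chain(self, tmp_path):
        """1-based closed GFF3 becomes 0-based half-open; the phase chain
        follows (phase_in + length) mod 3 across exons."""
        gff, fasta = _write_inputs(
            tmp_path, GFF.format(strand="+", p1=0, p2=0, p3=1))
        (gene,) = read_gene_structures(gff, fasta)
        assert [(e.start, e.end) for e in gene.exons] == \
            [(100, 160), (200, 280), (400, 460)]
        assert [e.phase_in for e in gene.exons] == [0, 0, 2]
        assert [e.phase_out for e in gene.exons] == [0, 2, 2]

    def test_minus_strand_reverses_exon_order(self, tmp_path):
        """Minus-strand genes store exon index 0 as the 5' exon; genomic
        coordinates are unchanged."""
        gff, fasta = _write_inputs(
            tmp_path, GFF.format(strand="-", p1=1, p2=0, p3=0))
        (gene,) = read_gene_structures(gff, fasta)
        assert [(e.start, e.end) for e in gene.exons] == \
            [(400, 460), (200, 280), (100, 160)]
        assert gene.exons[0].phase_in == 0

    def test_empty_gff_gives_empty_list(self, tmp_path):
        gff, fasta = _write_inputs(tmp_path, "##gff-version 3\n")
        assert read_gene_structures(gff, fasta) == []

    def test_missing_sequence_id_is_fatal(self, tmp_path):
        gff, fasta = _write_inputs(
            tmp_path, GFF.format(strand="+", p1=0, p2=0, p3=1))
        fasta.write_text(">other\nACGT\n")
        with pytest.raises(GeneModelError, match="chr1"):
            read_gene_structures(gff, fasta)

    def test_phase_inconsistency_is_fatal(self, tmp_path):
        gff, fasta = _write_inputs(
            tmp_path, GFF.format(strand="+", p1=0, p2=0, p3=0))
        with pytest.raises(PhaseError, match="g1"):
            read_gene_structures(gff, fasta)

    def test_overlapping_exons_are_fatal(self, tmp_path):
        bad = GFF.format(strand="+", p1=0, p2=0, p3=1).replace("201", "155")
        gff, fasta = _write_inputs(tmp_path, bad)
        with pytest.raises(GeneModelError):
            read_gene_structures(gff, fasta)


class TestCodingSequenceAndTranslation:
    def test_cds_length_is_sum_of_exons(self, tmp_path):
        gff, fasta = _write_inputs(
            tmp_path, GFF.format(strand="+", p1=0, p2=0, p3=1))
        (gene,) = read_gene_structures(gff, fasta)
        assert len(coding_sequence(
            gene, read_fasta_first(fasta)).residues) == 60 + 80 + 60

    def test_two_variant_cluster_enumerates_two_transcripts(self, default_sim):
        sim = default_sim
        cl = sim.gene.clusters[0]
        cds = {}
        for v in cl.variant_indices:
            cds[v] = coding_sequence(sim.gene, sim.genome,
                                     {cl.cluster_index_in_gene: v}).residues
        assert len(set(cds.values())) == 2

    def test_variant_choice_length_difference_matches_plant(self):
        sim = simulate_gene(GeneSimSpec(
            clusters=(ClusterSpec(4, 2, 0.6, length_delta_aa=9),), seed=2))
        cl = sim.gene.clusters[0]
        a, b = cl.variant_indices
        la = len(coding_sequence(sim.gene, sim.genome,
                                 {cl.cluster_index_in_gene: a}).residues)
        lb = len(coding_sequence(sim.gene, sim.genome,
                                 {cl.cluster_index_in_gene: b}).residues)
        assert abs(la - lb) == 27

    def test_selecting_unknown_variant_names_cluster(self, default_sim):
        sim = default_sim
        with pytest.raises(GeneModelError, match="cluster 0"):
            coding_sequence(sim.gene, sim.genome, {0: 999})

    def test_translation_flags_terminal_stop(self):
        res = translate_cds("ATGGCCTAA")
        assert res.protein.residues == "MA"
        assert res.terminal_stop and not res.internal_stop_codons

    def test_internal_stop_reported_with_codon_index(self):
        res = translate_cds("ATGTAAGCC")
        assert res.internal_stop_codons == [1]

    def test_length_not_divisible_by_three_cites_phase(self):
        with pytest.raises(PhaseError, match="trailing phase 2"):
            translate_cds("ATGGCCTA")

    def test_equal_frame_variants_align_outside_variant_region(self):
        """Two MXE variants of equal length translate identically outside
        the swapped exon."""
        sim = simulate_gene(GeneSimSpec(
            clusters=(ClusterSpec(4, 2, 0.6),), seed=9))
        cl = sim.gene.clusters[0]
        a, b = cl.variant_indices
        ta = translate_gene(sim.gene, sim.genome, {0: a}).protein.residues
        tb = translate_gene(sim.gene, sim.genome, {0: b}).protein.residues
        assert len(ta) == len(tb)
        diff = [i for i, (x, y) in enumerate(zip(ta, tb)) if x != y]
        # every differing residue lies within the variant exon's aa span
        ref = sim.gene.reference_exon_indices()
        cum = 0
        span = None
        for i in ref:
            e = sim.gene.exons[i]
            if i == a:
                span = (cum // 3, (cum + len(e) + 2) // 3)
            cum += len(e)
        assert span and all(span[0] <= d < span[1] for d in diff)


class TestSpliceSites:
    def test_canonical_gt_ag(self, toy_planted):
        gene, genome = toy_planted(None)
        rep = splice_site_report(gene, genome)
        assert all(e["canonical"] for e in rep.entries)
        assert [e["donor"] for e in rep.entries] == ["GT", "GT"]

    def test_gc_ag_needs_dialect_toggle(self, toy_planted):
        gene, genome = toy_planted(None)
        seq = genome.residues
        i = gene.exons[0].end
        mutated = SequenceRecord(
            id=genome.id, residues=seq[:i] + "GC" + seq[i + 2:],
            alphabet="dna")
        rep = splice_site_report(gene, mutated, DEFAULT_DIALECT)
        assert rep.entries[0]["canonical"] is False
        rep2 = splice_site_report(gene, mutated,
                                  frozenset({GT_AG, GC_AG}))
        assert rep2.entries[0]["canonical"] is True

    def test_minus_strand_reads_reverse_complement(self):
        sim = simulate_gene(GeneSimSpec(seed=4))
        minus = flip_to_minus_strand(sim)
        plus_rep = splice_site_report(sim.gene, sim.genome)
        minus_rep = splice_site_report(minus.gene, minus.genome)
        assert [(e["donor"], e["acceptor"]) for e in plus_rep.entries] == \
            [(e["donor"], e["acceptor"]) for e in minus_rep.entries]

    def test_short_intron_reported_per_entry(self, tmp_path):
        gff, fasta = _write_inputs(tmp_path, GFF.format(
            strand="+", p1=0, p2=0, p3=2).replace("201", "163"))
        (gene,) = read_gene_structures(gff, fasta)
        rep = splice_site_report(gene, read_fasta_first(fasta))
        assert rep.entries[0]["error"] is not None
        assert rep.entries[1]["error"] is None


class TestRoundTripAndStrand:
    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_gff3_sidecar_round_trip_is_exact(self, seed, tmp_path_factory):
        """Writing and re-reading reproduces coordinates, strands, phases,
        and cluster membership bit-exactly."""
        tmp = tmp_path_factory.mktemp("rt")
        sim = simulate_gene(GeneSimSpec(
            clusters=(ClusterSpec(3, 2, 0.6),), seed=seed))
        write_gene_structures([sim.gene], tmp / "x.gff3", tmp / "x.yaml")
        sim.write(tmp)  # genome fasta
        (back,) = read_gene_structures(tmp / "x.gff3", tmp / "genome.fasta",
                                       tmp / "x.yaml")
        assert [(e.start, e.end, e.phase_in, e.phase_out)
                for e in back.exons] == \
            [(e.start, e.end, e.phase_in, e.phase_out)
             for e in sim.gene.exons]
        assert back.strand == sim.gene.strand
        assert [c.variant_indices for c in back.clusters] == \
            [c.variant_indices for c in sim.gene.clusters]

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_strand_involution_preserves_translation(self, seed):
        """Reverse-complementing the genome and flipping the strand leaves
        the protein unchanged."""
        sim = simulate_gene(GeneSimSpec(seed=seed))
        minus = flip_to_minus_strand(sim)
        assert translate_gene(minus.gene, minus.genome).protein.residues == \
            translate_gene(sim.gene, sim.genome).protein.residues

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_phase_chain_holds_on_generator_output(self, seed):
        sim = simulate_gene(GeneSimSpec(seed=seed))
        ref = sim.gene.reference_exon_indices()
        for i, j in zip(ref, ref[1:]):
            assert sim.gene.exons[i].phase_out == sim.gene.exons[j].phase_in


def read_fasta_first(path):
    from mxevolve.gene_model import read_fasta
    return next(iter(read_fasta(path).values()))
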