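"""MXE candidate detection: thresholds, clustering, planted-truth recovery."""

import pytest

from mxevolve.errors import SearchError
from mxevolve.gene_model import coding_sequence, translate_cds
from mxevolve.mxe_search import (
    SearchParameters,
    TranscriptEvidence,
    annotate_clusters,
    check_transcript_consistency,
    find_mxe_candidates,
    group_into_clusters,
)
from mxevolve.synthetic_data import (
    ClusterSpec,
    GeneSimSpec,
    simulate_gene,
    strip_variant_annotation,
)

from conftest import make_planted_gene

PARAMS = SearchParameters()


def detect(sim, params=PARAMS):
    bare = strip_variant_annotation(sim.gene)
    cands = find_mxe_candidates(bare, sim.genome, params)
    return bare, cands, group_into_clusters(cands, bare)


class TestThresholds:
    def test_exact_duplicate_is_found_with_score_one(self, toy_planted):
        gene, genome = toy_planted("T" * 20)
        cands = find_mxe_candidates(gene, genome, PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.score == 1.0
        assert (c.phase_in, c.phase_out) == (gene.exons[1].phase_in,
                                             gene.exons[1].phase_out)

    def test_nine_aa_duplicate_is_rejected(self, toy_planted):
        """Candidates shorter than the 10-aa minimum exon length are not
        reported."""
        gene, genome = toy_planted("T" * 9)
        assert find_mxe_candidates(gene, genome, PARAMS) == []

    def test_ten_aa_duplicate_passes_minimum_length(self, toy_planted):
        gene, genome = toy_planted("T" * 10)
        assert len(find_mxe_candidates(gene, genome, PARAMS)) == 1

    def test_oversized_duplicate_beyond_20aa_difference_is_rejected(
            self, toy_planted):
        gene, genome = toy_planted("T" * 45)  # anchor is 20 aa: +25 aa
        assert find_mxe_candidates(gene, genome, PARAMS) == []

    def test_length_difference_of_exactly_20aa_is_kept(self, toy_planted):
        gene, genome = toy_planted("T" * 40)
        assert len(find_mxe_candidates(gene, genome, PARAMS)) == 1

    def test_similarity_threshold_separates_40_from_10_percent(
            self, toy_planted):
        # variant with m matching T residues out of 20 scores exactly m/20
        gene, genome = toy_planted("T" * 8 + "F" * 12)
        assert len(find_mxe_candidates(gene, genome, PARAMS)) == 1
        gene, genome = toy_planted("T" * 2 + "F" * 18)
        assert find_mxe_candidates(gene, genome, PARAMS) == []

    def test_internal_stop_codon_disqualifies(self, toy_planted):
        gene, genome = toy_planted("T" * 20)
        seq = genome.residues
        # plant a TAA stop inside the variant's 5th codon
        vstart = seq.index("ACT" * 20, gene.exons[1].end) + 12
        mutated = seq[:vstart] + "TAA" + seq[vstart + 3:]
        from mxevolve.gene_model import SequenceRecord
        genome2 = SequenceRecord(id=genome.id, residues=mutated,
                                 alphabet="dna")
        assert find_mxe_candidates(gene, genome2, PARAMS) == []

    def test_genome_gene_id_mismatch_is_fatal(self, toy_planted):
        gene, genome = toy_planted(None)
        from mxevolve.gene_model import SequenceRecord
        other = SequenceRecord(id="wrong", residues=genome.residues,
                               alphabet="dna")
        with pytest.raises(SearchError):
            find_mxe_candidates(gene, other, PARAMS)


class TestScopeAndMonotonicity:
    def test_internal_only_ignores_terminal_flanking_introns(self,
                                                             toy_planted):
        """A 3-exon gene's single internal anchor touches only terminal
        exons; restricting the scope to strictly internal introns leaves
        nothing to scan."""
        gene, genome = toy_planted("T" * 20)
        internal = SearchParameters(search_scope="internal_only")
        assert find_mxe_candidates(gene, genome, internal) == []
        assert len(find_mxe_candidates(gene, genome, PARAMS)) == 1

    def test_raising_min_score_never_adds_candidates(self, default_sim):
        bare = strip_variant_annotation(default_sim.gene)
        counts = [
            len(find_mxe_candidates(bare, default_sim.genome,
                                    SearchParameters(min_score=s)))
            for s in (0.15, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_raising_length_difference_never_removes_candidates(
            self, default_sim):
        bare = strip_variant_annotation(default_sim.gene)
        counts = [
            len(find_mxe_candidates(
                bare, default_sim.genome,
                SearchParameters(max_length_difference_aa=d)))
            for d in (0, 5, 20, 40)
        ]
        assert counts == sorted(counts)

    def test_output_is_deterministic_and_ordered(self, default_sim):
        bare = strip_variant_annotation(default_sim.gene)
        a = find_mxe_candidates(bare, default_sim.genome, PARAMS)
        b = find_mxe_candidates(bare, default_sim.genome, PARAMS)
        assert a == b
        assert [(c.start, c.end) for c in a] == \
            sorted((c.start, c.end) for c in a)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SearchError):
            SearchParameters(min_score=1.5)
        with pytest.raises(SearchError):
            SearchParameters(min_exon_length_aa=0)


class TestClustering:
    def test_candidates_on_both_sides_merge_into_one_cluster(self):
        """Two variants planted around one anchor give a single 3-variant
        cluster."""
        sim = simulate_gene(GeneSimSpec(
            clusters=(ClusterSpec(4, 3, 0.7),), seed=21))
        _, _, clusters = detect(sim)
        assert len(clusters) == 1
        assert len(clusters[0].variants) == 3

    def test_separate_anchors_give_separate_clusters(self, default_sim):
        _, _, clusters = detect(default_sim)
        assert [len(c.variants) for c in clusters] == [2, 3]

    def test_capitella_like_architecture_recovers_seven_clusters(self):
        """A gene modelled on the most cluster-rich annelid architecture
        (seven clusters of MXEs) is fully recovered."""
        spec = GeneSimSpec(
            n_exons=16,
            clusters=tuple(ClusterSpec(a, 2, 0.7)
                           for a in (2, 4, 6, 8, 10, 12, 14)),
            seed=88)
        sim = simulate_gene(spec)
        _, _, clusters = detect(sim)
        assert len(clusters) == 7

    def test_phase_mismatched_candidate_is_rejected_with_reason(
            self, default_sim):
        from dataclasses import replace
        bare = strip_variant_annotation(default_sim.gene)
        cands = find_mxe_candidates(bare, default_sim.genome, PARAMS)
        bad = replace(cands[0],
                      phase_in=(cands[0].phase_in + 1) % 3,
                      phase_out=(cands[0].phase_out + 1) % 3)
        with pytest.raises(SearchError, match="phases differ"):
            group_into_clusters([bad], bare)

    def test_frame_safety_of_reported_candidates(self, default_sim):
        """Substituting any reported candidate for its anchor yields a
        stop-free translation identical to the reference outside the
        cluster."""
        bare = strip_variant_annotation(default_sim.gene)
        cands = find_mxe_candidates(bare, default_sim.genome, PARAMS)
        annotated = annotate_clusters(bare, group_into_clusters(cands, bare))
        ref = translate_cds(
            coding_sequence(annotated, default_sim.genome).residues)
        assert not ref.internal_stop_codons
        for cl in annotated.clusters:
            for v in cl.variant_indices:
                res = translate_cds(coding_sequence(
                    annotated, default_sim.genome,
                    {cl.cluster_index_in_gene: v}).residues)
                assert not res.internal_stop_codons


class TestPlantedTruthRecovery:
    def test_recall_and_precision_are_perfect_on_200_genes(self):
        """Planted variants at the generator's default similarities are
        recovered exactly — no misses and no extra variants — across 200
        seeded genes."""
        tp = fp = fn = 0
        for seed in range(200):
            sim = simulate_gene(GeneSimSpec(
                clusters=(ClusterSpec(3, 2, 0.6), ClusterSpec(6, 3, 0.8)),
                seed=seed))
            bare, _, clusters = detect(sim)
            truth = {(v["start"], v["end"])
                     for tc in sim.truth["clusters"]
                     for v in tc["variants"]}
            anchor_coords = {
                (sim.gene.exons[c.annotated_index].start,
                 sim.gene.exons[c.annotated_index].end)
                for c in sim.gene.clusters}
            found = {(v.start, v.end)
                     for c in clusters for v in c.variants} - anchor_coords
            tp += len(truth & found)
            fp += len(found - truth)
            fn += len(truth - found)
        assert fp == 0 and fn == 0 and tp == 600


class TestTranscriptConsistency:
    def _gene(self):
        sim = simulate_gene(GeneSimSpec(
            clusters=(ClusterSpec(3, 2, 0.8),), seed=5))
        return sim.gene

    def test_one_variant_per_transcript_confirms(self):
        gene = self._gene()
        a, b = gene.clusters[0].variant_indices
        ev = [TranscriptEvidence("t1", [0, a, 5]),
              TranscriptEvidence("t2", [0, b, 5])]
        status = check_transcript_consistency(gene, ev)
        assert status[0]["status"] == "confirmed"

    def test_transcript_with_both_variants_is_flagged(self):
        gene = self._gene()
        a, b = gene.clusters[0].variant_indices
        status = check_transcript_consistency(
            gene, [TranscriptEvidence("t1", [a, b])])
        assert status[0]["status"] == "violated"
        assert status[0]["violations"][0]["variants"] == sorted([a, b])

    def test_no_evidence_is_unconfirmed_not_an_error(self):
        gene = self._gene()
        status = check_transcript_consistency(gene, [])
        assert status[0]["status"] == "unconfirmed"

    def test_unknown_exon_index_gives_per_record_error(self):
        gene = self._gene()
        status = check_transcript_consistency(
            gene, [TranscriptEvidence("t1", [999])])
        assert status[0]["errors"]
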