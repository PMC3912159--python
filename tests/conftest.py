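from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mxevolve.gene_model import ExonLocus, GeneStructure, SequenceRecord
from mxevolve.synthetic_data import (
    ClusterSpec,
    GeneSimSpec,
    simulate_gene,
    strip_variant_annotation,
)

# G-free codons: sequences built from them contain no AG or GT dinucleotide,
# so handcrafted genes have exactly the splice contexts we plant.
GFREE_CODON = {"F": "TTT", "L": "CTT", "S": "TCT", "Y": "TAT", "P": "CCT",
               "T": "ACT", "H": "CAT", "N": "AAT", "I": "ATT", "K": "AAA",
               "Q": "CAA"}


def encode_gfree(aa: str) -> str:
    return "".join(GFREE_CODON[r] for r in aa)


def make_planted_gene(variant_aa: str | None, anchor_aa: str = "T" * 20,
                      flank_aa: str = "I" * 12, gene_id: str = "toy"):
    """Three-exon plus-strand gene; optional planted variant in the intron
    after the (single, internal) anchor exon.  All sequences avoid G outside
    the designed GT/AG contexts, so detection sees only planted windows."""
    intron = "GT" + "T" * 12 + "AG"
    pad = "GT" + "T" * 8 + "AG"
    e1, e2, e3 = encode_gfree(flank_aa), encode_gfree(anchor_aa), encode_gfree(flank_aa)
    parts = ["T" * 10, e1, intron, e2]
    if variant_aa is not None:
        parts += [pad, encode_gfree(variant_aa), pad]
    else:
        parts += [intron]
    parts += [e3, "T" * 10]
    seq = "".join(parts)
    exons = []
    pos = 10
    for e in (e1, e2, e3):
        start = seq.index(e, pos)
        exons.append(ExonLocus(start=start, end=start + len(e),
                               phase_in=0, phase_out=0))
        pos = start + len(e)
    gene = GeneStructure(gene_id=gene_id, species="toy_species",
                         sequence_id="toy_contig", strand="+", exons=exons)
    genome = SequenceRecord(id="toy_contig", residues=seq, alphabet="dna")
    return gene, genome


@pytest.fixture
def toy_planted():
    return make_planted_gene


@pytest.fixture
def rng():
    return np.random.default_rng(20140203)


def bare_detection_view(sim) -> GeneStructure:
    """The simulated gene as the detector first sees it (variants hidden)."""
    return strip_variant_annotation(sim.gene)


@pytest.fixture
def default_sim():
    return simulate_gene(GeneSimSpec(
        clusters=(ClusterSpec(3, 2, 0.6), ClusterSpec(6, 3, 0.8)), seed=11))


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary topology over n named leaves."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})N{k}")
        k += 1
    return nodes[0] + ";"
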