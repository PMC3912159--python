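"""Synthetic inputs with machine-readable truth tables.

Three generators stand in for the genome assemblies behind the myosin heavy
chain survey:

* :func:`simulate_gene` — a multi-exon gene with planted MXE clusters:
  duplicated exons at a controlled similarity, equal flanking phases, and
  canonical GT..AG splice contexts, embedded in random intronic sequence.
* :func:`simulate_homolog_family` — homologous genes evolved down a tree
  with per-branch residue substitution, Bernoulli intron loss, and optional
  +/-1 nt intron shifts; the MSA comes from the true residue homology.
* :func:`simulate_matrix` — presence/absence matrices replayed from a
  planted gain/loss event map, with optional unknown-state masking.

Default architecture emulates a compact invertebrate gene: 15-30 aa exons
separated by 20-36 nt introns.  Plain introns that short cannot host a
spurious >= 10 aa reading frame between splice dinucleotides, so planted
variants are the only true positives by construction.  Variant divergence
is generated by replacing residues with non-positive-scoring BLOSUM62
partners until the similarity fraction reaches the target, then
back-translating with uniform codon choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .cluster_homology import ABSENT, PRESENT, UNKNOWN
from .dollo import EventMap, node_name, replay_events
from .errors import SimulationError
from .gene_model import (
    ExonLocus,
    GeneStructure,
    MXECluster,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_gene_structures,
)
from .similarity import _BLOSUM, score_exon_similarity

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for _c in ("TTT TTC TTA TTG CTT CTC CTA CTG ATT ATC ATA ATG GTT GTC GTA GTG "
           "TCT TCC TCA TCG CCT CCC CCA CCG ACT ACC ACA ACG GCT GCC GCA GCG "
           "TAT TAC CAT CAC CAA CAG AAT AAC AAA AAG GAT GAC GAA GAG TGT TGC "
           "TGG CGT CGC CGA CGG AGT AGC AGA AGG GGT GGC GGA GGG").split():
    from Bio.Seq import Seq as _Seq
    _aa = str(_Seq(_c).translate())
    _CODONS.setdefault(_aa, []).append(_c)

#: for each residue, substitution partners scoring <= 0 in BLOSUM62
_NONPOS_PARTNERS = {
    a: [b for b in AA20 if b != a and int(_BLOSUM[a, b]) <= 0] for a in AA20
}


@dataclass(frozen=True)
class ClusterSpec:
    anchor_exon_index: int
    n_variants: int = 2
    similarity: float = 0.6
    length_delta_aa: int = 0

    def __post_init__(self):
        if self.n_variants < 2:
            raise SimulationError("cluster needs >= 2 variants")
        if not (0 < self.similarity <= 1):
            raise SimulationError("target similarity must be in (0, 1]")


@dataclass(frozen=True)
class GeneSimSpec:
    n_exons: int = 9
    exon_len_aa: tuple[int, int] = (15, 30)
    intron_len_nt: tuple[int, int] = (20, 36)
    pad_intron_nt: tuple[int, int] = (8, 14)
    clusters: tuple[ClusterSpec, ...] = ()
    seed: int = 0
    gene_id: str = "simgene"
    species: str = "simulated"

    def __post_init__(self):
        if self.n_exons < 3:
            raise SimulationError("need >= 3 exons (internal anchors)")
        if self.intron_len_nt[0] < 4:
            raise SimulationError("introns must be >= 4 nt for splice sites")
        for cl in self.clusters:
            if not (0 < cl.anchor_exon_index < self.n_exons - 1):
                raise SimulationError(
                    f"cluster anchor {cl.anchor_exon_index} is not internal"
                )
            if self.pad_intron_nt[0] < 4:
                raise SimulationError(
                    f"cluster at anchor {cl.anchor_exon_index}: intron too "
                    f"short to host a variant (pads need >= 4 nt)"
                )


@dataclass
class SimulatedGene:
    genome: SequenceRecord
    gene: GeneStructure
    truth: dict
    protein: str

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "gff3_bare": outdir / "genes_bare.gff3",
            "sidecar": outdir / "clusters.yaml",
            "truth": outdir / "truth.json",
        }
        write_fasta([self.genome], paths["fasta"])
        write_gene_structures([self.gene], paths["gff3"], paths["sidecar"])
        write_gene_structures([strip_variant_annotation(self.gene)],
                              paths["gff3_bare"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


# -- low-level builders ----------------------------------------------------

def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein)


def _random_interior(rng: np.random.Generator, n: int,
                     alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _plain_intron(rng: np.random.Generator, lo: int, hi: int,
                  safe: bool = False) -> str:
    """GT..AG intron with a uniform random interior.

    ``safe`` interiors exclude G so the designed donor/acceptor are the only
    splice dinucleotides — used for the mini-introns between planted MXE
    variants, where an extra GT/AG would offer the detector a spurious
    frame-compatible window overlapping the plant.
    """
    n = int(rng.integers(lo, hi + 1))
    return "GT" + _random_interior(rng, n - 4, "ACT" if safe else "ACGT") + "AG"


SIMILARITY_TOL = 0.05


def _mutate_to_similarity(rng: np.random.Generator, anchor_aa: str,
                          target: float, delta: int) -> str:
    """Variant translation within ``SIMILARITY_TOL`` of the target score.

    The primary route replaces anchor residues one at a time with
    non-positive BLOSUM62 partners, re-measuring the score after each step,
    until the measured similarity enters the target band.  Edge residues
    stay identical to the anchor so the planted splice boundaries remain
    the similarity optimum (an in-frame truncation then never outscores the
    plant).  Because optimal realignment gives even unrelated sequences a
    background score around 0.25, targets below the reachable floor fall
    back to rejection-sampling random replacement sequences.
    """
    la = len(anchor_aa)
    if delta >= 0:
        mid = la // 2
        variant = list(anchor_aa[:mid] + _random_protein(rng, delta)
                       + anchor_aa[mid:])
        mutable = list(range(mid)) + list(range(mid + delta, la + delta))
    else:
        if la + delta < 3:
            raise SimulationError("length delta removes the whole exon")
        mid = la // 2
        variant = list(anchor_aa[:mid + delta // 2]
                       + anchor_aa[mid + delta // 2 - delta:])
        mutable = list(range(len(variant)))
    lv = len(variant)
    mutable = [p for p in mutable if 2 <= p < lv - 2]

    def measure(v):
        return score_exon_similarity("".join(v), anchor_aa)

    best, best_err = list(variant), abs(measure(variant) - target)
    current = list(variant)
    for pos in rng.permutation(mutable):
        s = measure(current)
        if s <= target + SIMILARITY_TOL:
            break
        old = current[pos]
        partners = _NONPOS_PARTNERS[old]
        current[pos] = partners[rng.integers(len(partners))]
        m = measure(current)
        err = abs(m - target)
        if err < best_err:
            best, best_err = list(current), err
        if m < target - SIMILARITY_TOL:
            current[pos] = old  # overshot the band; try another position
    if best_err <= SIMILARITY_TOL + 1e-9:
        return "".join(best)

    # rejection sampling for sub-background targets
    for _ in range(500):
        cand = list(_random_protein(rng, lv))
        err = abs(measure(cand) - target)
        if err < best_err:
            best, best_err = cand, err
        if best_err <= SIMILARITY_TOL + 1e-9:
            return "".join(best)
    raise SimulationError(
        f"could not hit target similarity {target:.2f} "
        f"(closest candidate is {best_err:.2f} away)"
    )


def _translate_nt(nt: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(nt).translate())


def _plant_is_unique_optimum(var_nt: str, lead: int, trail: int,
                             anchor_aa: str, plant_score: float) -> bool:
    """True iff no splice-context sub-window of the variant reaches the
    planted window's similarity.

    The detector accepts any AG..GT-bounded window whose length is frame
    compatible; a sub-window of the plant that scores at least as high
    would make the planted coordinates ambiguous as ground truth, so the
    generator redraws codons/mutations until the plant is the strict
    optimum of its hosting intron.
    """
    L = len(var_nt)
    for d in range(0, L - 8):
        if d and var_nt[d - 2:d] != "AG":
            continue
        for e in range(0, L - 8 - d):
            if d == 0 and e == 0:
                continue
            if (d + e) % 3 != 0:
                continue
            if e and var_nt[L - e:L - e + 2] != "GT":
                continue
            w = var_nt[d:L - e]
            core = w[lead: len(w) - trail]
            if len(core) < 9:
                continue
            aa = _translate_nt(core)
            if "*" in aa:
                continue
            if score_exon_similarity(aa, anchor_aa) >= plant_score - 1e-12:
                return False
    return True


def build_gene(
    protein: str,
    boundaries: list[int],
    clusters: list[ClusterSpec],
    rng: np.random.Generator,
    gene_id: str,
    species: str,
    intron_len_nt: tuple[int, int] = (20, 36),
    pad_intron_nt: tuple[int, int] = (8, 14),
    flank_nt: int = 25,
) -> SimulatedGene:
    """Assemble a plus-strand gene from a protein, intron boundary offsets
    (nt positions within the CDS), and planted cluster requests."""
    cds = _back_translate(rng, protein)
    n_nt = len(cds)
    bounds = [0] + sorted(boundaries) + [n_nt]
    if any(b <= 0 or b >= n_nt for b in boundaries):
        raise SimulationError("intron boundary outside the CDS")
    n_exons = len(bounds) - 1
    exon_nt = [cds[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
    by_anchor = {cl.anchor_exon_index: cl for cl in clusters}
    if len(by_anchor) != len(clusters):
        raise SimulationError("two clusters share one anchor exon")

    pieces = [_random_interior(rng, flank_nt)]
    pos = flank_nt
    exon_records: list[tuple[ExonLocus, int | None, float]] = []
    truth_clusters = []
    for i in range(n_exons):
        phase_in = bounds[i] % 3
        phase_out = bounds[i + 1] % 3
        lead = (3 - phase_in) % 3
        start = pos
        pieces.append(exon_nt[i])
        pos += len(exon_nt[i])
        role = "mxe_variant" if i in by_anchor else "constitutive"
        anchor_locus = ExonLocus(start=start, end=pos, phase_in=phase_in,
                                 phase_out=phase_out, role=role)
        exon_records.append((anchor_locus, by_anchor.get(i) and i, 1.0))
        if i in by_anchor:
            cl = by_anchor[i]
            aa_len = (len(exon_nt[i]) - lead - phase_out) // 3
            if aa_len < 1:
                raise SimulationError(
                    f"cluster at anchor {i}: anchor exon too short"
                )
            core = exon_nt[i][lead: lead + 3 * aa_len]
            from Bio.Seq import Seq
            anchor_aa = str(Seq(core).translate())
            trail_nt = exon_nt[i][lead + 3 * aa_len:]
            lead_nt = exon_nt[i][:lead]
            variant_info = []
            for _v in range(cl.n_variants - 1):
                pad = _plain_intron(rng, *pad_intron_nt, safe=True)
                pieces.append(pad)
                pos += len(pad)
                for _try in range(25):
                    var_aa = _mutate_to_similarity(rng, anchor_aa,
                                                   cl.similarity,
                                                   cl.length_delta_aa)
                    var_nt = (lead_nt + _back_translate(rng, var_aa)
                              + trail_nt)
                    sim_now = score_exon_similarity(var_aa, anchor_aa)
                    if _plant_is_unique_optimum(var_nt, lead, phase_out,
                                                anchor_aa, sim_now):
                        break
                else:
                    raise SimulationError(
                        f"cluster at anchor {i}: no identifiable variant "
                        f"after 25 draws"
                    )
                v_start = pos
                pieces.append(var_nt)
                pos += len(var_nt)
                locus = ExonLocus(start=v_start, end=pos, phase_in=phase_in,
                                  phase_out=phase_out, role="mxe_variant")
                sim = score_exon_similarity(var_aa, anchor_aa)
                exon_records.append((locus, i, sim))
                variant_info.append({"start": v_start, "end": pos,
                                     "similarity": sim,
                                     "length_aa": len(var_aa)})
            truth_clusters.append({"anchor_exon_spec_index": i,
                                   "target_similarity": cl.similarity,
                                   "length_delta_aa": cl.length_delta_aa,
                                   "variants": variant_info})
        if i < n_exons - 1:
            # the intron closing a variant-hosting gap is also kept free of
            # spurious splice dinucleotides
            intron = _plain_intron(rng, *intron_len_nt, safe=i in by_anchor)
            pieces.append(intron)
            pos += len(intron)
    pieces.append(_random_interior(rng, flank_nt))
    genome_seq = "".join(pieces)

    # assemble GeneStructure: records are already in genomic order
    exons = [rec[0] for rec in exon_records]
    gene_clusters = []
    anchor_to_members: dict[int, list[int]] = {}
    anchor_to_scores: dict[int, list[float]] = {}
    anchor_new_index: dict[int, int] = {}
    for new_idx, (locus, anchor, sim) in enumerate(exon_records):
        if anchor is None:
            continue
        anchor_to_members.setdefault(anchor, []).append(new_idx)
        anchor_to_scores.setdefault(anchor, []).append(sim)
        if locus.start == exons[new_idx].start and sim == 1.0 \
                and anchor not in anchor_new_index:
            anchor_new_index[anchor] = new_idx
    for k, anchor in enumerate(sorted(anchor_to_members)):
        members = anchor_to_members[anchor]
        gene_clusters.append(MXECluster(
            cluster_index_in_gene=k,
            variant_indices=members,
            annotated_index=anchor_new_index[anchor],
            scores=anchor_to_scores[anchor],
            flanking=(min(members) - 1, max(members) + 1),
        ))
    gene = GeneStructure(gene_id=gene_id, species=species,
                         sequence_id=f"{gene_id}_contig", strand="+",
                         exons=exons, clusters=gene_clusters)
    genome = SequenceRecord(id=f"{gene_id}_contig", residues=genome_seq,
                            alphabet="dna")
    # map spec anchor index -> cluster truth with final exon indices
    for tc, gc in zip(truth_clusters, gene_clusters):
        tc["cluster_index_in_gene"] = gc.cluster_index_in_gene
        tc["variant_exon_indices"] = list(gc.variant_indices)
        tc["annotated_exon_index"] = gc.annotated_index
    truth = {"gene_id": gene_id, "species": species,
             "n_exons_spec": n_exons, "clusters": truth_clusters,
             "boundaries_nt": list(bounds[1:-1])}
    return SimulatedGene(genome=genome, gene=gene, truth=truth,
                         protein=protein)


def simulate_gene(spec: GeneSimSpec) -> SimulatedGene:
    """Generate one gene (genome + structure + truth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    lens = [int(rng.integers(spec.exon_len_aa[0], spec.exon_len_aa[1] + 1))
            for _ in range(spec.n_exons)]
    protein = _random_protein(rng, sum(lens))
    boundaries = []
    cum = 0
    for L in lens[:-1]:
        cum += L
        boundaries.append(3 * cum + int(rng.integers(0, 3)) - 3)
    # keep boundaries strictly inside the CDS and increasing
    boundaries = sorted(set(max(1, b) for b in boundaries))
    if len(boundaries) != spec.n_exons - 1:
        raise SimulationError("exon boundaries collided; use longer exons")
    return build_gene(protein, boundaries, list(spec.clusters), rng,
                      spec.gene_id, spec.species,
                      intron_len_nt=spec.intron_len_nt,
                      pad_intron_nt=spec.pad_intron_nt)


def flip_to_minus_strand(sim: SimulatedGene) -> SimulatedGene:
    """The same gene on the minus strand of the reverse-complemented contig."""
    L = len(sim.genome.residues)
    genome = SequenceRecord(id=sim.genome.id,
                            residues=reverse_complement(sim.genome.residues),
                            alphabet="dna")
    exons = [ExonLocus(start=L - e.end, end=L - e.start, phase_in=e.phase_in,
                       phase_out=e.phase_out, role=e.role)
             for e in sim.gene.exons]
    gene = GeneStructure(gene_id=sim.gene.gene_id, species=sim.gene.species,
                         sequence_id=sim.gene.sequence_id, strand="-",
                         exons=exons, clusters=[MXECluster(
                             cluster_index_in_gene=c.cluster_index_in_gene,
                             variant_indices=list(c.variant_indices),
                             annotated_index=c.annotated_index,
                             scores=list(c.scores), flanking=c.flanking)
                             for c in sim.gene.clusters])
    return SimulatedGene(genome=genome, gene=gene, truth=sim.truth,
                         protein=sim.protein)


# -- homolog families ------------------------------------------------------

@dataclass
class HomologFamily:
    genes: list[GeneStructure]
    genomes: dict[str, SequenceRecord]
    msa: dict[str, str]
    truth: dict  # per-leaf intron fates + expected conservation groups


def simulate_homolog_family(
    tree: dendropy.Tree,
    n_exons: int = 10,
    exon_len_aa: tuple[int, int] = (15, 30),
    intron_loss_p: float = 0.3,
    intron_shift_p: float = 0.0,
    substitution_rate: float = 0.02,
    seed: int = 0,
    intron_len_nt: tuple[int, int] = (20, 36),
) -> HomologFamily:
    """Evolve an intron-rich ancestor gene down a tree.

    Exon interiors accumulate substitutions only (no indels), so the true
    MSA is ungapped; each ancestral intron is lost per branch with
    probability ``intron_loss_p`` and shifted by +/-1 nt with probability
    ``intron_shift_p``.
    """
    for p in (intron_loss_p, intron_shift_p):
        if not (0 <= p <= 1):
            raise SimulationError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lens = [int(rng.integers(exon_len_aa[0], exon_len_aa[1] + 1))
            for _ in range(n_exons)]
    total_aa = sum(lens)
    ancestor_protein = _random_protein(rng, total_aa)
    positions: dict[int, int] = {}
    cum = 0
    for k, L in enumerate(lens[:-1]):
        cum += L
        positions[k] = 3 * cum + int(rng.integers(0, 3)) - 3
    n_nt = 3 * total_aa

    def evolve(node, protein, introns):
        protein = list(protein)
        for i in range(len(protein)):
            if rng.random() < substitution_rate:
                choices = [a for a in AA20 if a != protein[i]]
                protein[i] = choices[rng.integers(len(choices))]
        protein = "".join(protein)
        introns = dict(introns)
        for iid in sorted(introns):
            if introns[iid] is None:
                continue
            if rng.random() < intron_loss_p:
                introns[iid] = None
            elif rng.random() < intron_shift_p:
                step = 1 if rng.random() < 0.5 else -1
                cand = introns[iid] + step
                taken = {v for j, v in introns.items()
                         if j != iid and v is not None}
                if 1 <= cand <= n_nt - 1 and cand not in taken:
                    introns[iid] = cand
        if node.is_leaf():
            return {node.taxon.label: (protein, introns)}
        out = {}
        for ch in node.child_nodes():
            out.update(evolve(ch, protein, introns))
        return out

    root = tree.seed_node
    leaf_states = {}
    for ch in root.child_nodes() or [root]:
        leaf_states.update(evolve(ch, ancestor_protein, positions))
    if root.is_leaf():
        leaf_states = evolve(root, ancestor_protein, positions)

    genes, genomes, msa = [], {}, {}
    fates = {}
    for leaf in sorted(leaf_states):
        protein, introns = leaf_states[leaf]
        kept = sorted(v for v in introns.values() if v is not None)
        sim = build_gene(protein, kept, [], rng, gene_id=f"{leaf}_Mhc1",
                         species=leaf, intron_len_nt=intron_len_nt)
        genes.append(sim.gene)
        genomes[sim.genome.id] = sim.genome
        msa[sim.gene.gene_id] = protein  # ungapped true homology
        fates[leaf] = {str(iid): introns[iid] for iid in sorted(introns)}

    groups: dict[tuple[int, int], list[str]] = {}
    for leaf in sorted(leaf_states):
        _, introns = leaf_states[leaf]
        for iid in sorted(introns):
            p = introns[iid]
            if p is None:
                continue
            groups.setdefault((p // 3, p % 3), []).append(f"{leaf}_Mhc1")
    truth = {
        "ancestral_intron_positions": positions,
        "leaf_intron_positions": fates,
        "conservation_groups": {f"{c}:{ph}": sorted(g)
                                for (c, ph), g in sorted(groups.items())},
    }
    return HomologFamily(genes=genes, genomes=genomes, msa=msa, truth=truth)


# -- presence/absence matrices --------------------------------------------

def simulate_matrix(
    tree: dendropy.Tree,
    events: EventMap,
    unknown_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leaf states from a planted event map, with unknown masking.

    Returns (masked matrix, unmasked truth matrix).
    """
    if not (0 <= unknown_rate <= 1):
        raise SimulationError("unknown_rate must be in [0, 1]")
    truth = replay_events(tree, events)
    rng = np.random.default_rng(seed)
    masked = truth.copy()
    if unknown_rate > 0:
        mask = rng.random(masked.shape) < unknown_rate
        masked = masked.mask(pd.DataFrame(mask, index=masked.index,
                                          columns=masked.columns), UNKNOWN)
    return masked, truth


def random_event_map(
    tree: dendropy.Tree,
    n_clusters: int,
    rng: np.random.Generator,
    loss_prob: float = 0.25,
) -> EventMap:
    """Random single-gain event maps for validation runs.

    The gain node is uniform over all tree nodes; each branch below the
    gain is independently lost with ``loss_prob``, without nesting (a lost
    subtree is not descended into).
    """
    nodes = list(tree.preorder_node_iter())
    events = EventMap()
    for k in range(n_clusters):
        cluster = f"cluster-{k}"
        gain = nodes[rng.integers(len(nodes))]
        losses: set[str] = set()

        def walk(node):
            for ch in node.child_nodes():
                if rng.random() < loss_prob:
                    losses.add(node_name(ch))
                else:
                    walk(ch)

        if not gain.is_leaf():
            walk(gain)
        events.gains[cluster] = node_name(gain)
        events.losses[cluster] = frozenset(losses)
    return events


# -- end-to-end study dataset ---------------------------------------------

#: fixed reference architecture: exon lengths (aa) of the synthetic myosin
#: stand-in; internal exon e anchors canonical cluster e-1 (clusters 0..11).
REFERENCE_EXON_LENS_AA = [20, 18, 22, 20, 24, 18, 20, 22, 16, 20, 18, 22, 20, 24]
#: within-codon offset of each internal intron boundary
REFERENCE_BOUNDARY_PHASES = [k % 3 for k in range(len(REFERENCE_EXON_LENS_AA) - 1)]

DEMO_TREE_NEWICK = (
    "((((PlatyA,PlatyB)Platyhelminthes,((AnnelidA,AnnelidB)Annelida,"
    "(MolluscA,MolluscB)Mollusca)AnnelidaMollusca)Lophotrochozoa,"
    "((ChelicerateA,MyriapodA)ChelicerMyriapod,(CrustaceanA,InsectA)"
    "Pancrustacea)Arthropoda)Protostomia,(DeuterostomeA,DeuterostomeB)"
    "Deuterostomia)Bilateria;"
)


def reference_boundaries() -> list[int]:
    out = []
    cum = 0
    for L, d in zip(REFERENCE_EXON_LENS_AA[:-1], REFERENCE_BOUNDARY_PHASES):
        cum += L
        out.append(3 * cum + d - 3)
    return out


def reference_anchor_intervals() -> list[dict]:
    """Canonical cluster anchors (MSA columns) of the reference
    architecture: cluster c sits on internal exon c+1."""
    bounds = [0] + reference_boundaries() + [3 * sum(REFERENCE_EXON_LENS_AA)]
    labels = {
        0: "loop-1/switch-1 (ctenophore)", 1: "SH3-motor junction",
        2: "P-loop/loop-1", 3: "loop-1 to switch-1", 4: "upper 50 kDa domain",
        5: "fiber-kinetics region", 6: "loop-4", 7: "relay helix/loop",
        8: "loop-2 C-terminus", 9: "central beta-sheet strand",
        10: "converter", 11: "coiled-coil hinge",
    }
    anchors = []
    for cid in range(12):
        e = cid + 1
        nt0, nt1 = bounds[e], bounds[e + 1]
        # complete codons only, so neighbouring anchors never share the
        # codon split by a phase-1/2 intron
        anchors.append({"cluster_id": cid, "col_start": (nt0 + 2) // 3,
                        "col_end": nt1 // 3, "label": labels[cid]})
    return anchors


def demo_event_map() -> EventMap:
    """Planted gain/loss history of the demo study: the bilaterian cluster-8,
    the five protostome clusters, the three arthropod clusters, the
    annelid/mollusc cluster-3 and the annelid-private cluster-4."""
    ev = EventMap()
    ev.gains = {
        "cluster-8": "Bilateria",
        "cluster-2": "Protostomia", "cluster-5": "Protostomia",
        "cluster-6": "Protostomia", "cluster-9": "Protostomia",
        "cluster-11": "Protostomia",
        "cluster-1": "Arthropoda", "cluster-7": "Arthropoda",
        "cluster-10": "Arthropoda",
        "cluster-3": "AnnelidaMollusca",
        "cluster-4": "AnnelidB",
    }
    ev.losses = {
        "cluster-2": frozenset({"Platyhelminthes", "MyriapodA"}),
        "cluster-5": frozenset({"Platyhelminthes"}),
        "cluster-6": frozenset({"Platyhelminthes", "ChelicerMyriapod",
                                "InsectA"}),
        "cluster-9": frozenset({"Platyhelminthes", "InsectA"}),
        "cluster-11": frozenset({"Platyhelminthes"}),
        "cluster-8": frozenset({"MolluscA"}),
        "cluster-1": frozenset({"ChelicerateA"}),
        "cluster-7": frozenset(),
        "cluster-10": frozenset({"MyriapodA"}),
        "cluster-3": frozenset({"AnnelidA"}),
        "cluster-4": frozenset(),
    }
    return ev


def strip_variant_annotation(gene: GeneStructure) -> GeneStructure:
    """The gene as an annotation pipeline would first see it: only the
    reference-transcript exons, all marked constitutive, no clusters."""
    from dataclasses import replace as _replace

    keep = gene.reference_exon_indices()
    exons = [_replace(gene.exons[i], role="constitutive") for i in keep]
    return GeneStructure(gene_id=gene.gene_id, species=gene.species,
                         sequence_id=gene.sequence_id, strand=gene.strand,
                         exons=exons, clusters=[])


@dataclass
class StudyDataset:
    genes_full: list[GeneStructure]   # with planted variants + clusters
    genomes: dict[str, SequenceRecord]
    msa: dict[str, str]
    tree_newick: str
    truth_events: EventMap
    truth_presence: pd.DataFrame
    species: list[str]

    @property
    def genes_bare(self) -> list[GeneStructure]:
        return [strip_variant_annotation(g) for g in self.genes_full]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .gene_model import write_fasta, write_gene_structures
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genomes.fasta",
            "gff3": outdir / "genes.gff3",
            "gff3_truth": outdir / "genes_with_planted_variants.gff3",
            "sidecar": outdir / "clusters_truth.yaml",
            "msa": outdir / "proteins_aligned.fasta",
            "tree": outdir / "species.nwk",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genomes.values(), paths["fasta"])
        write_gene_structures(self.genes_bare, paths["gff3"])
        write_gene_structures(self.genes_full, paths["gff3_truth"],
                              paths["sidecar"])
        write_fasta([SequenceRecord(id=g, residues=row, alphabet="protein")
                     for g, row in sorted(self.msa.items())], paths["msa"])
        paths["tree"].write_text(self.tree_newick + "\n")
        paths["truth"].write_text(json.dumps({
            "gains": self.truth_events.gains,
            "losses": {c: sorted(s) for c, s in self.truth_events.losses.items()},
            "presence": {sp: {c: str(self.truth_presence.loc[sp, c])
                              for c in self.truth_presence.columns}
                         for sp in self.truth_presence.index},
        }, indent=2, sort_keys=True))
        return paths


def simulate_study(
    seed: int = 0,
    tree_newick: str = DEMO_TREE_NEWICK,
    events: EventMap | None = None,
    similarity: float = 0.6,
    substitution_rate: float = 0.02,
) -> StudyDataset:
    """One gene per species on the reference architecture, with MXE clusters
    planted per species according to a gain/loss history on the tree."""
    from .dollo import load_tree

    tree = load_tree(tree_newick, from_string=True)
    events = events if events is not None else demo_event_map()
    presence = replay_events(tree, events)
    rng = np.random.default_rng(seed)
    base_protein = _random_protein(rng, sum(REFERENCE_EXON_LENS_AA))
    bounds = reference_boundaries()
    genes, genomes, msa = [], {}, {}
    for sp in sorted(presence.index):
        protein = list(base_protein)
        for i in range(len(protein)):
            if rng.random() < substitution_rate:
                choices = [a for a in AA20 if a != protein[i]]
                protein[i] = choices[rng.integers(len(choices))]
        protein = "".join(protein)
        clusters = []
        for col in presence.columns:
            if presence.loc[sp, col] != PRESENT:
                continue
            cid = int(col.split("-")[1])
            clusters.append(ClusterSpec(anchor_exon_index=cid + 1,
                                        similarity=similarity))
        sim = build_gene(protein, bounds, clusters, rng,
                         gene_id=f"{sp}_Mhc1", species=sp)
        genes.append(sim.gene)
        genomes[sim.genome.id] = sim.genome
        msa[sim.gene.gene_id] = protein
    return StudyDataset(genes_full=genes, genomes=genomes, msa=msa,
                        tree_newick=tree_newick, truth_events=events,
                        truth_presence=presence,
                        species=sorted(presence.index))
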