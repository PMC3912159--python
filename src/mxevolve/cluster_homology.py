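"""Canonical MXE cluster labelling and per-species presence collapsing.

Conserved MXE clusters of the muscle myosin heavy chain gene are numbered
0-11 from N- to C-terminus of the protein (cluster-0 is the ctenophore-only
cluster; cluster-8, covering the C-terminal part of loop-2, is the ancestral
bilaterian one).  A detected cluster in a new gene is recognised as, say,
"cluster-9" purely by position: its projected MSA column span is compared
with a fixture of anchor intervals on a reference alignment, and the anchor
with the largest fractional overlap wins when that fraction reaches a
configurable threshold (default 0.5).  Clusters overlapping no anchor are
*novel* and receive provisional ids ordered N->C.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import MxevolveError

PRESENT, ABSENT, UNKNOWN = "P", "A", "U"


@dataclass(frozen=True)
class CanonicalClusterAnchor:
    cluster_id: int
    col_start: int
    col_end: int
    label: str


@dataclass
class LabeledCluster:
    gene_id: str
    species: str
    cluster_index_in_gene: int
    canonical: str            # "cluster-<n>" or "novel-<k>"
    variant_count: int
    overlap_fraction: float   # vs the winning anchor; 0.0 for novel
    flagged_for_review: bool = False


@dataclass
class ClusterInventory:
    """Species x canonical-cluster states in {present, absent, unknown}."""

    table: pd.DataFrame       # index species, columns canonical ids, P/A/U
    provenance: dict[tuple[str, str], str]


def load_anchors(path: str | Path | None = None) -> list[CanonicalClusterAnchor]:
    """Load canonical anchors from YAML (packaged reference fixture by
    default)."""
    if path is None:
        ref = resources.files("mxevolve.data") / "synthetic_reference_anchors.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    anchors = [CanonicalClusterAnchor(cluster_id=int(a["cluster_id"]),
                                      col_start=int(a["col_start"]),
                                      col_end=int(a["col_end"]),
                                      label=str(a.get("label", "")))
               for a in raw["anchors"]]
    anchors.sort(key=lambda a: a.col_start)
    prev_end = -1
    for a in anchors:
        if a.col_start < prev_end:
            raise MxevolveError("anchor intervals overlap")
        if a.col_end <= a.col_start:
            raise MxevolveError(f"anchor {a.cluster_id}: empty interval")
        prev_end = a.col_end
    return anchors


def assign_canonical_labels(
    gene_spans: list[tuple[str, str, int, int, int, int]],
    anchors: list[CanonicalClusterAnchor],
    min_overlap: float = 0.5,
) -> list[LabeledCluster]:
    """Label projected clusters with canonical ids.

    ``gene_spans`` rows are (gene_id, species, cluster_index_in_gene,
    col_start, col_end, variant_count).  Each anchor claims at most one
    cluster per gene (highest overlap wins; the loser is flagged for review
    and falls back to a novel id).
    """
    per_gene: dict[str, list] = {}
    for row in gene_spans:
        per_gene.setdefault(row[0], []).append(row)

    labels: list[LabeledCluster] = []
    for gid in sorted(per_gene):
        rows = sorted(per_gene[gid], key=lambda r: r[3])
        scored = []
        for (gene_id, species, idx, c0, c1, nvar) in rows:
            span_len = c1 - c0
            if span_len <= 0:
                raise MxevolveError(f"gene {gene_id}: empty cluster span")
            best, best_frac = None, 0.0
            for a in anchors:
                ov = max(0, min(c1, a.col_end) - max(c0, a.col_start))
                frac = ov / span_len
                if frac > best_frac:
                    best, best_frac = a, frac
            scored.append([gene_id, species, idx, c0, c1, nvar,
                           best, best_frac])
        # each anchor claims at most one cluster per gene
        claimed: dict[int, list] = {}
        for rec in scored:
            if rec[6] is not None and rec[7] >= min_overlap:
                claimed.setdefault(rec[6].cluster_id, []).append(rec)
        flagged_ids = set()
        for cid, recs in claimed.items():
            recs.sort(key=lambda r: -r[7])
            for loser in recs[1:]:
                loser[6] = None
                flagged_ids.add(id(loser))
        novel_counter = 0
        for rec in scored:  # already ordered N->C by col_start
            gene_id, species, idx, c0, c1, nvar, anchor, frac = rec
            if anchor is not None and frac >= min_overlap:
                labels.append(LabeledCluster(
                    gene_id=gene_id, species=species,
                    cluster_index_in_gene=idx,
                    canonical=f"cluster-{anchor.cluster_id}",
                    variant_count=nvar, overlap_fraction=frac,
                ))
            else:
                novel_counter += 1
                labels.append(LabeledCluster(
                    gene_id=gene_id, species=species,
                    cluster_index_in_gene=idx,
                    canonical=f"novel-{novel_counter}",
                    variant_count=nvar, overlap_fraction=0.0,
                    flagged_for_review=id(rec) in flagged_ids,
                ))
    return labels


def collapse_species_presence(
    labels: list[LabeledCluster],
    species_list: list[str],
    anchors: list[CanonicalClusterAnchor],
    gap_annotations: set[tuple[str, int]] | None = None,
) -> ClusterInventory:
    """Collapse per-gene labels into a species x cluster inventory.

    A species is *present* for a canonical cluster iff any of its genes
    carries it; *unknown* only where a genome-assembly gap annotation covers
    the anchor region and no gene shows the cluster; *absent* otherwise.
    """
    gaps = gap_annotations or set()
    known_species = set(species_list)
    for lab in labels:
        if lab.species not in known_species:
            raise MxevolveError(f"species {lab.species!r} not in species list")
    cluster_ids = [a.cluster_id for a in sorted(anchors, key=lambda a: a.cluster_id)]
    cols = [f"cluster-{cid}" for cid in cluster_ids]
    table = pd.DataFrame(ABSENT, index=list(species_list), columns=cols)
    provenance: dict[tuple[str, str], str] = {}
    for sp in species_list:
        for cid in cluster_ids:
            if (sp, cid) in gaps:
                table.loc[sp, f"cluster-{cid}"] = UNKNOWN
                provenance[(sp, f"cluster-{cid}")] = "assembly gap over anchor"
    for lab in labels:
        if not lab.canonical.startswith("cluster-"):
            continue
        table.loc[lab.species, lab.canonical] = PRESENT
        key = (lab.species, lab.canonical)
        provenance[key] = (provenance.get(key, "") + f"+{lab.gene_id}").lstrip("+")
    return ClusterInventory(table=table, provenance=provenance)


def read_inventory_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    bad = set(df.values.ravel()) - {PRESENT, ABSENT, UNKNOWN}
    if bad:
        raise MxevolveError(f"inventory states outside P/A/U: {sorted(bad)}")
    return df


def write_inventory_tsv(inventory: ClusterInventory | pd.DataFrame,
                        path: str | Path,
                        header_lines: list[str] | None = None) -> None:
    df = inventory.table if isinstance(inventory, ClusterInventory) else inventory
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index_label="species")


def load_reference_inventory() -> pd.DataFrame:
    """The packaged per-species MXE cluster inventory of the myosin heavy
    chain survey (states P/A/U, species rows as stated in the Results)."""
    ref = resources.files("mxevolve.data") / "mhc_cluster_inventory.tsv"
    import io
    return read_inventory_tsv(io.StringIO(ref.read_text()))
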