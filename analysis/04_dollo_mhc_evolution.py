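#!/usr/bin/env python
"""Gain and loss of MXE clusters across the metazoan Mhc survey inventory.

Runs Dollo parsimony (single gain at the carriers' LCA, minimal subsequent
losses) on the packaged per-species cluster inventory over the reference
species topology, and prints the per-branch event summary: one cluster
(cluster-8, loop-2) at the bilaterian root, five clusters at the
Protostomia LCA, three more at the arthropod LCA, with wholesale losses on
the nematode and platyhelminth branches.

Writes results/mhc_cluster_events.tsv.
"""

from importlib import resources
from pathlib import Path

from mxevolve.cluster_homology import load_reference_inventory
from mxevolve.dollo import (
    dollo_reconstruct,
    gained_clusters,
    load_tree,
    lost_clusters,
    write_events_tsv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    tree = load_tree(str(resources.files("mxevolve.data")
                         / "metazoa_mhc_tree.nwk"))
    inv = load_reference_inventory()
    events = dollo_reconstruct(inv, tree)

    RESULTS.mkdir(exist_ok=True)
    write_events_tsv(events, RESULTS / "mhc_cluster_events.tsv")

    for node in ("Eumetazoa", "Bilateria", "Protostomia",
                 "AnnelidaMollusca", "Arthropoda"):
        g = gained_clusters(events, node)
        if g:
            print(f"gains at {node}: {', '.join(sorted(g))}")
    print(f"gains at Mnemiopsis_leidyi (ctenophore): "
          f"{', '.join(gained_clusters(events, 'Mnemiopsis_leidyi'))}")
    for branch in ("Caenorhabditis_elegans", "Platyhelminthes",
                   "Lepeophtheirus_salmonis", "Helobdella_robusta"):
        print(f"losses on branch to {branch}: "
              f"{', '.join(lost_clusters(events, branch)) or 'none'}")
    print(f"wrote {RESULTS / 'mhc_cluster_events.tsv'}")


if __name__ == "__main__":
    main()
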