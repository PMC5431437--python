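"""Pathway mapping and the compound-target-pathway view.

Maps the kept-network targets onto the three disease-relevant signalling
pathways of the study design (NO/cGMP, Ras kinase, VEGF) using a
synthetic membership table (the curated pathway assignments are not
published), counts compounds reaching each pathway, and exports the
tripartite C-T-P network.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from formulanet.adme_screen import screen_library
from formulanet.core_data import default_whitelist, load_fixture
from formulanet.ct_network import build_network
from formulanet.pathway_map import PathwayTable, build_ctp_network, compounds_per_pathway, map_targets
from formulanet.synthetic_data import SimulationConfig, generate_scores, generate_targets
from formulanet.target_consensus import consensus_filter

PATHWAYS = ("NO/cGMP", "Ras", "VEGF")


def synthetic_pathway_table(targets: list[str], seed: int) -> PathwayTable:
    """Assign ~20% of targets to each pathway (overlaps allowed)."""
    rng = np.random.default_rng(seed + 3)
    membership = {
        p: frozenset(t for t in targets if rng.random() < 0.2) for p in PATHWAYS
    }
    return PathwayTable(membership)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", default=1, type=int)
    parser.add_argument("--out-dir", default="results", type=Path)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table1 = load_fixture("table1")
    retained = table1.subset(screen_library(table1, default_whitelist()).retained)
    config = SimulationConfig(seed=args.seed)
    all_targets = generate_targets(config)
    scores, _ = generate_scores(retained, all_targets, config)
    net = build_network(consensus_filter(scores), retained)

    table = synthetic_pathway_table(all_targets, args.seed)
    mapping, unmapped = map_targets(net.target_nodes, table)
    counts = compounds_per_pathway(net, mapping)
    build_ctp_network(net, mapping, args.out_dir / "ctp_network.graphml")

    pd.DataFrame(
        [
            {"pathway": p, "targets": len(mapping[p]), "compounds": counts[p]}
            for p in PATHWAYS
        ]
    ).to_csv(args.out_dir / "pathway_counts.tsv", sep="\t", index=False)

    for p in PATHWAYS:
        print(
            f"{p:<8s} {len(mapping[p]):>3d} network targets, "
            f"{counts[p]:>2d}/{len(net.compound_nodes)} compounds participate"
        )
    print(f"{len(unmapped)} network targets on no modelled pathway")
    print(f"wrote {args.out_dir / 'pathway_counts.tsv'}")


if __name__ == "__main__":
    main()
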