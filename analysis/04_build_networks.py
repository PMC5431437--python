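"""Compound-target networks for the three disease axes.

From the kept interactions of the previous step, builds the three
sub-networks of the study design - vascular (Gymnadenia Conopsea,
Stigma Croci, Myristica Semena), CNS (Semen Strychni, Myristica Semena)
and hormone (Gymnadenia Conopsea, Rhizoma Alpiniae Officinarum,
Boswellia, Syringa Oblata) - and reports compound counts, mean targets
per compound, and the shared/specific target partition per network.
"""

import argparse
from pathlib import Path

import pandas as pd

from formulanet.adme_screen import screen_library
from formulanet.core_data import default_whitelist, load_fixture
from formulanet.ct_network import (
    build_network,
    degree_stats,
    export_network,
    overlap_percentage,
    partition_targets,
)
from formulanet.synthetic_data import SimulationConfig, generate_scores, generate_targets
from formulanet.target_consensus import consensus_filter

AXES = {
    "vascular": ["Gymnadenia Conopsea", "Stigma Croci", "Myristica Semena"],
    "cns": ["Semen Strychni", "Myristica Semena"],
    "hormone": [
        "Gymnadenia Conopsea",
        "Rhizoma Alpiniae Officinarum",
        "Boswellia",
        "Syringa Oblata",
    ],
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", default=1, type=int)
    parser.add_argument("--out-dir", default="results", type=Path)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table1 = load_fixture("table1")
    retained = table1.subset(screen_library(table1, default_whitelist()).retained)
    config = SimulationConfig(seed=args.seed)
    scores, _ = generate_scores(retained, generate_targets(config), config)
    kept = consensus_filter(scores)

    rows = []
    for axis, herbs in AXES.items():
        members = {rec.compound_id for h in herbs for rec in retained.by_herb(h)}
        axis_kept = [x for x in kept if x.compound_id in members]
        net = build_network(axis_kept, retained, keep_isolated=members)
        export_network(net, "edge-tsv", args.out_dir / f"ct_{axis}.tsv")
        stats = degree_stats(net)
        part = partition_targets(net, herbs)
        shared_pct = (
            overlap_percentage(len(part.shared_targets), len(net.target_nodes))
            if net.target_nodes
            else 0.0
        )
        rows.append(
            {
                "network": axis,
                "compounds": len(net.compound_nodes),
                "targets": len(net.target_nodes),
                "edges": len(net.edges),
                "mean_targets_per_compound": stats.mean_targets_per_compound,
                "shared_targets": len(part.shared_targets),
                "shared_percent": shared_pct,
            }
        )
        print(
            f"{axis}: {len(net.compound_nodes)} compounds, "
            f"{len(net.target_nodes)} targets, {len(net.edges)} edges; "
            f"{len(part.shared_targets)} targets ({shared_pct}%) shared by all "
            f"{len(herbs)} herbs"
        )

    summary = pd.DataFrame(rows)
    summary.to_csv(args.out_dir / "network_summary.tsv", sep="\t", index=False)
    print(f"wrote {args.out_dir / 'network_summary.tsv'}")


if __name__ == "__main__":
    main()
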