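"""Stage-chaining pipeline: screen -> consensus -> networks -> comparison.

Each stage reads/writes TSV artifacts under an output directory and logs
record counts in and out, so the per-stage attrition is machine-readable.
A manifest (JSON) records the seed and a hash of the effective
configuration; a rerun with identical config and inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .adme_screen import ScreenConfig, screen_library
from .core_data import (
    CompoundLibrary,
    default_whitelist,
    load_fixture,
    read_annotation_table,
    read_compound_table,
    write_annotation_table,
    write_compound_table,
)
from .ct_network import build_network, degree_stats, export_network, partition_targets
from .formula_compare import (
    DEFAULT_SHARED_FRACTION_THRESHOLD,
    compare_formulae,
    removal_verdict,
)
from .herb_mining import DEFAULT_ALPHA, rank_herbs, read_counts_table
from .pathway_map import build_ctp_network, compounds_per_pathway, map_targets, read_pathway_table
from .synthetic_data import (
    SimulationConfig,
    generate_formula_pair,
    generate_scores,
    generate_targets,
)
from .target_consensus import (
    ConsensusConfig,
    consensus_filter,
    read_score_table,
    write_score_table,
)

logger = logging.getLogger("formulanet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``compound_table`` may be a TSV path or ``"fixture:table1"`` /
    ``"fixture:table3"``. When ``simulate`` is true, score tables,
    formula-pair networks and annotations are generated from
    ``simulation`` instead of read from files.
    """

    out_dir: Path = Path("pipeline_out")
    seed: int = 0
    compound_table: str = "fixture:table1"
    whitelist: Optional[tuple[str, ...]] = None  # None -> fixture default
    counts_table: Optional[str] = None
    score_table: Optional[str] = None
    annotation_table: Optional[str] = None
    pathway_table: Optional[str] = None
    simulate: bool = True
    run_mine: bool = True
    run_screen: bool = True
    run_targets: bool = True
    run_network: bool = True
    run_compare: bool = True
    run_pathways: bool = True
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    comparison_threshold: float = DEFAULT_SHARED_FRACTION_THRESHOLD
    mining_alpha: float = DEFAULT_ALPHA
    simulation: Optional[SimulationConfig] = None

    def effective_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (Path, frozenset, set, tuple, list)):
                if isinstance(obj, (frozenset, set)):
                    return sorted(str(x) for x in obj)
                if isinstance(obj, Path):
                    return str(obj)
                return [encode(x) for x in obj]
            return obj

        payload = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_library(config: PipelineConfig) -> CompoundLibrary:
    if config.compound_table.startswith("fixture:"):
        return load_fixture(config.compound_table.split(":", 1)[1])
    return read_compound_table(config.compound_table)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"formulanet {__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    sim = config.effective_simulation()

    library = _load_library(config)
    write_compound_table(library, out / "input_compounds.tsv")

    retained_library = library
    if config.run_screen:
        whitelist = (
            default_whitelist() & frozenset(library.ids)
            if config.whitelist is None
            else frozenset(config.whitelist)
        )
        result = screen_library(library, whitelist, config.screen)
        result.to_frame(library).to_csv(out / "screen_report.tsv", sep="\t", index=False)
        result.per_herb_frame().to_csv(out / "per_herb.tsv", sep="\t", index=False)
        retained_library = library.subset(result.retained)
        manifest["stages"]["screen"] = {
            "in": len(library),
            "strict_pass": len(result.strict_pass),
            "rescued": len(result.rescued),
            "retained": len(result.retained),
        }
        logger.info(
            "screen: %d in, %d strict, %d rescued, %d retained",
            len(library),
            len(result.strict_pass),
            len(result.rescued),
            len(result.retained),
        )

    if config.run_mine and config.counts_table:
        batch = read_counts_table(config.counts_table)
        table = rank_herbs(batch, config.mining_alpha)
        table.to_csv(out / "herb_associations.tsv", sep="\t", index=False)
        manifest["stages"]["mine"] = {
            "in": len(table),
            "significant": int(table["significant"].sum()),
        }

    kept = None
    if config.run_targets:
        if config.score_table:
            scores = read_score_table(config.score_table)
        elif config.simulate:
            scores, _ = generate_scores(
                retained_library, generate_targets(sim), sim,
                rf_min=config.consensus.rf_min, svm_min=config.consensus.svm_min,
            )
        else:
            raise ValueError("targets stage needs a score table or simulate=True")
        kept = consensus_filter(scores, config.consensus)
        write_score_table(kept, out / "kept_interactions.tsv")
        manifest["stages"]["targets"] = {"in": len(scores), "kept": len(kept)}
        logger.info("targets: %d scored, %d kept", len(scores), len(kept))

    net = None
    if config.run_network and kept is not None:
        net = build_network(kept, retained_library)
        export_network(net, "edge-tsv", out / "ct_network.tsv")
        export_network(net, "sif", out / "ct_network.sif")
        stats = degree_stats(net) if net.compound_nodes else None
        groups = sorted(net.groups())
        rows = []
        if groups and net.target_nodes:
            part = partition_targets(net, groups)
            rows = part.to_frame(len(net.target_nodes)).to_dict("records")
        pd.DataFrame(rows).to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "compounds": len(net.compound_nodes),
            "targets": len(net.target_nodes),
            "edges": len(net.edges),
            "mean_targets_per_compound": (
                stats.mean_targets_per_compound if stats else None
            ),
        }

    if config.run_compare:
        if config.simulate:
            net_a, net_b, annotations = generate_formula_pair(sim)
            write_annotation_table(annotations, out / "annotations.tsv")
        else:
            raise ValueError(
                "compare stage is driven by simulated formula pairs unless "
                "invoked through the compare CLI subcommand on edge TSVs"
            )
        if config.annotation_table:
            annotations = read_annotation_table(config.annotation_table)
        report = compare_formulae(net_a, net_b, annotations)
        verdict = removal_verdict(report, config.comparison_threshold)
        frame = pd.DataFrame(
            [
                {
                    "shared": len(report.shared_targets),
                    "a_specific": len(report.a_specific),
                    "b_specific": len(report.b_specific),
                    "shared_fraction": report.shared_fraction,
                    "b_specific_disease_linked": len(report.b_specific_disease_linked),
                    "removable": verdict.removable,
                }
            ]
        )
        frame.to_csv(out / "comparison_report.tsv", sep="\t", index=False)
        (out / "verdict.txt").write_text(
            f"removable={verdict.removable}\n" + "\n".join(verdict.reasons) + "\n"
        )
        manifest["stages"]["compare"] = {
            "shared_fraction": report.shared_fraction,
            "removable": verdict.removable,
        }

    if config.run_pathways and config.pathway_table and net is not None:
        table = read_pathway_table(config.pathway_table)
        mapping, unmapped = map_targets(net.target_nodes, table)
        counts = compounds_per_pathway(net, mapping)
        pd.DataFrame(
            [
                {
                    "pathway": p,
                    "targets": len(mapping[p]),
                    "compounds": counts[p],
                }
                for p in sorted(mapping)
            ]
        ).to_csv(out / "pathway_counts.tsv", sep="\t", index=False)
        build_ctp_network(net, mapping, out / "ctp_network.graphml")
        manifest["stages"]["pathways"] = {
            "pathways": len(mapping),
            "unmapped_targets": len(unmapped),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
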