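"""Mapping consensus targets onto disease pathways; C-T-P tripartite view.

Pathway membership is a caller-supplied annotation table (pathway ->
target ids), typically the disease-relevant pathways curated for the
indication — e.g. the NO/cGMP, Ras kinase and VEGF signalling pathways
for erectile dysfunction. No live pathway database is queried.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .ct_network import BipartiteNetwork

__all__ = [
    "PathwayTable",
    "map_targets",
    "compounds_per_pathway",
    "build_ctp_network",
    "read_pathway_table",
]


@dataclass(frozen=True)
class PathwayTable:
    """Pathway name -> member target ids; a target may sit in several."""

    membership: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name in self.membership:
            if not name:
                raise ValueError("pathway names must be non-empty")

    @property
    def pathways(self) -> list[str]:
        return list(self.membership)

    def targets(self) -> set[str]:
        out: set[str] = set()
        for members in self.membership.values():
            out |= set(members)
        return out


def read_pathway_table(path: str | Path) -> PathwayTable:
    """Read a long-form pathway TSV (pathway, target)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"pathway", "target"} - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    membership: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        membership.setdefault(str(row_map["pathway"]), set()).add(
            str(row_map["target"])
        )
    return PathwayTable({p: frozenset(t) for p, t in membership.items()})


def map_targets(
    targets: Iterable[str], table: PathwayTable
) -> tuple[dict[str, set[str]], set[str]]:
    """Intersect a target set with each pathway's membership.

    Returns ``(per-pathway hits, targets in no pathway)``.
    """
    target_set = set(targets)
    mapping = {
        pathway: target_set & set(members)
        for pathway, members in table.membership.items()
    }
    unmapped = target_set - table.targets()
    return mapping, unmapped


def compounds_per_pathway(
    net: BipartiteNetwork, mapping: Mapping[str, Iterable[str]]
) -> dict[str, int]:
    """Count compounds with >= 1 edge into each pathway's targets.

    A compound hitting targets in several pathways counts once in each.
    """
    counts: dict[str, int] = {}
    for pathway, targets in mapping.items():
        target_set = set(targets)
        compounds = {c for c, t in net.edges if t in target_set}
        counts[pathway] = len(compounds)
    return counts


def build_ctp_network(
    net: BipartiteNetwork,
    mapping: Mapping[str, Iterable[str]],
    path: str | Path,
    fmt: str = "graphml",
) -> Path:
    """Overlay the C-T network with target-pathway (T-P) edges and export.

    Node roles: compound, target, pathway; edge roles: ct, tp. Exported
    as GraphML or a long-form edge TSV (source, target, interaction).
    Only T-P edges whose target appears in the C-T network are drawn;
    others would be unconnected and are dropped.
    """
    path = Path(path)
    tp_edges = sorted(
        (t, p)
        for p, targets in mapping.items()
        for t in targets
        if t in net.target_nodes
    )
    if fmt == "graphml":
        g = nx.Graph()
        for c in sorted(net.compound_nodes):
            g.add_node(c, role="compound")
        for t in sorted(net.target_nodes):
            g.add_node(t, role="target")
        for p in sorted(mapping):
            g.add_node(p, role="pathway")
        for c, t in sorted(net.edges):
            g.add_edge(c, t, interaction="ct")
        for t, p in tp_edges:
            g.add_edge(t, p, interaction="tp")
        nx.write_graphml(g, path)
    elif fmt == "edge-tsv":
        rows = [
            {"source": c, "target": t, "interaction": "ct"}
            for c, t in sorted(net.edges)
        ] + [{"source": t, "target": p, "interaction": "tp"} for t, p in tp_edges]
        pd.DataFrame(rows, columns=["source", "target", "interaction"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
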