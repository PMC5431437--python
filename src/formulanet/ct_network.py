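"""Bipartite compound-target networks and their summary statistics.

The network statistics mirror what practitioners read off a Cytoscape
view of a compound-target (C-T) graph: node degrees, the mean number of
targets per compound, and the partition of the target side into targets
shared by every herb group, targets specific to one group, and the rest.
Percentages are rounded half-up so they match hand-computed figures
(67/132 -> 50.76).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .core_data import CompoundLibrary, ValidationError
from .target_consensus import ScoredInteraction

__all__ = [
    "BipartiteNetwork",
    "OverlapPartition",
    "DegreeStats",
    "build_network",
    "degree_stats",
    "partition_targets",
    "overlap_percentage",
    "export_network",
    "read_edge_tsv",
    "round_half_up",
]

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BipartiteNetwork:
    """Compound and target node sets with deduplicated edges.

    ``group_of_compound`` maps each compound to the herb/component groups
    it belongs to; a multi-herb compound contributes its targets to every
    group it is attributed to.
    """

    compound_nodes: frozenset[str]
    target_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    group_of_compound: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, target in self.edges:
            if compound not in self.compound_nodes:
                raise ValidationError(f"edge endpoint {compound!r} not a compound node")
            if target not in self.target_nodes:
                raise ValidationError(f"edge endpoint {target!r} not a target node")

    def compound_degree(self) -> dict[str, int]:
        deg = {c: 0 for c in self.compound_nodes}
        for compound, _ in self.edges:
            deg[compound] += 1
        return deg

    def target_degree(self) -> dict[str, int]:
        deg = {t: 0 for t in self.target_nodes}
        for _, target in self.edges:
            deg[target] += 1
        return deg

    def targets_of_group(self, group: str) -> set[str]:
        """Targets hit by at least one compound of *group*."""
        members = {
            c for c, groups in self.group_of_compound.items() if group in groups
        }
        return {t for c, t in self.edges if c in members}

    def groups(self) -> set[str]:
        out: set[str] = set()
        for groups in self.group_of_compound.values():
            out |= set(groups)
        return out


@dataclass(frozen=True)
class OverlapPartition:
    """Disjoint cover of the target side by group membership."""

    groups: tuple[str, ...]
    shared_targets: frozenset[str]
    specific_targets: Mapping[str, frozenset[str]]
    other_targets: frozenset[str]

    def to_frame(self, total_targets: int) -> pd.DataFrame:
        rows = [
            {
                "group": "shared(all)",
                "count": len(self.shared_targets),
                "percentage": overlap_percentage(
                    len(self.shared_targets), total_targets
                )
                if total_targets
                else 0.0,
            }
        ]
        for group in self.groups:
            n = len(self.specific_targets[group])
            rows.append(
                {
                    "group": f"specific:{group}",
                    "count": n,
                    "percentage": overlap_percentage(n, total_targets)
                    if total_targets
                    else 0.0,
                }
            )
        rows.append(
            {
                "group": "other",
                "count": len(self.other_targets),
                "percentage": overlap_percentage(
                    len(self.other_targets), total_targets
                )
                if total_targets
                else 0.0,
            }
        )
        return pd.DataFrame(rows, columns=["group", "count", "percentage"])


@dataclass(frozen=True)
class DegreeStats:
    compound_degree: Mapping[str, int]
    target_degree: Mapping[str, int]
    mean_targets_per_compound: float
    max_degree_compound: str
    max_degree_target: str


def build_network(
    interactions: Iterable[ScoredInteraction] | Iterable[tuple[str, str]],
    library: Optional[CompoundLibrary] = None,
    group_map: Optional[Mapping[str, Iterable[str]]] = None,
    keep_isolated: Iterable[str] = (),
) -> BipartiteNetwork:
    """Build a bipartite C-T network from kept interactions.

    Interactions may be :class:`ScoredInteraction` rows or plain
    ``(compound, target)`` pairs; duplicates collapse into one edge. Group
    membership comes from *group_map* when given, else from the library's
    herb attributions. *keep_isolated* declares compound nodes retained
    even without edges.
    """
    edges: set[tuple[str, str]] = set()
    for item in interactions:
        if isinstance(item, ScoredInteraction):
            pair = (item.compound_id, item.target_id)
        else:
            pair = (str(item[0]), str(item[1]))
        edges.add(pair)

    compounds = {c for c, _ in edges} | set(keep_isolated)
    targets = {t for _, t in edges}

    if library is not None:
        missing = compounds - set(library.ids)
        if missing:
            raise ValidationError(
                f"interactions reference unknown compounds: {sorted(missing)}"
            )

    groups: dict[str, frozenset[str]] = {}
    for c in compounds:
        if group_map is not None and c in group_map:
            groups[c] = frozenset(group_map[c])
        elif library is not None:
            groups[c] = library[c].herbs
        else:
            groups[c] = frozenset()

    return BipartiteNetwork(
        compound_nodes=frozenset(compounds),
        target_nodes=frozenset(targets),
        edges=frozenset(edges),
        group_of_compound=groups,
    )


def degree_stats(net: BipartiteNetwork) -> DegreeStats:
    """Per-node degrees plus the mean target count per compound (2 dp,
    half-up), as read off the network figures."""
    if not net.compound_nodes:
        raise ValueError("mean undefined: network has no compound nodes")
    cdeg = net.compound_degree()
    tdeg = net.target_degree()
    mean = round_half_up(len(net.edges) / len(net.compound_nodes), 2)
    max_c = max(sorted(cdeg), key=cdeg.__getitem__)
    max_t = max(sorted(tdeg), key=tdeg.__getitem__) if tdeg else ""
    return DegreeStats(
        compound_degree=cdeg,
        target_degree=tdeg,
        mean_targets_per_compound=mean,
        max_degree_compound=max_c,
        max_degree_target=max_t,
    )


def partition_targets(
    net: BipartiteNetwork, groups: Sequence[str]
) -> OverlapPartition:
    """Partition targets into shared-by-all-groups, specific-to-one, other.

    A target is *shared* iff every named group has a compound hitting it,
    and *specific to g* iff only compounds of g hit it.
    """
    unknown = set(groups) - net.groups()
    if unknown:
        raise KeyError(f"unknown group names: {sorted(unknown)}")
    for g in groups:
        if not net.targets_of_group(g) and not any(
            g in gs for gs in net.group_of_compound.values()
        ):
            raise KeyError(f"group {g!r} has no compounds in the network")

    hits = {g: net.targets_of_group(g) for g in groups}
    shared: set[str] = set()
    specific: dict[str, set[str]] = {g: set() for g in groups}
    other: set[str] = set()
    for target in net.target_nodes:
        member_of = [g for g in groups if target in hits[g]]
        if len(member_of) == len(groups):
            shared.add(target)
        elif len(member_of) == 1:
            specific[member_of[0]].add(target)
        else:
            other.add(target)
    return OverlapPartition(
        groups=tuple(groups),
        shared_targets=frozenset(shared),
        specific_targets={g: frozenset(s) for g, s in specific.items()},
        other_targets=frozenset(other),
    )


def overlap_percentage(
    shared_count: int, total_count: int, decimals: int = 2
) -> float:
    """100 * shared/total, rounded half-up to *decimals* places."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= shared_count <= total_count:
        raise ValueError(
            f"shared_count {shared_count} outside [0, {total_count}]"
        )
    return round_half_up(100.0 * shared_count / total_count, decimals)


def _to_networkx(net: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    for c in sorted(net.compound_nodes):
        g.add_node(
            c,
            side="compound",
            groups=",".join(sorted(net.group_of_compound.get(c, ()))),
        )
    for t in sorted(net.target_nodes):
        g.add_node(t, side="target", groups="")
    for c, t in sorted(net.edges):
        g.add_edge(c, t, interaction="ct")
    return g


def export_network(net: BipartiteNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as Cytoscape SIF, GraphML, or an edge-list TSV.

    The edge-TSV round-trips through :func:`build_network` (columns
    compound, target, groups).
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for c, t in sorted(net.edges):
                fh.write(f"{c} ct {t}\n")
    elif fmt == "graphml":
        nx.write_graphml(_to_networkx(net), path)
    elif fmt == "edge-tsv":
        rows = [
            {
                "compound": c,
                "target": t,
                "groups": ",".join(sorted(net.group_of_compound.get(c, ()))),
            }
            for c, t in sorted(net.edges)
        ]
        pd.DataFrame(rows, columns=["compound", "target", "groups"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected {EXPORT_FORMATS}")
    return path


def read_edge_tsv(path: str | Path) -> BipartiteNetwork:
    """Rebuild a network from an edge-list TSV written by export_network."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"compound", "target"} - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    pairs = []
    group_map: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        c, t = str(row_map["compound"]), str(row_map["target"])
        pairs.append((c, t))
        groups = {
            g.strip()
            for g in str(row_map.get("groups", "")).split(",")
            if g.strip()
        }
        group_map.setdefault(c, set()).update(groups)
    return build_network(pairs, group_map=group_map)
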