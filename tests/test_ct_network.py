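"""Bipartite network construction, degree statistics, overlap partition."""

import itertools
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from formulanet.core_data import ValidationError
from formulanet.ct_network import (
    build_network,
    degree_stats,
    export_network,
    overlap_percentage,
    partition_targets,
    read_edge_tsv,
    round_half_up,
)


def complete_bipartite(nc, nt, group="G"):
    edges = [
        (f"c{i}", f"t{j}") for i, j in itertools.product(range(nc), range(nt))
    ]
    groups = {f"c{i}": {group} for i in range(nc)}
    return build_network(edges, group_map=groups)


def random_network(rng, n_compounds=12, n_targets=10, n_groups=3, p=0.3):
    groups = [f"g{k}" for k in range(n_groups)]
    group_map = {
        f"c{i}": {groups[int(rng.integers(n_groups))]} for i in range(n_compounds)
    }
    edges = [
        (f"c{i}", f"t{j}")
        for i in range(n_compounds)
        for j in range(n_targets)
        if rng.random() < p
    ]
    return build_network(edges, group_map=group_map), groups


class TestBuildNetwork:
    def test_complete_bipartite_counts(self):
        net = complete_bipartite(3, 2)
        assert len(net.edges) == 6
        assert all(d == 2 for d in net.compound_degree().values())
        assert all(d == 3 for d in net.target_degree().values())

    def test_empty_interactions(self):
        net = build_network([])
        assert not net.edges and not net.compound_nodes and not net.target_nodes

    def test_duplicate_edges_collapse(self):
        net = build_network([("c", "t"), ("c", "t")])
        assert len(net.edges) == 1

    def test_vascular_herbs_have_30_compounds(self, table1):
        vascular = ["Gymnadenia Conopsea", "Stigma Croci", "Myristica Semena"]
        compounds = sorted(
            {rec.compound_id for h in vascular for rec in table1.by_herb(h)}
        )
        assert len(compounds) == 30
        # any score table over these compounds yields a 30-node compound side
        edges = [(c, f"T{i % 5}") for i, c in enumerate(compounds)]
        net = build_network(edges, table1)
        assert len(net.compound_nodes) == 30

    def test_unknown_compound_rejected(self, table1):
        with pytest.raises(ValidationError, match="M999"):
            build_network([("M999", "T001")], table1)

    def test_degree_sum_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net, _ = random_network(rng)
            assert sum(net.compound_degree().values()) == len(net.edges)
            assert sum(net.target_degree().values()) == len(net.edges)


class TestDegreeStats:
    def test_complete_bipartite_mean(self):
        assert degree_stats(complete_bipartite(3, 2)).mean_targets_per_compound == 2.00

    def test_mean_from_mixed_degrees(self):
        edges = (
            [("a", f"t{i}") for i in range(1)]
            + [("b", f"t{i}") for i in range(2)]
            + [("c", f"t{i}") for i in range(3)]
            + [("d", f"t{i}") for i in range(4)]
        )
        net = build_network(edges)
        assert degree_stats(net).mean_targets_per_compound == 2.50

    def test_single_edge(self):
        net = build_network([("c", "t")])
        stats = degree_stats(net)
        assert stats.mean_targets_per_compound == 1.00
        assert stats.max_degree_compound == "c"

    def test_empty_compound_side_undefined(self):
        with pytest.raises(ValueError, match="mean undefined"):
            degree_stats(build_network([]))

    def test_half_up_rounding(self):
        # 7 edges / 2 compounds = 3.5 -> two-decimal mean stays 3.50;
        # and the rounding helper itself rounds .005 upward
        assert round_half_up(3.505, 2) == 3.51
        assert round_half_up(0.125, 2) == 0.13


class TestPartitionTargets:
    def test_identical_hit_sets_all_shared(self):
        edges = [("a", "t1"), ("a", "t2"), ("b", "t1"), ("b", "t2")]
        net = build_network(edges, group_map={"a": {"g1"}, "b": {"g2"}})
        part = partition_targets(net, ["g1", "g2"])
        assert part.shared_targets == {"t1", "t2"}
        assert all(not s for s in part.specific_targets.values())

    def test_disjoint_hit_sets_all_specific(self):
        edges = [("a", "t1"), ("b", "t2")]
        net = build_network(edges, group_map={"a": {"g1"}, "b": {"g2"}})
        part = partition_targets(net, ["g1", "g2"])
        assert not part.shared_targets
        assert part.specific_targets["g1"] == {"t1"}
        assert part.specific_targets["g2"] == {"t2"}

    def test_matches_per_target_membership_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            net, groups = random_network(rng)
            present = [g for g in groups if any(
                g in gs for gs in net.group_of_compound.values()
            )]
            if not present:
                continue
            part = partition_targets(net, present)
            hits = {g: net.targets_of_group(g) for g in present}
            for t in net.target_nodes:
                members = [g for g in present if t in hits[g]]
                if len(members) == len(present):
                    assert t in part.shared_targets
                elif len(members) == 1:
                    assert t in part.specific_targets[members[0]]
                else:
                    assert t in part.other_targets

    def test_disjoint_cover_of_target_side(self):
        rng = np.random.default_rng(9)
        net, groups = random_network(rng, n_compounds=20, n_targets=15)
        part = partition_targets(net, groups)
        pieces = [part.shared_targets, part.other_targets] + list(
            part.specific_targets.values()
        )
        union = set().union(*pieces)
        assert union == set(net.target_nodes)
        assert sum(len(p) for p in pieces) == len(net.target_nodes)

    def test_unknown_group_rejected(self):
        net = build_network([("a", "t")], group_map={"a": {"g1"}})
        with pytest.raises(KeyError):
            partition_targets(net, ["g1", "nope"])


class TestOverlapPercentage:
    def test_printed_hormone_network_overlap(self):
        assert overlap_percentage(67, 132, 2) == 50.76

    def test_printed_animal_shared_figure(self):
        assert overlap_percentage(135, 139, 0) == 97

    @pytest.mark.parametrize("n", [1, 7, 132])
    def test_extremes(self, n):
        assert overlap_percentage(0, n) == 0.00
        assert overlap_percentage(n, n) == 100.00

    def test_complement_sums_to_100_within_rounding(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            total = int(rng.integers(1, 500))
            a = int(rng.integers(0, total + 1))
            s = overlap_percentage(a, total) + overlap_percentage(total - a, total)
            assert s == pytest.approx(100.0, abs=0.011)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage(0, 0)


class TestExport:
    def test_sif_has_one_row_per_edge(self, tmp_path):
        net = build_network([("a", "t1"), ("b", "t2")])
        path = export_network(net, "sif", tmp_path / "net.sif")
        lines = path.read_text().strip().splitlines()
        assert sorted(lines) == ["a ct t1", "b ct t2"]

    def test_edge_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        net, _ = random_network(rng)
        path = export_network(net, "edge-tsv", tmp_path / "net.tsv")
        again = read_edge_tsv(path)
        assert again.edges == net.edges
        assert again.group_of_compound == {
            c: g for c, g in net.group_of_compound.items() if c in again.compound_nodes
        }

    def test_graphml_node_and_edge_counts(self, tmp_path):
        net = complete_bipartite(3, 2)
        path = export_network(net, "graphml", tmp_path / "net.graphml")
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        tree = ET.parse(path)
        assert len(tree.findall(".//g:node", ns)) == 5
        assert len(tree.findall(".//g:edge", ns)) == 6

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network([("a", "t")])
        with pytest.raises(ValueError, match="format"):
            export_network(net, "gexf", tmp_path / "x")
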