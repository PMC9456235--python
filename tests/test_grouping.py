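import itertools

import numpy as np
import pytest

from csnkit import (
    ChemSpaceNetwork,
    CSNEdge,
    CSNode,
    SimilarityMatrix,
    filter_groups,
    group_network,
    mwgs,
    select_representative,
    spatial_group,
)
from csnkit.grouping import CompoundGroup, edge_length_at_quantile


def _network_from_points(points, edges):
    """points: {id: (x, y)}; edges: iterable of (a, b, similarity)."""
    nodes = [CSNode(mol_id=i, x=x, y=y) for i, (x, y) in points.items()]
    edge_objs = []
    for a, b, s in edges:
        length = float(
            np.hypot(points[a][0] - points[b][0], points[a][1] - points[b][1])
        )
        edge_objs.append(CSNEdge(id_a=a, id_b=b, similarity=s, embedded_length=length))
    return ChemSpaceNetwork(nodes=nodes, edges=edge_objs, isolated_ids=[])


@pytest.fixture
def bridged_network():
    """Two tight 6-node clusters joined by a single long bridge edge."""
    points = {}
    edges = []
    for c, (cx, cy) in enumerate([(0.1, 0.1), (0.9, 0.9)]):
        ids = [f"c{c}n{i}" for i in range(6)]
        for i, mol in enumerate(ids):
            points[mol] = (cx + 0.02 * i, cy + 0.015 * i)
        for a, b in itertools.combinations(ids, 2):
            edges.append((a, b, 0.8))
    edges.append(("c0n0", "c1n0", 0.5))  # the long inter-cluster bridge
    return _network_from_points(points, edges)


class TestSpatialGroup:
    def test_large_threshold_equals_plain_connected_components(self, bridged_network):
        partition = spatial_group(bridged_network, edge_length_threshold=10.0)
        assert len(partition) == 1
        assert len(partition[0]) == 12

    def test_tiny_threshold_gives_all_singletons(self, bridged_network):
        partition = spatial_group(bridged_network, edge_length_threshold=1e-9)
        assert all(len(c) == 1 for c in partition)
        assert len(partition) == 12

    def test_intermediate_threshold_separates_the_two_clusters(self, bridged_network):
        lengths = sorted(e.embedded_length for e in bridged_network.edges)
        bridge = lengths[-1]
        internal_max = lengths[-2]
        cut = (internal_max + bridge) / 2
        partition = spatial_group(bridged_network, edge_length_threshold=cut)
        assert sorted(len(c) for c in partition) == [6, 6]
        prefixes = [{m[:2] for m in c} for c in partition]
        assert all(len(p) == 1 for p in prefixes)

    def test_infinite_threshold_matches_independent_traversal(self):
        """Oracle: components by explicit breadth-first traversal."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 15))
            ids = [str(i) for i in range(n)]
            points = {i: tuple(rng.random(2)) for i in ids}
            pairs = [
                (a, b, 0.9)
                for a, b in itertools.combinations(ids, 2)
                if rng.random() < 0.15
            ]
            net = _network_from_points(points, pairs)
            partition = spatial_group(net, edge_length_threshold=np.inf)
            # independent BFS
            adjacency = {i: set() for i in ids}
            for a, b, _ in pairs:
                adjacency[a].add(b)
                adjacency[b].add(a)
            seen, components = set(), []
            for start in ids:
                if start in seen:
                    continue
                queue, comp = [start], set()
                while queue:
                    v = queue.pop()
                    if v in comp:
                        continue
                    comp.add(v)
                    queue.extend(adjacency[v] - comp)
                seen |= comp
                components.append(frozenset(comp))
            assert {frozenset(c) for c in partition} == set(components)


class TestFilterGroups:
    def test_small_components_move_to_unassigned(self):
        partition = [["a", "b", "c", "d", "e"], ["f", "g"], ["h"]]
        result = filter_groups(partition, min_group_size=3)
        assert len(result.groups) == 1
        assert result.groups[0].size == 5
        assert result.unassigned_ids == ["f", "g", "h"]

    def test_min_size_one_filters_nothing(self):
        partition = [["a"], ["b", "c"]]
        result = filter_groups(partition, min_group_size=1)
        assert len(result.groups) == 2
        assert result.unassigned_ids == []

    def test_boundary_size_three_survives(self):
        result = filter_groups([["a", "b", "c"], ["d", "e", "f"]], min_group_size=3)
        assert len(result.groups) == 2
        assert result.unassigned_ids == []

    def test_groups_renumbered_by_size_then_smallest_member(self):
        partition = [["9", "10"], ["5", "6", "7"], ["1", "2", "3"]]
        result = filter_groups(partition, min_group_size=2)
        assert [g.member_ids for g in result.groups] == [
            ["1", "2", "3"],
            ["5", "6", "7"],
            ["9", "10"],
        ]
        assert [g.group_id for g in result.groups] == [1, 2, 3]

    def test_invalid_min_size_raises(self):
        with pytest.raises(ValueError):
            filter_groups([["a"]], min_group_size=0)

    def test_partition_conservation_on_random_networks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            ids = [str(i) for i in range(n)]
            cuts = sorted(rng.choice(n, size=min(4, n - 1), replace=False))
            partition, prev = [], 0
            for c in list(cuts) + [n]:
                if c > prev:
                    partition.append(ids[prev:c])
                    prev = c
            result = filter_groups(partition, min_group_size=3)
            grouped = [m for g in result.groups for m in g.member_ids]
            assert sorted(grouped + result.unassigned_ids) == sorted(ids)
            assert len(set(grouped) & set(result.unassigned_ids)) == 0


def _matrix(ids, values):
    return SimilarityMatrix(ids=ids, values=np.asarray(values, dtype=float))


class TestMWGS:
    def test_identical_molecules_score_one(self):
        ids = ["a", "b", "c", "d"]
        m = _matrix(ids, np.ones((4, 4)))
        assert mwgs(ids, m) == {i: 1.0 for i in ids}

    def test_three_member_hand_calculation(self):
        # S(1,2)=0.5, S(1,3)=0.7 → member 1: (1 + 0.5 + 0.7 − 1)/2 = 0.6
        m = _matrix(
            ["1", "2", "3"],
            [[1.0, 0.5, 0.7], [0.5, 1.0, 0.2], [0.7, 0.2, 1.0]],
        )
        values = mwgs(["1", "2", "3"], m)
        assert values["1"] == pytest.approx(0.6)
        assert values["2"] == pytest.approx((0.5 + 0.2) / 2)
        assert values["3"] == pytest.approx((0.7 + 0.2) / 2)

    def test_matches_brute_force_loop_excluding_self(self):
        rng = np.random.default_rng(5)
        values = rng.random((6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        ids = [str(i) for i in range(6)]
        m = _matrix(ids, values)
        result = mwgs(ids, m)
        for i, mol in enumerate(ids):
            expected = np.mean([values[i, j] for j in range(6) if j != i])
            assert result[mol] == pytest.approx(expected)

    def test_literal_denominator_mode(self):
        m = _matrix(
            ["1", "2", "3"],
            [[1.0, 0.5, 0.7], [0.5, 1.0, 0.2], [0.7, 0.2, 1.0]],
        )
        values = mwgs(["1", "2", "3"], m, denominator="n")
        assert values["1"] == pytest.approx((1 + 0.5 + 0.7 - 1) / 3)

    def test_values_always_within_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            values = rng.random((n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 1.0)
            ids = [str(i) for i in range(n)]
            result = mwgs(ids, _matrix(ids, values))
            assert all(0.0 <= v <= 1.0 for v in result.values())

    def test_singleton_group_is_undefined(self):
        m = _matrix(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="undefined"):
            mwgs(["a"], m)


class TestSelectRepresentative:
    def test_argmax_wins(self):
        assert select_representative(["A", "B", "C"], {"A": 0.6, "B": 0.4, "C": 0.5}) == "A"

    def test_tie_broken_by_smallest_id(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="csnkit.grouping"):
            winner = select_representative(["3", "1", "2"], {"1": 0.5, "2": 0.5, "3": 0.5})
        assert winner == "1"
        assert any("tie" in r.message.lower() for r in caplog.records)

    def test_stable_under_member_permutation(self):
        values = {"b": 0.41, "a": 0.47, "c": 0.42}
        for perm in itertools.permutations(["a", "b", "c"]):
            assert select_representative(list(perm), values) == "a"


class TestGroupNetwork:
    def test_full_grouping_on_planted_families(
        self, three_family_records, three_family_fps, three_family_matrix
    ):
        from csnkit import assemble_network

        net = assemble_network(
            three_family_records, three_family_fps, three_family_matrix, seed=0
        )
        names = {r.mol_id: r.name for r in three_family_records}
        result = group_network(net, three_family_matrix, names=names)
        assert len(result.groups) == 3
        truth = {r.mol_id: r.family_label for r in three_family_records}
        for g in result.groups:
            assert len({truth[m] for m in g.member_ids}) == 1
            assert g.representative_id in g.member_ids
            best = max(g.mwgs_by_member.values())
            assert g.mwgs_by_member[g.representative_id] == best
            assert g.label.endswith(" group")

    def test_quantile_threshold_computed_from_edge_lengths(self, bridged_network):
        q = edge_length_at_quantile(bridged_network, 1.0)
        assert q == pytest.approx(max(e.embedded_length for e in bridged_network.edges))
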