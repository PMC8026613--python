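"""Merged-network construction, components, communities and distances."""

import itertools

import networkx as nx
import numpy as np
import pytest

from canvasnet.genome_io import FragmentMap, GenomicInterval, InteractionCall
from canvasnet import network_core as nc


def tiling_map(n=40, chrom="chr1", size=4000):
    return FragmentMap(
        [
            (f"{chrom}:{i * size}-{(i + 1) * size}",
             GenomicInterval(chrom, i * size, (i + 1) * size))
            for i in range(n)
        ]
    )


def fid(i, chrom="chr1", size=4000):
    return f"{chrom}:{i * size}-{(i + 1) * size}"


def call(i, j, score, cond):
    return InteractionCall(fid(i), fid(j), score, 1, cond)


class TestEdgeClassification:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (5.2, 1.0, "A_specific"),
            (5.2, 3.5, "shared"),       # significant in A, supported (>3) in B
            (5.2, 3.0, "A_specific"),   # support threshold is strict
            (4.9, 4.9, None),           # below significance in both
            (None, 6.0, "B_specific"),
            (3.5, 5.0, "shared"),
            (6.0, 6.0, "shared"),
            (5.0, None, "A_specific"),
        ],
    )
    def test_specificity_rule(self, a, b, expected):
        assert nc.classify_edge(a, b) == expected

    def test_labels_recomputable_from_stored_scores(self):
        fm = tiling_map()
        rng = np.random.default_rng(3)
        calls_a = [call(i, i + 1, float(rng.uniform(0, 10)), "A") for i in range(0, 30, 2)]
        calls_b = [call(i, i + 1, float(rng.uniform(0, 10)), "B") for i in range(0, 30, 2)]
        net = nc.build_merged_network(calls_a, calls_b, fm)
        for u, v, d in net.graph.edges(data=True):
            assert d["specificity"] == nc.classify_edge(d["score_A"], d["score_B"])

    def test_sig_must_exceed_support(self):
        with pytest.raises(ValueError):
            nc.build_merged_network([], [], tiling_map(), sig_threshold=2, support_threshold=3)


class TestBuildMergedNetwork:
    def test_edge_set_matches_brute_force_rule(self):
        """The constructed edge set equals direct set construction from the
        same scores for random call sets."""
        fm = tiling_map()
        rng = np.random.default_rng(11)
        for _ in range(20):
            pairs = [
                (int(a), int(b))
                for a, b in rng.integers(0, 40, size=(30, 2))
                if a != b
            ]
            scores = {}
            calls = {"A": [], "B": []}
            for a, b in pairs:
                key = frozenset((fid(a), fid(b)))
                for cond in ("A", "B"):
                    if rng.random() < 0.7:
                        s = float(rng.uniform(0, 10))
                        calls[cond].append(call(a, b, s, cond))
                        scores.setdefault(key, {})[cond] = max(
                            s, scores.get(key, {}).get(cond, 0)
                        )
            expected = {
                key
                for key, sc in scores.items()
                if nc.classify_edge(sc.get("A"), sc.get("B")) is not None
            }
            net = nc.build_merged_network(calls["A"], calls["B"], fm)
            assert {frozenset(e) for e in net.graph.edges} == expected

    def test_no_orphan_nodes(self):
        fm = tiling_map()
        net = nc.build_merged_network([call(0, 1, 4.0, "A")], [], fm)
        assert net.graph.number_of_nodes() == 0

    def test_unknown_fragment_rejected(self):
        fm = tiling_map(n=2)
        bad = InteractionCall("chrX:0-1000", fid(0), 6.0, 1, "A")
        with pytest.raises(KeyError):
            nc.build_merged_network([bad], [], fm)


def union_find_components(edges):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    comps = {}
    for x in list(parent):
        comps.setdefault(find(x), set()).add(x)
    return {frozenset(c) for c in comps.values()}


class TestComponents:
    def test_two_triangles(self):
        fm = tiling_map()
        calls = [call(a, b, 6, "A") for a, b in [(0, 1), (1, 2), (0, 2), (5, 6), (6, 7), (5, 7)]]
        net = nc.build_merged_network(calls, [], fm)
        comps = nc.connected_components(net)
        assert [c.n_nodes for c in comps] == [3, 3]
        assert comps[0].members[0] < comps[1].members[0]

    def test_empty_network(self):
        net = nc.build_merged_network([], [], tiling_map())
        assert nc.connected_components(net) == []

    def test_matches_union_find_oracle(self):
        fm = tiling_map()
        rng = np.random.default_rng(5)
        for _ in range(10):
            calls = [
                call(int(a), int(b), 6.0, "A")
                for a, b in rng.integers(0, 40, size=(25, 2))
                if a != b
            ]
            net = nc.build_merged_network(calls, [], fm)
            got = {frozenset(c.members) for c in nc.connected_components(net)}
            assert got == union_find_components(net.graph.edges)

    def test_node_and_edge_counts_conserved(self, network):
        comps = nc.connected_components(network)
        assert sum(c.n_nodes for c in comps) == network.graph.number_of_nodes()
        assert sum(c.n_edges for c in comps) == network.graph.number_of_edges()


def brute_force_best_modularity(g):
    """Exhaustive modularity maximisation over all set partitions (<=10 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1 :]
            yield part + [[head]]

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(p) for p in part])
        best = max(best, q)
    return best


def clique_calls(members, start_score=6.0):
    return [call(a, b, start_score, "A") for a, b in itertools.combinations(members, 2)]


class TestCommunities:
    def test_two_cliques_match_exhaustive_optimum(self):
        """The detected best partition equals exhaustive modularity
        maximisation on this 10-node graph. A two-community partition can
        never reach Q = 0.7 (the attainable maximum with two communities is
        0.5), so the split is checked below the default gate."""
        fm = tiling_map()
        calls = clique_calls(range(5)) + clique_calls(range(5, 10)) + [call(0, 5, 6, "A")]
        net = nc.build_merged_network(calls, [], fm)
        (comp,) = nc.connected_components(net)
        part = nc.detect_communities(net, comp, modularity_threshold=0.3, seed=0)
        best = brute_force_best_modularity(net.graph)
        assert part.modularity == pytest.approx(best, abs=1e-12)
        assert len(part.communities) == 2
        assert {frozenset(c) for c in part.communities} == {
            frozenset(fid(i) for i in range(5)),
            frozenset(fid(i) for i in range(5, 10)),
        }
        # under the default 0.7 gate this component stays whole
        gated = nc.detect_communities(net, comp, seed=0)
        assert not gated.split_applied and len(gated.communities) == 1

    def test_complete_graph_not_split(self):
        fm = tiling_map()
        net = nc.build_merged_network(clique_calls(range(6)), [], fm)
        (comp,) = nc.connected_components(net)
        part = nc.detect_communities(net, comp, seed=0)
        assert not part.split_applied
        assert len(part.communities) == 1

    def test_ring_of_four_cliques(self):
        fm = tiling_map()
        blocks = [list(range(k * 6, k * 6 + 6)) for k in range(4)]
        calls = sum((clique_calls(b) for b in blocks), [])
        for k in range(4):
            calls.append(call(blocks[k][0], blocks[(k + 1) % 4][0], 6, "A"))
        net = nc.build_merged_network(calls, [], fm)
        (comp,) = nc.connected_components(net)
        # ring of four 6-cliques: best Q = 60/64 - 4/16 = 0.6875
        part = nc.detect_communities(net, comp, modularity_threshold=0.5, seed=0)
        assert part.split_applied
        assert part.modularity == pytest.approx(0.6875)
        assert {frozenset(c) for c in part.communities} == {
            frozenset(fid(i) for i in b) for b in blocks
        }

    def test_singleton_component(self):
        fm = tiling_map()
        net = nc.build_merged_network([call(0, 1, 6, "A")], [], fm)
        comp = nc.SubNetwork(0, [fid(0)], 1, 0)
        part = nc.detect_communities(net, comp, seed=0)
        assert part.modularity == 0.0
        assert part.communities == [[fid(0)]]

    def test_deterministic_given_seed(self, network):
        comps = nc.connected_components(network)
        p1 = nc.detect_communities(network, comps[0], seed=42)
        p2 = nc.detect_communities(network, comps[0], seed=42)
        assert p1.communities == p2.communities


class TestCensus:
    def test_quadrants(self):
        fm = tiling_map()
        calls_a = [call(i, i + 1, 6, "A") for i in range(0, 4)]
        calls_b = [call(i, i + 1, 6, "B") for i in range(0, 8)]
        net = nc.build_merged_network(calls_a, calls_b, fm)
        (diff,) = nc.subnetwork_census(net)
        assert diff.quadrant == "larger-in-B"
        assert diff.edges_B == 8 and diff.edges_A == 4

    def test_all_shared_unchanged(self):
        fm = tiling_map()
        calls = [call(i, i + 1, 6, "A") for i in range(3)]
        net = nc.build_merged_network(calls, [call(i, i + 1, 6, "B") for i in range(3)], fm)
        (diff,) = nc.subnetwork_census(net)
        assert diff.quadrant == "unchanged"
        assert diff.nodes_A == diff.nodes_B == 4


class TestDistances:
    def test_midpoint_distance(self):
        fm = tiling_map()
        net = nc.build_merged_network([call(0, 3, 6, "A")], [], fm)
        # chr1:0-4000 mid 2000; chr1:12000-16000 mid 14000
        assert net.interaction_distance(fid(0), fid(3)) == 12000
        assert net.interaction_distance(fid(3), fid(0)) == 12000

    def test_trans_flagged(self, small_map):
        calls = [InteractionCall("chr1:0-4000", "chr2:0-4000", 6.0, 1, "A")]
        net = nc.build_merged_network(calls, [], small_map)
        assert net.interaction_distance("chr1:0-4000", "chr2:0-4000") is None

    def test_random_pairs_match_arithmetic(self):
        fm = tiling_map(n=100)
        rng = np.random.default_rng(9)
        net = nc.build_merged_network(
            [call(0, 1, 6, "A")], [], fm
        )
        for a, b in rng.integers(0, 100, size=(50, 2)):
            if a == b:
                continue
            expected = abs((a * 4000 + 2000) - (b * 4000 + 2000))
            assert net.interaction_distance(fid(int(a)), fid(int(b))) == expected

    @pytest.mark.parametrize(
        "distance,band",
        [
            (1_000_001, "long"),
            (1_000_000, "mid"),   # boundary excluded from long
            (100_001, "mid"),
            (100_000, "short"),
            (0, "short"),
        ],
    )
    def test_distance_bands(self, distance, band):
        assert nc.classify_distance_band(distance) == band

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            nc.classify_distance_band(-1)

    def test_band_sweep_consistent(self):
        bands = {"short_mid": 50_000, "mid_long": 500_000}
        for d in [0, 49_999, 50_000, 50_001, 499_999, 500_000, 500_001, 10**7]:
            band = nc.classify_distance_band(d, bands)
            if d > bands["mid_long"]:
                assert band == "long"
            elif d > bands["short_mid"]:
                assert band == "mid"
            else:
                assert band == "short"


class TestTopLongest:
    def test_matches_sort_oracle(self):
        fm = tiling_map(n=200)
        rng = np.random.default_rng(13)
        calls = [
            call(int(a), int(b), 6.0, "A")
            for a, b in rng.integers(0, 200, size=(60, 2))
            if a != b
        ]
        net = nc.build_merged_network(calls, [], fm)
        top = nc.select_top_longest(net, "A", n=10)
        all_d = sorted(
            (net.interaction_distance(u, v) for u, v in net.graph.edges), reverse=True
        )
        assert [t[2] for t in top] == all_d[:10]
        assert min(t[2] for t in top) >= max(all_d[10:], default=0)

    def test_fewer_edges_than_requested_warns(self):
        fm = tiling_map()
        net = nc.build_merged_network([call(0, 5, 6, "A")], [], fm)
        with pytest.warns(UserWarning, match="only 1"):
            top = nc.select_top_longest(net, "A", n=3)
        assert len(top) == 1

    def test_tie_break_deterministic(self):
        fm = tiling_map(n=50)
        # three edges with identical distance
        calls = [call(0, 2, 6, "A"), call(10, 12, 6, "A"), call(20, 22, 6, "A")]
        net = nc.build_merged_network(calls, [], fm)
        runs = [nc.select_top_longest(net, "A", n=2) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]


class TestExtractStateNetwork:
    def test_planted_predicate_edges_recovered(self):
        fm = tiling_map()
        calls = [call(0, 1, 6, "A"), call(1, 2, 6, "A"), call(4, 5, 6, "A")]
        net = nc.build_merged_network(calls, [], fm)
        marked = {fid(0), fid(1), fid(4), fid(5)}
        sub, genes = nc.extract_state_network(net, "A", lambda f: f in marked)
        assert {frozenset(e) for e in sub.edges} == {
            frozenset((fid(0), fid(1))), frozenset((fid(4), fid(5)))
        }

    def test_true_predicate_is_identity(self, network):
        sub, _ = nc.extract_state_network(network, "A", lambda f: True)
        expected = {
            frozenset(e) for e in network.condition_edges("A")
        }
        assert {frozenset(e) for e in sub.edges} == expected
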