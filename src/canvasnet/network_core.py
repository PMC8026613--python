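"""Merged two-condition promoter-interaction networks.

Each node is a restriction fragment; each edge a significant interaction call
in at least one of two conditions (labelled A and B throughout). An edge is
significant when its score reaches ``sig_threshold`` (default 5.0, the
conventional CHiCAGO significance cutoff) in at least one condition. Edge
specificity uses a cautious sub-threshold support rule: an interaction that is
significant in one condition but has a score above ``support_threshold``
(default 3.0) in the other is treated as shared, so that condition-specific
calls are not driven by a minor sub-threshold difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import FragmentMap, InteractionCall

logger = logging.getLogger(__name__)

A_SPECIFIC = "A_specific"
B_SPECIFIC = "B_specific"
SHARED = "shared"
SPECIFICITIES = (A_SPECIFIC, B_SPECIFIC, SHARED)


def classify_edge(
    score_a: float | None,
    score_b: float | None,
    sig_threshold: float = 5.0,
    support_threshold: float = 3.0,
) -> str | None:
    """Specificity of an edge given its two condition scores.

    Returns None when the edge is not significant in either condition. This is
    the single point of truth: stored specificity labels are recomputable by
    calling it again on the stored scores.
    """
    a = -np.inf if score_a is None else score_a
    b = -np.inf if score_b is None else score_b
    if max(a, b) < sig_threshold:
        return None
    if a >= sig_threshold and b > support_threshold:
        return SHARED
    if b >= sig_threshold and a > support_threshold:
        return SHARED
    return A_SPECIFIC if a >= sig_threshold else B_SPECIFIC


@dataclass
class MergedNetwork:
    """Two-condition interaction network over one fragment map."""

    graph: nx.Graph
    fragment_map: FragmentMap
    sig_threshold: float = 5.0
    support_threshold: float = 3.0

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_supported_in(self, u: str, v: str, condition: str) -> bool:
        """Whether the edge carries support in condition ``A`` or ``B``
        (specific to that condition, or shared)."""
        spec = self.graph.edges[u, v]["specificity"]
        if spec == SHARED:
            return True
        return spec == (A_SPECIFIC if condition == "A" else B_SPECIFIC)

    def condition_edges(self, condition: str) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v in self.graph.edges
            if self.edge_supported_in(u, v, condition)
        ]

    def interaction_distance(self, u: str, v: str) -> float | None:
        """Linear genomic distance between fragment midpoints; None for trans."""
        iu = self.fragment_map.get_interval(u)
        iv = self.fragment_map.get_interval(v)
        if iu.chrom != iv.chrom:
            return None
        return abs(iu.midpoint - iv.midpoint)


def build_merged_network(
    calls_a: list[InteractionCall],
    calls_b: list[InteractionCall],
    fragment_map: FragmentMap,
    sig_threshold: float = 5.0,
    support_threshold: float = 3.0,
) -> MergedNetwork:
    """Merge interaction calls from two conditions into one network.

    Nodes enter only through a significant edge (no orphan nodes). Node
    specificity is derived from incident edges: a node touching only
    A-supported edges is A-specific, only B-supported is B-specific, otherwise
    shared.
    """
    if sig_threshold < support_threshold:
        raise ValueError("sig_threshold must be >= support_threshold")
    scores: dict[frozenset, dict[str, float]] = {}
    reads: dict[frozenset, dict[str, int]] = {}
    baitness: dict[frozenset, tuple[str, str]] = {}
    for calls, cond in ((calls_a, "A"), (calls_b, "B")):
        for c in calls:
            for fid in (c.bait_fragment_id, c.other_fragment_id):
                if fid not in fragment_map:
                    raise KeyError(f"unknown fragment {fid!r} in interaction call")
            key = frozenset((c.bait_fragment_id, c.other_fragment_id))
            scores.setdefault(key, {})[cond] = max(
                c.score, scores.get(key, {}).get(cond, -np.inf)
            )
            reads.setdefault(key, {})[cond] = (
                reads.get(key, {}).get(cond, 0) + c.read_count
            )
            baitness.setdefault(key, (c.bait_fragment_id, c.other_fragment_id))

    g = nx.Graph(sig_threshold=sig_threshold, support_threshold=support_threshold)
    for key, sc in scores.items():
        spec = classify_edge(
            sc.get("A"), sc.get("B"), sig_threshold, support_threshold
        )
        if spec is None:
            continue
        u, v = baitness[key]
        g.add_edge(
            u,
            v,
            score_A=sc.get("A"),
            score_B=sc.get("B"),
            reads_A=reads[key].get("A", 0),
            reads_B=reads[key].get("B", 0),
            specificity=spec,
            bait=u,
        )
    for node in g.nodes:
        specs = {g.edges[node, nb]["specificity"] for nb in g.neighbors(node)}
        if specs == {A_SPECIFIC}:
            node_spec = A_SPECIFIC
        elif specs == {B_SPECIFIC}:
            node_spec = B_SPECIFIC
        else:
            node_spec = SHARED
        iv = fragment_map.get_interval(node)
        g.nodes[node].update(
            specificity=node_spec, chrom=iv.chrom, start=iv.start, end=iv.end
        )
    return MergedNetwork(g, fragment_map, sig_threshold, support_threshold)


@dataclass
class SubNetwork:
    """A connected component of the merged network."""

    component_id: int
    members: list[str]
    n_nodes: int
    n_edges: int


def connected_components(network: MergedNetwork) -> list[SubNetwork]:
    """Connected components, ordered by (size desc, smallest fragment id)."""
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [
        SubNetwork(i, c, len(c), network.graph.subgraph(c).number_of_edges())
        for i, c in enumerate(comps)
    ]


@dataclass
class CommunityPartition:
    """Best modularity partition of one component."""

    component_id: int
    modularity: float
    communities: list[list[str]]
    split_applied: bool
    seed: int


def _exact_best_partition(g: nx.Graph) -> tuple[list[set], float]:
    """Exhaustive modularity maximisation over all set partitions.

    Only feasible for very small graphs (Bell(10) ~ 1.2e5 partitions); used
    below :data:`EXACT_PARTITION_MAX_NODES` where greedy multilevel moves can
    miss the global optimum. Deterministic: ties resolved by enumeration
    order.
    """
    nodes = list(g.nodes)
    m = g.number_of_edges()
    adj = {n: set(g.neighbors(n)) for n in nodes}
    deg = dict(g.degree())

    def q_of(part):
        q = 0.0
        for comm in part:
            intra = sum(len(adj[n] & comm) for n in comm) / 2
            dsum = sum(deg[n] for n in comm)
            q += intra / m - (dsum / (2 * m)) ** 2
        return q

    best_q, best_p = -1.0, None

    # recursive enumeration of set partitions (restricted growth)
    def partitions(i, part):
        if i == len(nodes):
            yield part
            return
        n = nodes[i]
        for j in range(len(part)):
            part[j].add(n)
            yield from partitions(i + 1, part)
            part[j].remove(n)
        part.append({n})
        yield from partitions(i + 1, part)
        part.pop()

    for part in partitions(0, []):
        q = q_of(part)
        if q > best_q + 1e-15:
            best_q, best_p = q, [set(c) for c in part]
    return best_p, best_q


EXACT_PARTITION_MAX_NODES = 10


def best_modularity_partition(
    g: nx.Graph, seed: int = 0
) -> tuple[list[set], float]:
    """Best modularity partition of a connected graph.

    Exhaustive search for graphs of at most
    :data:`EXACT_PARTITION_MAX_NODES` nodes, multilevel (Louvain)
    optimisation with the given seed above that.
    """
    if g.number_of_nodes() <= EXACT_PARTITION_MAX_NODES:
        return _exact_best_partition(g)
    parts = nx.community.louvain_communities(g, seed=seed)
    return [set(p) for p in parts], nx.community.modularity(g, parts)


def detect_communities(
    network: MergedNetwork,
    component: SubNetwork,
    modularity_threshold: float = 0.7,
    seed: int = 0,
) -> CommunityPartition:
    """Modularity-optimal community structure of one component.

    Components whose best partition reaches ``modularity_threshold`` (default
    0.7) are split into their communities; below the threshold the component
    is kept whole. Deterministic for a fixed seed (exhaustive and therefore
    seed-free on components of <= 10 nodes).
    """
    sub = network.graph.subgraph(component.members)
    if sub.number_of_nodes() == 1 or sub.number_of_edges() == 0:
        return CommunityPartition(
            component.component_id, 0.0, [sorted(sub.nodes)], False, seed
        )
    parts, q = best_modularity_partition(sub, seed=seed)
    communities = sorted((sorted(p) for p in parts), key=lambda c: c[0])
    split = q >= modularity_threshold and len(communities) > 1
    if not split:
        communities = [sorted(sub.nodes)]
    return CommunityPartition(component.component_id, float(q), communities, split, seed)


@dataclass
class SubNetworkDiff:
    """Per-component condition-resolved size census."""

    component_id: int
    nodes_A: int
    nodes_B: int
    edges_A: int
    edges_B: int
    quadrant: str  # larger-in-A / larger-in-B / unchanged / mixed


def _quadrant(d_edges: int, d_nodes: int) -> str:
    if d_edges == 0 and d_nodes == 0:
        return "unchanged"
    if d_edges >= 0 and d_nodes >= 0:
        return "larger-in-B"
    if d_edges <= 0 and d_nodes <= 0:
        return "larger-in-A"
    return "mixed"


def subnetwork_census(
    network: MergedNetwork, components: list[SubNetwork] | None = None
) -> list[SubNetworkDiff]:
    """Per-component counts of condition-supported edges and nodes.

    ``edges_X`` counts edges supported in condition X (shared or X-specific);
    ``nodes_X`` counts nodes incident to at least one such edge. The quadrant
    label is assigned from the sign of the B - A differences.
    """
    if components is None:
        components = connected_components(network)
    out = []
    for comp in components:
        sub = network.graph.subgraph(comp.members)
        counts = {"A": 0, "B": 0}
        nodes: dict[str, set] = {"A": set(), "B": set()}
        for u, v in sub.edges:
            for cond in ("A", "B"):
                if network.edge_supported_in(u, v, cond):
                    counts[cond] += 1
                    nodes[cond].update((u, v))
        out.append(
            SubNetworkDiff(
                comp.component_id,
                len(nodes["A"]),
                len(nodes["B"]),
                counts["A"],
                counts["B"],
                _quadrant(counts["B"] - counts["A"], len(nodes["B"]) - len(nodes["A"])),
            )
        )
    return out


def census_table(diffs: list[SubNetworkDiff]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in diffs])


DEFAULT_BANDS = {"short_mid": 100_000, "mid_long": 1_000_000}


def classify_distance_band(
    distance: float, bands: dict[str, float] | None = None
) -> str:
    """Assign a cis distance to the short / mid / long band.

    Long range is strictly greater than the mid/long breakpoint (1 Mb by
    convention, so 1,000,000 bp itself is mid-range). The short/mid breakpoint
    (default 100 kb) is a reporting choice and configurable.
    """
    if distance < 0:
        raise ValueError("negative genomic distance")
    bands = bands or DEFAULT_BANDS
    if distance > bands["mid_long"]:
        return "long"
    if distance > bands["short_mid"]:
        return "mid"
    return "short"


def distance_table(network: MergedNetwork, condition: str, bands=None) -> pd.DataFrame:
    """Cis interaction distances for one condition, with band labels and a
    Tukey outlier flag (values beyond 1.5 x IQR past the quartiles are flagged,
    never dropped)."""
    rows = []
    for u, v in network.condition_edges(condition):
        d = network.interaction_distance(u, v)
        if d is None:
            continue
        rows.append({"frag1": u, "frag2": v, "distance": d})
    df = pd.DataFrame(rows, columns=["frag1", "frag2", "distance"])
    if df.empty:
        df["band"] = pd.Series(dtype=str)
        df["outlier"] = pd.Series(dtype=bool)
        return df
    df["band"] = [classify_distance_band(d, bands) for d in df["distance"]]
    q1, q3 = df["distance"].quantile([0.25, 0.75])
    iqr = q3 - q1
    df["outlier"] = (df["distance"] < q1 - 1.5 * iqr) | (df["distance"] > q3 + 1.5 * iqr)
    return df


def select_top_longest(
    network: MergedNetwork, condition: str, n: int = 1000
) -> list[tuple[str, str, float]]:
    """The ``n`` condition-supported cis edges spanning the largest linear
    genomic distance. Ties at the cutoff are broken by fragment id for
    determinism; if fewer than ``n`` eligible edges exist, all are returned
    with a warning."""
    scored = []
    for u, v in network.condition_edges(condition):
        d = network.interaction_distance(u, v)
        if d is None:
            continue
        lo, hi = sorted((u, v))
        scored.append((lo, hi, d))
    scored.sort(key=lambda t: (-t[2], t[0], t[1]))
    if len(scored) < n:
        warnings.warn(
            f"only {len(scored)} cis edges supported in {condition}; "
            f"requested top {n}",
            stacklevel=2,
        )
    return scored[:n]


def extract_state_network(
    network: MergedNetwork,
    condition: str,
    node_predicate,
    bait_annotation=None,
) -> tuple[nx.Graph, list[str]]:
    """Induced sub-graph on condition-supported edges whose both endpoints
    satisfy ``node_predicate`` (e.g. fragment state in {bivalent, polycomb}).

    Returns the sub-graph and the sorted gene list of baited nodes inside it
    (empty when no bait annotation is given).
    """
    keep = [
        (u, v)
        for u, v in network.condition_edges(condition)
        if node_predicate(u) and node_predicate(v)
    ]
    sub = network.graph.edge_subgraph(keep).copy() if keep else nx.Graph()
    genes: set[str] = set()
    if bait_annotation is not None:
        for node in sub.nodes:
            genes |= bait_annotation.genes_by_fragment.get(node, set())
    return sub, sorted(genes)
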