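"""Deterministic network layouts and static rendering.

Two layouts are provided. A simplified force-directed layout in the
ForceAtlas2 family (linear attraction along edges, degree-weighted repulsion
between all node pairs, central gravity, adaptive step) positions highly
interacting nodes close together; it is seed-deterministic and logs its
parameters, which together with the qualitative contract (connected pairs end
up closer than disconnected ones) is the reproducible part of an otherwise
interactive visualisation step. A metric MDS layout embeds nodes by pairwise
linear genomic distance and reports Kruskal stress-1,
sqrt(sum (d_ij - delta_ij)^2 / sum delta_ij^2) over all node pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class LayoutResult:
    coordinates: dict[str, tuple[float, float]]
    algorithm: str
    parameters: dict
    seed: int | None
    iterations: int
    stress: float | None = None


DEFAULT_FA2 = {"repulsion": 1.0, "gravity": 0.05, "edge_weight_influence": 1.0}


def force_directed_layout(
    graph: nx.Graph,
    iterations: int = 200,
    seed: int = 0,
    params: dict | None = None,
    tolerance: float = 1e-4,
) -> LayoutResult:
    """Simplified ForceAtlas2-style layout, deterministic given the seed.

    Attraction is linear in edge length (scaled by edge weight raised to
    ``edge_weight_influence``), repulsion between every node pair scales with
    (degree+1)(degree+1)/distance, and a central gravity term keeps
    disconnected components on the canvas. The step size decays geometrically
    and iteration stops early once total displacement falls below
    ``tolerance`` x n_nodes.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    p = dict(DEFAULT_FA2)
    p.update(params or {})
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n, 2))
    deg = np.array([graph.degree(v) for v in nodes], dtype=float) + 1.0
    edges = np.array(
        [
            (index[u], index[v], graph.edges[u, v].get("weight", 1.0))
            for u, v in graph.edges
        ]
    )
    step = 0.1
    n_iter = 0
    for n_iter in range(1, iterations + 1):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2)) + 1e-9
        # repulsion ~ k_r * (deg_i+1)(deg_j+1) / d, pairwise
        rep = p["repulsion"] * np.outer(deg, deg) / (dist**2)
        np.fill_diagonal(rep, 0.0)
        force = (rep[:, :, None] * delta).sum(axis=1)
        if len(edges):
            i = edges[:, 0].astype(int)
            j = edges[:, 1].astype(int)
            w = edges[:, 2] ** p["edge_weight_influence"]
            pull = (pos[j] - pos[i]) * w[:, None]
            np.add.at(force, i, pull)
            np.add.at(force, j, -pull)
        force -= p["gravity"] * deg[:, None] * pos
        norm = np.sqrt((force**2).sum(axis=1, keepdims=True)) + 1e-9
        move = step * force / np.maximum(norm / 10.0, 1.0)
        pos += move
        step *= 0.995
        if np.abs(move).sum() < tolerance * n:
            break
    coords = {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}
    return LayoutResult(coords, "forceatlas2-simplified", p, seed, n_iter)


def kruskal_stress(coords: np.ndarray, dissimilarity: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix,
    over all pairs."""
    n = coords.shape[0]
    if n < 2:
        return 0.0
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(n, 1)
    denom = (dissimilarity[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d[iu] - dissimilarity[iu]) ** 2).sum() / denom))


def _classical_mds(delta: np.ndarray) -> np.ndarray:
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w2)


def mds_layout(
    node_ids: list[str],
    dissimilarity: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> LayoutResult:
    """2-D metric MDS of a dissimilarity matrix with Kruskal stress-1.

    Initialised from the classical-scaling eigendecomposition, then refined
    by SMACOF stress majorisation; fully deterministic (no random restarts).
    Configurations that are exactly 2-D embeddable (e.g. collinear genomic
    positions) reach stress 0. Fewer than 3 nodes are placed analytically.
    """
    delta = np.asarray(dissimilarity, dtype=float)
    n = len(node_ids)
    if delta.shape != (n, n):
        raise ValueError("dissimilarity matrix shape mismatch")
    if n == 1:
        coords = np.zeros((1, 2))
    elif n == 2:
        coords = np.array([[0.0, 0.0], [delta[0, 1], 0.0]])
    else:
        coords = _classical_mds(delta)
        # SMACOF majorisation of raw stress
        prev = np.inf
        it = 0
        for it in range(max_iter):
            d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
            np.fill_diagonal(d, 1.0)
            ratio = delta / d
            np.fill_diagonal(ratio, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            coords = (b @ coords) / n
            s = kruskal_stress(coords, delta)
            if prev - s < tol:
                break
            prev = s
    stress = kruskal_stress(coords, delta)
    return LayoutResult(
        {node: (float(x), float(y)) for node, (x, y) in zip(node_ids, coords)},
        "mds-smacof",
        {"max_iter": max_iter, "tol": tol},
        None,
        0 if n < 3 else it + 1,
        stress=stress,
    )


def genomic_mds_layout(network, node_ids: list[str], max_iter: int = 300) -> LayoutResult:
    """MDS layout of a node set using linear genomic distance between fragment
    midpoints as the dissimilarity; trans pairs get the maximum observed cis
    distance (flagged in the parameters)."""
    fm = network.fragment_map
    mids = np.array([fm.midpoint(f) for f in node_ids])
    chroms = [fm.chrom_of(f) for f in node_ids]
    n = len(node_ids)
    delta = np.abs(mids[:, None] - mids[None, :])
    same = np.array([[c1 == c2 for c2 in chroms] for c1 in chroms])
    has_trans = bool((~same).any())
    if has_trans:
        max_cis = delta[same].max() if same.any() else 1.0
        delta = np.where(same, delta, max_cis)
        np.fill_diagonal(delta, 0.0)
    result = mds_layout(node_ids, delta, max_iter=max_iter)
    result.parameters["trans_pairs_clamped"] = has_trans
    return result


# distinct colours for all eight fragment state labels
STATE_COLOURS = {
    "active": "#7fbf4d",
    "h3k4me1_only": "#1b6b1b",
    "bivalent": "#f59e0b",
    "polycomb": "#d62728",
    "heterochromatin": "#7b2d8b",
    "unclassified": "#3b76af",
    "background": "#b0b0b0",
    "mixed": "#e377c2",
}

SPECIFICITY_COLOURS = {
    "A_specific": "#2166ac",
    "B_specific": "#b2182b",
    "shared": "#878787",
}

EXPRESSION_COLOURS = {
    "up": "#b2182b",
    "down": "#2166ac",
    "unchanged": "#bdbdbd",
    "mixed": "#f4a582",
}

_COLOUR_MAPS = {
    "state": STATE_COLOURS,
    "specificity": SPECIFICITY_COLOURS,
    "expression": EXPRESSION_COLOURS,
}


def render_static(
    graph: nx.Graph,
    layout: LayoutResult,
    path,
    colour_by: str = "specificity",
    node_attribute: str | None = None,
    size_by: str = "degree",
) -> dict:
    """Render a laid-out network to SVG/PNG with a legend.

    Node size is a monotone function of degree; node colour comes from the
    requested categorical map (state / specificity / expression) read from
    ``node_attribute`` (defaults to the map name). Returns the styling
    actually used (sizes and colours per node) for inspection.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if colour_by not in _COLOUR_MAPS:
        raise ValueError(f"unknown styling key {colour_by!r}")
    if size_by != "degree":
        raise ValueError(f"unknown styling key {size_by!r}")
    cmap = _COLOUR_MAPS[colour_by]
    attr = node_attribute or colour_by
    nodes = sorted(graph.nodes)
    deg = np.array([graph.degree(v) for v in nodes], dtype=float)
    max_deg = deg.max() if len(deg) and deg.max() > 0 else 1.0
    sizes = 10 + 90 * deg / max_deg
    colours = [
        cmap.get(str(graph.nodes[v].get(attr, "")), "#000000") for v in nodes
    ]
    xy = np.array([layout.coordinates[v] for v in nodes])
    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v in graph.edges:
        x1, y1 = layout.coordinates[u]
        x2, y2 = layout.coordinates[v]
        ax.plot([x1, x2], [y1, y2], color="#cccccc", linewidth=0.5, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=sizes, c=colours, zorder=2)
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=col, label=lab)
        for lab, col in cmap.items()
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)
    return {
        "sizes": dict(zip(nodes, sizes.tolist())),
        "colours": dict(zip(nodes, colours)),
    }
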