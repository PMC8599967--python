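"""MCODE-style molecular-complex detection on PPI graphs.

Implements the classic three-stage procedure: (1) weight every vertex by
the highest k-core of its closed neighborhood times that core's density;
(2) seed complexes from the highest-weighted unassigned vertex and grow
them outward through neighbors whose weight is within ``node_score_cutoff``
of the seed weight; (3) post-process with an optional haircut (iteratively
strip singly-connected members) and keep complexes with at least
``min_size`` members containing a ``k_core``-core.  Ties are broken by
node id so the output is independent of edge-list order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx


@dataclass
class Cluster:
    """A detected complex: member nodes and the density-based score
    (subgraph density times member count)."""

    cluster_id: int
    members: List[str]
    score: float


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph) -> Dict[str, float]:
    """Core-density vertex weighting.

    For each vertex v, take the subgraph induced on v and its neighbors,
    find its highest k-core, and set weight(v) = k * density(core).
    Isolated vertices weigh 0.
    """
    weights: Dict[str, float] = {}
    for v in graph.nodes:
        nbhd = graph.subgraph(set(graph[v]) | {v})
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        cores = nx.core_number(nbhd)
        kmax = max(cores.values())
        core_nodes = [u for u, c in cores.items() if c == kmax]
        core = nbhd.subgraph(core_nodes)
        weights[v] = kmax * _density(core)
    return weights


def mcode_cluster(
    graph: nx.Graph | Iterable[Tuple[str, str]],
    k_core: int = 2,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_size: int = 3,
) -> List[Cluster]:
    """Detect dense complexes in a simple undirected graph.

    ``graph`` may be a networkx graph or an iterable of edges.  Self-loops
    are removed.  ``fluff`` (adding back dense neighbors) is accepted for
    interface compatibility with the original tool but off by default.
    Returns clusters sorted by descending score, ties by smallest member
    id.
    """
    if not isinstance(graph, nx.Graph):
        g = nx.Graph()
        g.add_edges_from(graph)
    else:
        g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        return []

    weights = vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw_clusters: List[List[str]] = []
    threshold_of: List[float] = []

    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in sorted(g[v], key=str):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append(u)
        assigned |= members
        raw_clusters.append(sorted(members, key=str))
        threshold_of.append(threshold)

    clusters: List[Cluster] = []
    for members, threshold in zip(raw_clusters, threshold_of):
        sub = g.subgraph(members).copy()
        if haircut:
            while True:
                leaves = [v for v in sub.nodes if sub.degree(v) < 2]
                if not leaves or sub.number_of_nodes() - len(leaves) < 2:
                    break
                sub.remove_nodes_from(leaves)
        if fluff:
            fringe = set()
            for v in list(sub.nodes):
                for u in g[v]:
                    if u in sub or u in fringe:
                        continue
                    nbhd = g.subgraph(set(g[u]) | {u})
                    if _density(nbhd) >= threshold:
                        fringe.add(u)
            sub = g.subgraph(set(sub.nodes) | fringe).copy()
        if sub.number_of_nodes() < min_size:
            continue
        if max(nx.core_number(sub).values(), default=0) < k_core:
            continue
        clusters.append(
            Cluster(
                cluster_id=0,
                members=sorted(sub.nodes, key=str),
                score=_density(sub) * sub.number_of_nodes(),
            )
        )
    clusters.sort(key=lambda c: (-c.score, c.members))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def clusters_table(clusters: Sequence[Cluster]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "score": [c.score for c in clusters],
            "n_members": [len(c.members) for c in clusters],
            "members": [",".join(c.members) for c in clusters],
        }
    )
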