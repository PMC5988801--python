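"""Classical edge- and vertex-based comparison measures.

Edge level: betweenness centrality (number of geodesics through an edge),
embeddedness (common neighbours of the endpoints) and dispersion (how
poorly connected those common neighbours are among themselves). Vertex
level: degree, betweenness centrality and local clustering coefficient.

Betweenness values are left unnormalized (pair counts); rank correlations
are invariant to the positive scaling. Dispersion is the absolute variant:
for an edge (u, v) it sums, over unordered pairs {s, t} of common
neighbours, an indicator that s and t are non-adjacent and share no common
neighbour other than u and v themselves.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from .graph import triangles_on_edge
from .tables import EdgeMeasureTable, VertexMeasureTable


def edge_betweenness(g: nx.Graph) -> EdgeMeasureTable:
    """Geodesic counts through each edge, over unordered vertex pairs."""
    vals = nx.edge_betweenness_centrality(g, normalized=False)
    return EdgeMeasureTable("ebc", vals)


def embeddedness(g: nx.Graph, e) -> int:
    """|N(u) ∩ N(v)| — identical to the triangle count on the edge."""
    return triangles_on_edge(g, e)


def dispersion(g: nx.Graph, e) -> float:
    """Absolute dispersion of edge e = (u, v)."""
    u, v = e
    if not g.has_edge(u, v):
        raise ValueError(f"({u},{v}) is not an edge")
    common = set(g[u]) & set(g[v])
    total = 0
    for s, t in combinations(sorted(common), 2):
        if g.has_edge(s, t):
            continue
        if (set(g[s]) & set(g[t])) - {u, v}:
            continue
        total += 1
    return float(total)


def embeddedness_all(g: nx.Graph) -> EdgeMeasureTable:
    return EdgeMeasureTable("emb", {e: embeddedness(g, e) for e in g.edges})


def dispersion_all(g: nx.Graph) -> EdgeMeasureTable:
    return EdgeMeasureTable("dis", {e: dispersion(g, e) for e in g.edges})


def vertex_degree(g: nx.Graph) -> VertexMeasureTable:
    return VertexMeasureTable("deg", dict(g.degree()))


def vertex_betweenness(g: nx.Graph) -> VertexMeasureTable:
    """Brandes betweenness over unordered pairs, endpoints excluded."""
    return VertexMeasureTable("bc", nx.betweenness_centrality(g, normalized=False))


def clustering_coefficient(g: nx.Graph) -> VertexMeasureTable:
    """2 T(v) / (deg(v)(deg(v)-1)), zero for degree < 2."""
    return VertexMeasureTable("cc", nx.clustering(g))


EDGE_MEASURES = {
    "ebc": edge_betweenness,
    "emb": embeddedness_all,
    "dis": dispersion_all,
}

VERTEX_MEASURES = {
    "deg": vertex_degree,
    "bc": vertex_betweenness,
    "cc": clustering_coefficient,
}
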