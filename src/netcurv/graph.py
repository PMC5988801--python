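"""Graph data model and shared primitives.

Graphs are plain :class:`networkx.Graph` objects, always simple and
undirected. Optional strictly positive weights live in standard attribute
slots: ``G.nodes[v]["weight"]`` and ``G.edges[e]["weight"]`` (both default to
1). Weights of triangular faces, used by the weighted augmented curvature,
are passed separately as a mapping ``frozenset({u, v, w}) -> weight``.

Edge-list input follows the KONECT dialect: whitespace-separated columns,
lines starting with ``%`` are comments, the first two columns are vertex
labels and any further columns (weights, timestamps) are ignored. On load,
vertex labels are normalized to contiguous integers ``0..n-1`` (ascending
label order); the original label is kept in ``G.nodes[v]["label"]``.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

INF = math.inf


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


def load_edgelist(path) -> nx.Graph:
    """Read a simple undirected graph from a KONECT-style edge list.

    Duplicate lines (in either orientation) collapse to one edge; self-loop
    lines are dropped with a logged count. Raises
    :class:`EdgeListParseError` on a malformed line (naming its number) and
    :class:`ValueError` if no edge survives.
    """
    edges = set()
    n_loops = 0
    n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%") or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"line {lineno}: non-integer vertex label in {tokens[:2]!r}"
                ) from exc
            if u == v:
                n_loops += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in edges:
                n_dups += 1
            edges.add(key)
    if n_loops:
        logger.warning("dropped %d self-loop line(s) from %s", n_loops, path)
    if n_dups:
        logger.warning("collapsed %d duplicate edge line(s) from %s", n_dups, path)
    if not edges:
        raise ValueError(f"{path}: no edges after dropping self-loops")

    labels = sorted({u for e in edges for u in e})
    index = {lab: i for i, lab in enumerate(labels)}
    g = nx.Graph()
    for i, lab in enumerate(labels):
        g.add_node(i, label=lab)
    g.add_edges_from((index[u], index[v]) for u, v in edges)
    return g


def write_edgelist(g: nx.Graph, path, header: str | None = None) -> None:
    """Write a KONECT-style edge list, using original labels when present."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"% {line}\n")
        for u, v in sorted(
            (u, v) if u <= v else (v, u) for u, v in g.edges
        ):
            lu = g.nodes[u].get("label", u)
            lv = g.nodes[v].get("label", v)
            fh.write(f"{lu} {lv}\n")


def vertex_weight(g: nx.Graph, v) -> float:
    w = float(g.nodes[v].get("weight", 1.0))
    if w <= 0:
        raise ValueError(f"vertex {v} has nonpositive weight {w}")
    return w


def edge_weight(g: nx.Graph, u, v) -> float:
    w = float(g.edges[u, v].get("weight", 1.0))
    if w <= 0:
        raise ValueError(f"edge ({u},{v}) has nonpositive weight {w}")
    return w


def is_weighted(g: nx.Graph) -> bool:
    """True if any vertex or edge carries an explicit weight attribute."""
    return any("weight" in d for _, d in g.nodes(data=True)) or any(
        "weight" in d for _, _, d in g.edges(data=True)
    )


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component, weights carried over.

    Ties between equally large components are broken in favor of the one
    containing the smallest vertex id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no vertices")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def triangles_on_edge(g: nx.Graph, e) -> int:
    """Number of triangles containing edge e = |N(u) ∩ N(v)|."""
    u, v = e
    if not g.has_edge(u, v):
        raise ValueError(f"({u},{v}) is not an edge")
    return len(set(g[u]) & set(g[v]))


def all_triangle_faces(g: nx.Graph) -> list[frozenset]:
    """All 3-cliques of g, as frozensets of three vertices."""
    faces = set()
    for u, v in g.edges:
        for w in set(g[u]) & set(g[v]):
            faces.add(frozenset((u, v, w)))
    return sorted(faces, key=sorted)


def shortest_path_distances(g: nx.Graph, source) -> dict:
    """BFS hop counts from source; unreachable vertices map to math.inf."""
    if source not in g:
        raise ValueError(f"{source} is not a vertex")
    dist = nx.single_source_shortest_path_length(g, source)
    return {v: float(dist.get(v, INF)) for v in g.nodes}

def distance_matrix(g: nx.Graph):
    """All-pairs hop distances.

    Returns ``(D, index)`` where ``D`` is a dense float matrix (``inf`` for
    unreachable pairs) and ``index`` maps vertex id to its row/column.
    """
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight=None, format="csr")
    D = shortest_path(adj, method="D", unweighted=True, directed=False)
    return D, index
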