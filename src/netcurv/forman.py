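"""Forman-Ricci curvature of edges and vertices.

Forman's discretization assigns a curvature to each edge of a weighted CW
complex via a combinatorial Bochner-Weitzenboeck decomposition. On a graph
(1-complex) with edge weights w_e and vertex weights w_v it reads

    F(e) = w_e * ( w_v1/w_e + w_v2/w_e
                   - sum_{e' ~ e} [ w_v/sqrt(w_e w_e') ] )

where the sum runs over edges e' != e incident on either endpoint, each
contributing through the endpoint v it shares with e. With unit weights
this collapses to the combinatorial form F(e) = 4 - deg(v1) - deg(v2).

The *augmented* variant additionally treats every 3-clique as a triangular
2-cell (cycles of length 4 and more are deliberately not filled in). Two
cells are "parallel" when they share a parent (coface) or a child (face)
but not both; only parallel edges enter the curvature sum. With unit
weights the augmented curvature satisfies F#(e) = F(e) + 3 m where m is
the number of triangles containing e, which is the fast path used for
unweighted graphs.
"""

from __future__ import annotations

import math

import networkx as nx

from .graph import (
    all_triangle_faces,
    edge_weight,
    is_weighted,
    triangles_on_edge,
    vertex_weight,
)
from .tables import EdgeMeasureTable, VertexMeasureTable, incident_edge_sums


def _check_edge(g, e):
    u, v = e
    if not g.has_edge(u, v):
        raise ValueError(f"({u},{v}) is not an edge")
    return u, v


def forman_edge(g: nx.Graph, e) -> float:
    """Weighted Forman-Ricci curvature of edge e (1-complex form)."""
    v1, v2 = _check_edge(g, e)
    we = edge_weight(g, v1, v2)
    w1 = vertex_weight(g, v1)
    w2 = vertex_weight(g, v2)
    parallel = 0.0
    for v, wv, other in ((v1, w1, v2), (v2, w2, v1)):
        for nb in g[v]:
            if nb == other:
                continue
            parallel += wv / math.sqrt(we * edge_weight(g, v, nb))
    return we * (w1 / we + w2 / we - parallel)


def forman_edge_combinatorial(g: nx.Graph, e) -> int:
    """F(e) = 4 - deg(v1) - deg(v2) for unweighted graphs."""
    v1, v2 = _check_edge(g, e)
    return 4 - g.degree(v1) - g.degree(v2)


def augmented_forman_edge(g: nx.Graph, e, face_weights: dict | None = None) -> float:
    """Augmented Forman-Ricci curvature of edge e (3-cliques as 2-cells).

    Unweighted graphs take the fast path F(e) + 3 m; if the graph carries
    weights (or explicit ``face_weights`` are given) the full CW-complex
    formula is evaluated via :func:`augmented_forman_edge_cw`.
    """
    if face_weights is None and not is_weighted(g):
        u, v = _check_edge(g, e)
        return float(forman_edge_combinatorial(g, e) + 3 * triangles_on_edge(g, e))
    return augmented_forman_edge_cw(g, e, face_weights)


def augmented_forman_edge_cw(g: nx.Graph, e, face_weights: dict | None = None) -> float:
    """Direct evaluation of the weighted augmented curvature.

    Faces are the 3-cliques containing at least one endpoint of e;
    ``face_weights`` maps ``frozenset({u,v,w})`` to a positive weight
    (missing faces default to 1). For each other edge ê the parallelism
    rule applies: ê contributes only if it shares a face or a vertex with
    e but not both, and its contribution is

        | sum_{f > e, ê} sqrt(w_e w_ê)/w_f  -  sum_{v < e, ê} w_v/sqrt(w_e w_ê) |

    With triangle faces only, an edge co-bounding a face with e always also
    shares a vertex, so the surviving parallel edges are exactly the
    incident edges spanning no common triangle.
    """
    v1, v2 = _check_edge(g, e)
    face_weights = face_weights or {}
    we = edge_weight(g, v1, v2)

    def wf(face):
        w = float(face_weights.get(face, 1.0))
        if w <= 0:
            raise ValueError(f"face {set(face)} has nonpositive weight {w}")
        return w

    # triangles containing e
    apexes = set(g[v1]) & set(g[v2])
    faces_e = {w: frozenset((v1, v2, w)) for w in apexes}

    total = sum(we / wf(f) for f in faces_e.values())
    total += (vertex_weight(g, v1) + vertex_weight(g, v2)) / we

    for v, other in ((v1, v2), (v2, v1)):
        wv = vertex_weight(g, v)
        for nb in g[v]:
            if nb == other:
                continue
            weh = edge_weight(g, v, nb)
            shared_faces = [faces_e[nb]] if nb in apexes else []
            # common child: the shared vertex v. Parallel iff not also a
            # common parent (triangle), per the parallelism rule.
            if shared_faces:
                continue
            total -= abs(0.0 - wv / math.sqrt(we * weh))
    return we * total


def forman_all_edges(
    g: nx.Graph, variant: str = "classical", face_weights: dict | None = None
) -> EdgeMeasureTable:
    """Edge table of the chosen Forman variant over all edges of g.

    variant: "classical" (1-complex) or "augmented" (triangles as 2-cells).
    Unweighted graphs use the combinatorial fast paths.
    """
    if variant not in ("classical", "augmented"):
        raise ValueError(f"unknown variant {variant!r}")
    weighted = is_weighted(g) or face_weights is not None
    vals = {}
    for e in g.edges:
        if variant == "classical":
            vals[e] = forman_edge(g, e) if weighted else forman_edge_combinatorial(g, e)
        else:
            vals[e] = augmented_forman_edge(g, e, face_weights)
    name = "afr" if variant == "augmented" else "fr"
    return EdgeMeasureTable(name, vals)


def populate_face_weights(g: nx.Graph, weight: float = 1.0) -> dict:
    """Explicit unit face weights for all 3-cliques (lazy Eq.-9 path)."""
    return {f: weight for f in all_triangle_faces(g)}


def forman_vertex(g: nx.Graph, edge_table: EdgeMeasureTable) -> VertexMeasureTable:
    """Vertex curvature: sum of incident-edge curvatures (0 if isolated)."""
    return incident_edge_sums(g, edge_table, edge_table.measure_name + "_vertex")
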