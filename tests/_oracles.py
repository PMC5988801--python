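"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the transport oracle
goes through networkx's min-cost-flow network simplex on an integer-scaled
transportation network, the dual bound through an explicitly constructed
1-Lipschitz-potential LP, and the betweenness oracles through exhaustive
enumeration of all geodesics.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.optimize import linprog


def exact_measure(support, masses):
    """(support, Fraction masses) with validation."""
    masses = [Fraction(m) for m in masses]
    assert sum(masses) == 1
    return list(support), masses


def w1_flow_oracle(g, mu, nu):
    """Exact W1 via integer min-cost flow (network simplex).

    mu, nu are (support, Fraction-mass) pairs; hop distances are integers, so
    scaling masses by the lcm of denominators gives an integral transportation
    problem whose optimum is exact.
    """
    (s_mu, m_mu), (s_nu, m_nu) = mu, nu
    scale = math.lcm(*[f.denominator for f in m_mu + m_nu])
    flow_net = nx.DiGraph()
    dist = {s: nx.single_source_shortest_path_length(g, s) for s in s_mu}
    for i, s in enumerate(s_mu):
        flow_net.add_node(("src", i), demand=-int(m_mu[i] * scale))
    for j, t in enumerate(s_nu):
        flow_net.add_node(("dst", j), demand=int(m_nu[j] * scale))
    for i, s in enumerate(s_mu):
        for j, t in enumerate(s_nu):
            flow_net.add_edge(("src", i), ("dst", j), weight=dist[s][t])
    cost = nx.min_cost_flow_cost(flow_net)
    return Fraction(cost, scale)


def w1_dual_bound(g, mu, nu):
    """Best 1-Lipschitz potential value: max sum f (dmu - dnu), |f(a)-f(b)| <= d(a,b)."""
    (s_mu, m_mu), (s_nu, m_nu) = mu, nu
    nodes = sorted(set(s_mu) | set(s_nu))
    idx = {v: i for i, v in enumerate(nodes)}
    delta = np.zeros(len(nodes))
    for s, m in zip(s_mu, m_mu):
        delta[idx[s]] += float(m)
    for t, m in zip(s_nu, m_nu):
        delta[idx[t]] -= float(m)
    dist = {s: nx.single_source_shortest_path_length(g, s) for s in nodes}
    A_ub, b_ub = [], []
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            row = np.zeros(len(nodes))
            row[idx[a]], row[idx[b]] = 1.0, -1.0
            A_ub.append(row)
            b_ub.append(float(dist[a][b]))
    res = linprog(-delta, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=(None, None), method="highs")
    assert res.status == 0
    return -res.fun


def brute_edge_betweenness(g):
    """Edge betweenness by enumerating every geodesic of every pair."""
    acc = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in combinations(sorted(g.nodes), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for u, v in zip(path, path[1:]):
                acc[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return acc


def brute_vertex_betweenness(g):
    """Vertex betweenness (endpoints excluded) by geodesic enumeration."""
    acc = {v: 0.0 for v in g.nodes}
    for s, t in combinations(sorted(g.nodes), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                acc[v] += 1.0 / len(paths)
    return acc


def brute_triangles_on_edge(g, e):
    u, v = e
    return sum(1 for w in g.nodes if w not in (u, v)
               and g.has_edge(u, w) and g.has_edge(v, w))
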