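"""Ensemble comparison and robustness experiments.

Two experiment families:

1. Rank correlations between measures across a seeded ensemble of model
   graphs. For each sample the largest connected component is taken, both
   measures are computed on it, and their Spearman (or Pearson) correlation
   recorded; the report carries per-sample values and their mean.

2. Removal experiments: edges or vertices are deleted cumulatively in an
   order given by a ranking strategy, and the damage is scored by
   communication efficiency

       E = 1/(n (n-1)) * sum_{i<j} 1/d_ij,

   with unreachable pairs contributing 0 and n fixed to the intact vertex
   count so curves are comparable across strategies. A complete graph has
   E = 1/2 under this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .forman import forman_all_edges, forman_vertex
from .generators import ModelSpec
from .graph import distance_matrix, largest_connected_component
from .measures import (
    clustering_coefficient,
    dispersion_all,
    edge_betweenness,
    embeddedness_all,
    vertex_betweenness,
    vertex_degree,
)
from .ollivier import ollivier_all_edges, ollivier_vertex
from .tables import EdgeMeasureTable, VertexMeasureTable, incident_edge_sums

logger = logging.getLogger(__name__)

EDGE_MEASURE_NAMES = ("or", "fr", "afr", "ebc", "emb", "dis")
VERTEX_MEASURE_NAMES = ("or", "fr", "afr", "deg", "bc", "cc")


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


def rank_correlation(x, y, method: str = "spearman") -> float:
    """Spearman (mid-rank) or Pearson correlation of two aligned lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(r):
        raise UndefinedCorrelationError("correlation undefined on this input")
    return float(r)


# ---------------------------------------------------------------------------
# Measure computation on one graph


def _ollivier_table_any(g: nx.Graph, alpha: float) -> EdgeMeasureTable:
    """Ollivier table that tolerates disconnected graphs (per component)."""
    if g.number_of_edges() and nx.is_connected(g):
        return ollivier_all_edges(g, alpha)
    vals = {}
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        vals.update(ollivier_all_edges(sub, alpha).values)
    return EdgeMeasureTable(f"or[alpha={alpha:g}]", vals)


def compute_edge_tables(g: nx.Graph, names, alpha: float = 0.5) -> dict:
    """Edge measure tables by short name ("or", "fr", "afr", "ebc", "emb", "dis")."""
    out = {}
    for name in names:
        if name == "or":
            out[name] = _ollivier_table_any(g, alpha)
        elif name == "fr":
            out[name] = forman_all_edges(g, "classical")
        elif name == "afr":
            out[name] = forman_all_edges(g, "augmented")
        elif name == "ebc":
            out[name] = edge_betweenness(g)
        elif name == "emb":
            out[name] = embeddedness_all(g)
        elif name == "dis":
            out[name] = dispersion_all(g)
        else:
            raise ValueError(f"unknown edge measure {name!r}")
    return out


def compute_vertex_tables(
    g: nx.Graph, names, alpha: float = 0.5, edge_tables: dict | None = None
) -> dict:
    """Vertex measure tables; curvature names are incident-edge sums."""
    edge_tables = dict(edge_tables or {})
    out = {}
    for name in names:
        if name in ("or", "fr", "afr"):
            if name not in edge_tables:
                edge_tables.update(compute_edge_tables(g, [name], alpha))
            out[name] = incident_edge_sums(g, edge_tables[name], name + "_vertex")
        elif name == "deg":
            out[name] = vertex_degree(g)
        elif name == "bc":
            out[name] = vertex_betweenness(g)
        elif name == "cc":
            out[name] = clustering_coefficient(g)
        else:
            raise ValueError(f"unknown vertex measure {name!r}")
    return out


# ---------------------------------------------------------------------------
# Ensemble correlations


@dataclass
class CorrelationReport:
    """Per-sample correlations of one measure pair over a model ensemble."""

    measure_pair: tuple
    level: str
    method: str
    per_sample: list
    spec: ModelSpec | str
    n_samples: int
    alpha: float = 0.5
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_sample))

    @property
    def mean_rounded(self) -> float:
        return round(self.mean, 2)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.measure_pair),
            "level": self.level,
            "method": self.method,
            "mean": self.mean,
            "mean_rounded": self.mean_rounded,
            "per_sample": [float(v) for v in self.per_sample],
            "n_samples": self.n_samples,
            "n_excluded": self.n_excluded,
            "alpha": self.alpha,
            "spec": self.spec.describe() if isinstance(self.spec, ModelSpec) else str(self.spec),
        }


def ensemble_correlations(
    spec: ModelSpec,
    requests,
    n_samples: int = 100,
    alpha: float = 0.5,
    method: str = "spearman",
) -> list[CorrelationReport]:
    """Correlations for several (pair, level) requests over one ensemble.

    Measures are computed once per sample and shared across requests, so
    asking for many pairs costs barely more than asking for one.
    ``requests`` is a list of ``((name_a, name_b), level)``.
    """
    for (pair, level) in requests:
        valid = EDGE_MEASURE_NAMES if level == "edge" else VERTEX_MEASURE_NAMES
        for name in pair:
            if name not in valid:
                raise ValueError(f"unknown {level} measure {name!r}")

    edge_names = sorted(
        {n for (pair, level) in requests for n in pair if level == "edge"}
        | {n for (pair, level) in requests for n in pair
           if level == "vertex" and n in ("or", "fr", "afr")}
    )
    vertex_names = sorted(
        {n for (pair, level) in requests for n in pair if level == "vertex"}
    )

    per_request = [[] for _ in requests]
    excluded = [0 for _ in requests]
    for seed in spec.sample_seeds(n_samples):
        g = largest_connected_component(spec.generate(seed))
        etabs = compute_edge_tables(g, edge_names, alpha)
        vtabs = compute_vertex_tables(g, vertex_names, alpha, edge_tables=etabs)
        edges = list(g.edges)
        verts = list(g.nodes)
        for i, (pair, level) in enumerate(requests):
            tabs, keys = (etabs, edges) if level == "edge" else (vtabs, verts)
            try:
                r = rank_correlation(
                    tabs[pair[0]].array(keys), tabs[pair[1]].array(keys), method
                )
            except UndefinedCorrelationError:
                excluded[i] += 1
                logger.warning(
                    "sample seed=%d: undefined %s correlation for %s, excluded",
                    seed, method, pair,
                )
                continue
            per_request[i].append(r)

    return [
        CorrelationReport(
            measure_pair=tuple(pair),
            level=level,
            method=method,
            per_sample=per_request[i],
            spec=spec,
            n_samples=n_samples,
            alpha=alpha,
            n_excluded=excluded[i],
        )
        for i, (pair, level) in enumerate(requests)
    ]


def ensemble_correlation(
    spec: ModelSpec,
    pair,
    level: str = "edge",
    n_samples: int = 100,
    alpha: float = 0.5,
    method: str = "spearman",
) -> CorrelationReport:
    """Single-pair convenience wrapper over :func:`ensemble_correlations`."""
    return ensemble_correlations(spec, [(tuple(pair), level)], n_samples, alpha, method)[0]


# ---------------------------------------------------------------------------
# Robustness under removal


def communication_efficiency(g: nx.Graph, n_reference: int | None = None) -> float:
    """Average reciprocal hop distance over unordered pairs.

    ``n_reference`` defaults to the current vertex count; during removal
    experiments it stays fixed at the intact count.
    """
    n_ref = g.number_of_nodes() if n_reference is None else n_reference
    if n_ref < 2:
        raise ValueError("n_reference must be >= 2")
    if g.number_of_edges() == 0:
        return 0.0
    D, _ = distance_matrix(g)
    iu = np.triu_indices(D.shape[0], k=1)
    d = D[iu]
    finite = np.isfinite(d)
    return float(np.sum(1.0 / d[finite]) / (n_ref * (n_ref - 1)))


@dataclass
class RemovalCurve:
    """Efficiency as a function of the fraction of units removed."""

    strategy: str
    unit: str
    fractions: np.ndarray
    efficiency: np.ndarray
    alpha: float = 0.5
    seed: int = 0

    def auc(self) -> float:
        return float(np.trapezoid(self.efficiency, self.fractions))


EDGE_STRATEGIES = ("random", "fr_asc", "afr_asc", "or_asc", "ebc_desc")
VERTEX_STRATEGIES = (
    "random", "fr_asc", "afr_asc", "or_asc", "bc_desc", "deg_desc", "cc_desc",
)


def _strategy_order(g, unit, strategy, alpha, rng):
    """Removal order of all units of g under one strategy (ties by id)."""
    if unit == "edge":
        keys = sorted((u, v) if u <= v else (v, u) for u, v in g.edges)
    else:
        keys = sorted(g.nodes)
    if strategy == "random":
        return [keys[i] for i in rng.permutation(len(keys))]
    name, _, direction = strategy.rpartition("_")
    if direction not in ("asc", "desc"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if unit == "edge":
        table = compute_edge_tables(g, [name], alpha)[name]
    else:
        table = compute_vertex_tables(g, [name], alpha)[name]
    sign = 1.0 if direction == "asc" else -1.0
    return sorted(keys, key=lambda k: (sign * table[k], k))


def default_fraction_grid(step: float = 0.02) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def removal_experiment(
    g: nx.Graph,
    unit: str,
    strategy: str,
    fraction_grid=None,
    alpha: float = 0.5,
    seed: int = 0,
    recompute: bool = False,
) -> RemovalCurve:
    """Efficiency curve for one ranking strategy.

    The ranking is computed once on the intact graph (static attack) unless
    ``recompute`` is set, in which case the surviving graph is re-ranked at
    every grid step (adaptive attack). Vertices are removed together with
    their incident edges; n_reference stays at the intact vertex count.
    """
    valid = EDGE_STRATEGIES if unit == "edge" else VERTEX_STRATEGIES
    if unit not in ("edge", "vertex"):
        raise ValueError(f"unit must be 'edge' or 'vertex', got {unit!r}")
    if strategy not in valid:
        raise ValueError(f"unknown {unit} strategy {strategy!r}; expected one of {valid}")
    fractions = np.asarray(
        default_fraction_grid() if fraction_grid is None else fraction_grid, dtype=float
    )
    if np.any(np.diff(fractions) <= 0) or fractions[0] < 0 or fractions[-1] > 1:
        raise ValueError("fraction grid must be strictly increasing within [0, 1]")

    rng = np.random.default_rng(seed)
    n_ref = g.number_of_nodes()
    total = g.number_of_edges() if unit == "edge" else g.number_of_nodes()
    work = g.copy()
    order = None if recompute else _strategy_order(g, unit, strategy, alpha, rng)

    eff = []
    removed = 0
    for frac in fractions:
        k = int(round(frac * total))
        while removed < k:
            if recompute:
                batch = _strategy_order(work, unit, strategy, alpha, rng)[: k - removed]
            else:
                batch = order[removed:k]
            if unit == "edge":
                work.remove_edges_from(batch)
            else:
                work.remove_nodes_from(batch)
            removed += len(batch)
        eff.append(
            communication_efficiency(work, n_ref) if work.number_of_nodes() >= 2 else 0.0
        )
    return RemovalCurve(
        strategy=strategy,
        unit=unit,
        fractions=fractions,
        efficiency=np.array(eff),
        alpha=alpha,
        seed=seed,
    )


def targeted_vs_random_gap(curves) -> list[tuple[str, float]]:
    """Area under each curve, sorted ascending (smaller = faster disintegration)."""
    curves = list(curves)
    base = curves[0].fractions
    for c in curves[1:]:
        if not np.array_equal(c.fractions, base):
            raise ValueError("curves must share the same fraction grid")
    return sorted(((c.strategy, c.auc()) for c in curves), key=lambda t: t[1])
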