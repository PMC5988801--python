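"""Seeded random-graph generators: ER, WS, BA and hyperbolic geometric.

Every generator is deterministic given its parameters and seed, and returns
a simple undirected :class:`networkx.Graph` on vertices ``0..n-1``. Ensemble
experiments derive sample seeds as ``base_seed + i``.

The first three models delegate to networkx:

* ER — ``G(n, p)``, each of the C(n,2) pairs present independently with
  probability p (geometric-skipping sampler, exact same distribution).
* WS — ring lattice with k nearest neighbours, then one endpoint of each
  lattice edge rewired with probability beta to a uniform vertex, rejecting
  self-loops and duplicates; edge count stays nk/2.
* BA — growth with linear preferential attachment (urn sampling without
  replacement); the initial graph is a path on ``m0 = max(m, 2)`` vertices,
  so the final edge count is ``(m0 - 1) + (n - m0) m``.

The hyperbolic geometric graph (T=0) is implemented here: n points on a
hyperbolic disk (curvature constant zeta = 1), angular coordinate uniform,
radial density proportional to sinh(alpha r) with ``alpha = (gamma - 1)/2``,
and a hard connection rule d_H(u, v) <= R. The disk radius R is calibrated
numerically so the expected average degree matches ``k_target``; gamma is
the target power-law exponent of the degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

_MODELS = ("er", "ws", "ba", "hgg")


@dataclass
class ModelSpec:
    """A model name, its parameters, and the base random seed."""

    model: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.model = self.model.lower()
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        self.validate()

    def validate(self) -> None:
        p = self.params
        n = p.get("n", 2)
        if n < 2:
            raise ValueError("n must be >= 2")
        if self.model == "er" and not 0 <= p["p"] <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.model == "ws":
            if p["k"] % 2 or p["k"] >= n:
                raise ValueError("WS requires k even and k < n")
            if not 0 <= p["beta"] <= 1:
                raise ValueError("beta must be in [0, 1]")
        if self.model == "ba":
            m0 = p.get("m0", max(p["m"], 2))
            if not 1 <= p["m"] <= m0 < n:
                raise ValueError("BA requires 1 <= m <= m0 < n")
        if self.model == "hgg":
            if p["gamma"] <= 1:
                raise ValueError("gamma must be > 1")
            if p.get("T", 0) < 0:
                raise ValueError("T must be >= 0")

    def generate(self, seed: int | None = None) -> nx.Graph:
        seed = self.seed if seed is None else seed
        p = self.params
        if self.model == "er":
            return generate_er(p["n"], p["p"], seed)
        if self.model == "ws":
            return generate_ws(p["n"], p["k"], p["beta"], seed)
        if self.model == "ba":
            return generate_ba(p["n"], p["m"], seed, m0=p.get("m0"))
        return generate_hgg(
            p["n"], p["k_target"], p.get("gamma", 2.0), p.get("T", 0.0), seed
        )

    def sample_seeds(self, n_samples: int) -> list[int]:
        """Seeds base_seed + i for an ensemble of n_samples graphs."""
        return [self.seed + i for i in range(n_samples)]

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params.items())
        return f"{self.model}({inner}, seed={self.seed})"


def generate_er(n: int, p: float, seed: int) -> nx.Graph:
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return nx.fast_gnp_random_graph(n, p, seed=seed)


def generate_ws(n: int, k: int, beta: float, seed: int) -> nx.Graph:
    if k % 2 or k >= n:
        raise ValueError("WS requires k even and k < n")
    return nx.watts_strogatz_graph(n, k, beta, seed=seed)


def generate_ba(n: int, m: int, seed: int, m0: int | None = None) -> nx.Graph:
    if m0 is None:
        m0 = max(m, 2)
    if not 1 <= m <= m0 < n + 1:
        raise ValueError("BA requires 1 <= m <= m0 <= n")
    initial = nx.path_graph(m0)
    if n == m0:
        return initial
    return nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=initial)


# ---------------------------------------------------------------------------
# Hyperbolic geometric graphs (T = 0)


def _radial_sample(rng, size, alpha, R):
    """Inverse-CDF sample of the radial density ~ sinh(alpha r) on [0, R]."""
    u = rng.random(size)
    return np.arccosh(1.0 + u * (np.cosh(alpha * R) - 1.0)) / alpha


def _hyperbolic_distance(r1, r2, dtheta):
    # cosh d = cosh r1 cosh r2 - sinh r1 sinh r2 cos(dtheta); clip guards
    # rounding below 1 for near-coincident points.
    ch = np.cosh(r1) * np.cosh(r2) - np.sinh(r1) * np.sinh(r2) * np.cos(dtheta)
    return np.arccosh(np.clip(ch, 1.0, None))


def _expected_degree(R, n, alpha, rng_seed, n_pairs=100_000):
    """Monte-Carlo estimate of the expected average degree at disk radius R."""
    rng = np.random.default_rng(rng_seed)
    r1 = _radial_sample(rng, n_pairs, alpha, R)
    r2 = _radial_sample(rng, n_pairs, alpha, R)
    dtheta = rng.random(n_pairs) * np.pi  # |theta1 - theta2| mod 2pi is uniform on [0, pi)
    p_edge = np.mean(_hyperbolic_distance(r1, r2, dtheta) <= R)
    return (n - 1) * p_edge


def calibrate_hgg_radius(
    n: int, k_target: float, gamma: float, seed: int, rtol: float = 0.02
) -> float:
    """Disk radius R whose expected average degree matches k_target.

    The expected degree is a decreasing function of R (points spread apart
    faster than the connection threshold grows), so bisection applies. The
    Monte-Carlo estimator reuses one substream per call so the bisection sees
    a deterministic monotone function.
    """
    alpha = (gamma - 1.0) / 2.0
    mc_seed = (seed * 1_000_003 + 17) % (2**31)
    lo, hi = 1e-3, 10.0
    while _expected_degree(hi, n, alpha, mc_seed) > k_target:
        lo, hi = hi, hi * 2.0
        if hi > 200:  # degenerate target, essentially empty graph
            break
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        k_hat = _expected_degree(mid, n, alpha, mc_seed)
        if abs(k_hat - k_target) <= rtol * k_target:
            return mid
        if k_hat > k_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_hgg(
    n: int, k_target: float, gamma: float = 2.0, T: float = 0.0, seed: int = 0
) -> nx.Graph:
    if T != 0:
        raise ValueError("only the T=0 (hard threshold) regime is supported")
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    alpha = (gamma - 1.0) / 2.0
    R = calibrate_hgg_radius(n, k_target, gamma, seed)
    rng = np.random.default_rng(seed)
    theta = rng.random(n) * 2.0 * np.pi
    r = _radial_sample(rng, n, alpha, R)

    g = nx.empty_graph(n)
    iu, ju = np.triu_indices(n, k=1)
    d = _hyperbolic_distance(r[iu], r[ju], theta[iu] - theta[ju])
    keep = d <= R
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return g
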