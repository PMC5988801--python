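# Methods

## The two curvature notions

`netcurv` computes two inequivalent discretizations of Ricci curvature on
simple undirected graphs. Both assign a number to each *edge*; vertex
curvature is in both cases the sum over incident edges (the discrete
analogue of scalar curvature).

**Ollivier-Ricci curvature.** For an edge (x, y),

    kappa(x, y) = 1 - W1(m_x, m_y) / d(x, y),

where d is the combinatorial (hop-count) metric, and m_x is the one-step
random-walk measure around x: mass `alpha` (the *idleness*) stays at x and
the rest spreads uniformly over the neighbours. W1 is the Wasserstein-1
(earth mover) distance — the minimum of sum(mass x distance) over all
couplings with marginals m_x and m_y. Positive curvature means the
neighbourhoods are closer than their centres (triangles and short cycles
help); the most negative value on an edge at idleness 0 is -2, since all
support points lie within distance 3 of each other.

**Forman-Ricci curvature.** A combinatorial curvature derived from a
Bochner-Weitzenboeck decomposition on weighted CW complexes. On a graph
with positive edge weights w_e and vertex weights w_v:

    F(e) = w_e * ( w_v1/w_e + w_v2/w_e
                   - sum_{e' ~ e} w_v / sqrt(w_e w_e') ),

the sum running over edges e' != e incident on either endpoint, each
contributing through its shared vertex v. With unit weights this is
F(e) = 4 - deg(v1) - deg(v2): an entirely local quantity, negative on any
edge whose endpoints have combined degree above 4.

**Augmented Forman-Ricci curvature** fills every 3-clique with a
triangular 2-cell and evaluates Forman's CW-complex formula on the
resulting 2-complex. Cells enter the curvature of e only when *parallel*
to it — sharing a parent (coface) or a child (face) but not both. With
triangle faces only, an edge that co-bounds a triangle with e always also
shares a vertex, so it drops out of the sum entirely; the surviving
parallel edges are the incident edges spanning no common triangle. For
unit weights this collapses to the identity F#(e) = F(e) + 3 m, with m the
number of triangles on e, which is the fast path used on unweighted
graphs. Cycles of length 4 and greater are deliberately not filled in;
quadrangular and higher cells are out of scope. For general (non-unit)
weights the formula's absolute value can interact with mixed-sign
contributions; the implementation follows the parent/child classification
literally, and the unit-weight case is pinned to the F + 3m identity by an
oracle sweep in the tests.

## Numerical choices

* **Exact transport LP.** W1 is solved exactly with HiGHS
  (`scipy.optimize.linprog`) on the dense transportation formulation, one
  redundant marginal constraint dropped. No entropic (Sinkhorn)
  approximation is used: curvature values feed *rank* correlations, and at
  these support sizes (typically deg+1 <= a few dozen) the exact LP is
  fast, ~1 ms per edge. Tests cross-check the LP against an integer-scaled
  min-cost-flow oracle (network simplex) and against the dual
  1-Lipschitz-potential LP (strong duality).
* **Distances.** Transport costs are hop distances on the full connected
  graph (not the subgraph of supports), computed once per graph as a dense
  BFS distance matrix and reused by every edge's LP. Unreachable distances
  are an explicit `inf`, never a large number, so reciprocal-distance sums
  treat disconnected pairs as exactly 0.
* **Idleness.** `alpha = 0.5` (the conventional lazy walk) is the default
  for ensemble experiments; the closed-form worked examples (star, path,
  complete graph) hold at `alpha = 0` and are validated there. Edge tables
  record the alpha used. Spearman correlations proved insensitive to the
  choice in the ER ensemble; the acceptance suite re-checks this.
* **Degenerate inputs.** Isolated vertices have no walk measure (error at
  the edge level; vertex-curvature sums give them 0). Measures supported
  on different components have infinite W1 (error, with a pointer to the
  LCC helper). Multiple optimal transport plans may exist; only the
  optimal cost is consumed downstream.
* **Ranking ties** in removal experiments break by ascending edge (u, v)
  or vertex id, so curves are reproducible.

## Graph generators and what the ensembles emulate

The four seeded models reproduce the standard ensembles used for the
correlation tables; defaults in the experiments are n = 1000 with the
parameter combinations named there (ER p = 0.003–0.01; WS k = 2–10,
beta = 0.5; BA m = 2–5; HGG k = 3–10, gamma = 2, T = 0). Ensembles use
seeds `base_seed + i`.

* **ER** G(n, p): each pair independently with probability p
  (geometric-skipping sampler; identical distribution to the naive
  Bernoulli sweep).
* **WS**: ring lattice, k nearest neighbours, one endpoint of each lattice
  edge rewired with probability beta to a uniform target, rejecting
  self-loops and duplicates (rejections are redrawn until valid); edge
  count is conserved at nk/2.
* **BA**: linear preferential attachment, m edges per arriving vertex,
  sampled without replacement from the degree-weighted urn. The seed graph
  is a path on m0 = max(m, 2) vertices — the published description leaves
  the seed topology open, and a connected seed guarantees m distinct
  attachment targets; the choice is recorded in generator metadata since
  tail exponents and correlations can be mildly sensitive to it.
* **HGG** (T = 0 only): n points on a hyperbolic disk with curvature
  constant zeta = 1, angles uniform, radii with density ~ sinh(alpha r),
  alpha = (gamma - 1)/2; hard connection rule d_H <= R. R is calibrated by
  bisection against a Monte-Carlo estimate (1e5 pairs, 2% relative
  tolerance) of the expected average degree, so the realized mean degree
  tracks `k_target` to within sampling error (~15% across seeds at
  n = 1000). Positive temperature regimes are not implemented.

These are clean mathematical ensembles: they have no degree-degree
correlations beyond what the models induce, no weights, no metadata noise.
Passing ensemble tests therefore demonstrates correctness of the measures
and of the comparison protocol on such graphs, not that the empirical
correlations carry over to any particular real network — real networks are
supported through the KONECT-dialect edge-list reader and the same
pipeline, but no real-network values are asserted.

## Experiment protocol

**Correlations.** For each sample: generate, take the largest connected
component (ties by smallest vertex id; needed so transport distances are
finite, and applied to *both* measures so the paired vectors align),
compute both measures, Spearman-correlate (mid-ranks on ties). Reports
carry per-sample values; the mean is rounded to 2 decimals only at the
reporting layer. Samples with undefined correlation (zero variance) are
excluded with a logged count. The acceptance suite runs 25 samples per
ensemble — the sample mean of per-sample Spearman values over 25 graphs of
this size has a standard error well below 0.01, so it is compared at
+/- 0.05 against published means computed from 100 samples.

**Robustness.** Communication efficiency is

    E = 1/(n(n-1)) * sum_{i<j} 1/d_ij

exactly as printed — the unordered-pair sum with the n(n-1) prefactor, so
a complete graph scores 1/2. (The i != j convention would double every
value and change no ordering.) Removal experiments rank units once on the
intact graph (static attack; an adaptive `recompute` mode that re-ranks
the surviving graph at every grid step is available but off by default),
delete cumulatively at a fraction grid (default 0.00:0.02:1.00; the
acceptance suite uses a 0.05 step), and evaluate E with n fixed to the
intact vertex count so curves are comparable across strategies. Edge
strategies: random, fr_asc, afr_asc, or_asc, ebc_desc; vertex strategies
add bc_desc, deg_desc, cc_desc. Curves are compared by trapezoidal
area-under-curve; smaller area = faster disintegration.

## Known limitations

* Ollivier curvature is implemented for unweighted graphs only (the
  weighted case needs a normalization convention for neighbour edge
  weights); Forman variants accept arbitrary positive vertex/edge/face
  weights.
* Dispersion follows the global reading of "no common neighbour other
  than u and v"; the original social-network formulation restricts the
  mediating vertex to the ego network of u. The two coincide on ego
  subgraphs (tested); correlations involving dispersion are
  property-tested, not value-matched.
* Directed graphs, multigraphs, temporal edges, hypergraph extensions and
  curvature flows are out of scope.
* The Lin-Lu-Yau idleness limit (alpha -> 1) is not provided; alpha is a
  plain parameter in [0, 1).
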