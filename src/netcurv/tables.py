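"""Per-edge and per-vertex measure tables.

Edges are keyed by sorted vertex pairs ``(u, v)`` with ``u < v`` so that a
measure computed on an undirected graph has exactly one entry per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def edge_key(u, v):
    """Canonical (sorted) key for an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class EdgeMeasureTable:
    """Values of one edge-level measure on a fixed graph."""

    measure_name: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = {edge_key(*e): float(x) for e, x in self.values.items()}

    def __len__(self):
        return len(self.values)

    def __getitem__(self, e):
        return self.values[edge_key(*e)]

    def array(self, edges):
        """Values aligned with an iterable of edges."""
        return np.array([self[e] for e in edges], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.values.items())
        return pd.DataFrame(
            [(u, v, x) for (u, v), x in rows], columns=["u", "v", "value"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class VertexMeasureTable:
    """Values of one vertex-level measure on a fixed graph."""

    measure_name: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = {v: float(x) for v, x in self.values.items()}

    def __len__(self):
        return len(self.values)

    def __getitem__(self, v):
        return self.values[v]

    def array(self, vertices):
        return np.array([self[v] for v in vertices], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.values.items()), columns=["v", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def incident_edge_sums(g, edge_table: EdgeMeasureTable, name: str) -> VertexMeasureTable:
    """Vertex table whose value at v is the sum of the edge measure over edges
    incident on v (isolated vertices get 0).

    This is the vertex-curvature construction shared by both curvature notions,
    the discrete analogue of scalar curvature.
    """
    sums = {v: 0.0 for v in g.nodes}
    for (u, v), x in edge_table.values.items():
        sums[u] += x
        sums[v] += x
    return VertexMeasureTable(name, sums)
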