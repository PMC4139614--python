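"""Province adjacency graphs and the intrinsic CAR (ICAR) precision matrix.

The spatial prior used throughout the package is the intrinsic conditional
autoregressive (ICAR, Markov random field) prior: for a region effect vector
``s`` over the nodes of an adjacency graph, the prior density is proportional
to ``exp(-s' Q s / (2 tau2))`` with ``Q = D - A`` the graph Laplacian
(degree matrix minus adjacency matrix).  ``Q`` is singular — constant vectors
lie in its null space — which is why the model imposes a sum-to-zero
constraint on the spatial effect.

The adjacency structure is configuration, not code: the package ships a
default edge list for the 11 pre-2015 provinces of the Democratic Republic
of Congo (see :func:`default_drc_graph`), but every result downstream is a
function of whatever graph is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AdjacencyGraph",
    "ICARPrecision",
    "load_graph",
    "is_connected",
    "icar_precision",
    "default_drc_graph",
    "DRC_PROVINCES",
]

#: Pre-2015 DRC province codes, in the canonical node order used by the
#: default graph and the synthetic-data presets.
DRC_PROVINCES: tuple[str, ...] = (
    "KIN", "BCG", "BDD", "EQT", "ORI", "NKV", "MNM", "SKV", "KTG", "KOC", "KOR",
)


class GraphError(ValueError):
    """Raised for malformed adjacency input (self-loops, unknown codes...)."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected graph over named regions.

    Parameters
    ----------
    nodes
        Ordered region codes; the order fixes the row/column order of every
        matrix built from the graph.
    edges
        Unordered node pairs, stored canonically as ``frozenset`` of sorted
        tuples; duplicates and reversed duplicates collapse.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("duplicate node codes")
        node_set = set(self.nodes)
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise GraphError(f"edge endpoint not in node list: ({a}, {b})")
            canon.add(tuple(sorted((a, b))))
        object.__setattr__(self, "edges", frozenset(canon))

    @classmethod
    def from_edges(cls, nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> "AdjacencyGraph":
        return cls(tuple(nodes), frozenset(tuple(e) for e in edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, code: str) -> int:
        return self.nodes.index(code)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in node order."""
        idx = {c: i for i, c in enumerate(self.nodes)}
        A = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.edges:
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)


@dataclass(frozen=True)
class ICARPrecision:
    """Graph-Laplacian precision structure ``Q = D - A`` with its rank."""

    nodes: tuple[str, ...]
    Q: np.ndarray
    rank: int

    def quadratic_form(self, s: np.ndarray) -> float:
        return float(s @ self.Q @ s)


def load_graph(path: str | Path, nodes: Sequence[str] | None = None) -> AdjacencyGraph:
    """Read an adjacency graph from an edge-list text file.

    The file holds two whitespace- or comma-separated region codes per line;
    blank lines and lines starting with ``#`` are ignored.  A line of the form
    ``nodes: A B C ...`` (or a ``nodes`` argument) fixes the node order;
    otherwise nodes appear in first-encounter order.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    node_order: list[str] | None = list(nodes) if nodes is not None else None
    seen: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("nodes:"):
            node_order = line.split(":", 1)[1].replace(",", " ").split()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise GraphError(f"expected two codes per edge line, got: {raw!r}")
        a, b = parts
        edges.append((a, b))
        for c in (a, b):
            if c not in seen:
                seen.append(c)
    order = node_order if node_order is not None else seen
    unknown = {c for e in edges for c in e} - set(order)
    if unknown:
        raise GraphError(f"edge codes not in node list: {sorted(unknown)}")
    return AdjacencyGraph.from_edges(order, edges)


def default_drc_graph() -> AdjacencyGraph:
    """The packaged pre-2015 DRC 11-province contiguity graph."""
    with resources.as_file(resources.files("geobirth.data") / "drc_provinces.txt") as p:
        return load_graph(p, nodes=DRC_PROVINCES)


def is_connected(g: AdjacencyGraph) -> bool:
    """Breadth-first connectivity check."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    A = g.adjacency_matrix()
    seen = np.zeros(g.n_nodes, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(A[i])[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def icar_precision(g: AdjacencyGraph, rank_rtol: float = 1e-8) -> ICARPrecision:
    """Build ``Q = D - A`` and report its rank.

    Rank is the count of eigenvalues exceeding ``rank_rtol`` times the largest
    eigenvalue; for a graph with ``k`` connected components this equals
    ``n - k``.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    A = g.adjacency_matrix()
    Q = np.diag(A.sum(axis=1)) - A
    ev = np.linalg.eigvalsh(Q)
    top = ev[-1] if ev[-1] > 0 else 1.0
    rank = int(np.sum(ev > rank_rtol * top))
    return ICARPrecision(g.nodes, Q, rank)
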