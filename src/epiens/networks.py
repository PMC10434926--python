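"""Contact-network construction and I/O.

All inference and simulation code in this package operates on a single
canonical :class:`Network` representation: an undirected simple graph whose
nodes are the contiguous integers ``0..n_nodes-1``.  Four synthetic families
are provided (complete b-ary trees, Erdős–Rényi, configuration-model
power-law, random regular) together with a plain edge-list reader for
externally supplied contact networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "build_complete_tree",
    "build_er",
    "build_powerlaw_config",
    "build_random_regular",
    "read_edge_list",
]


@dataclass
class Network:
    """Undirected simple graph with contiguous 0-based node indices.

    Parameters
    ----------
    n_nodes
        Number of nodes ``N``.
    edges
        Set of unordered node pairs stored as sorted tuples ``(i, j)`` with
        ``i < j``.  No self-loops, no duplicates.
    labels
        Optional original node labels (``labels[i]`` is the external label of
        node ``i``); populated by :func:`read_edge_list`.
    """

    n_nodes: int
    edges: set[tuple[int, int]]
    labels: list | None = None

    # derived, cached structures
    _adjacency: list[set[int]] | None = field(default=None, repr=False)
    _csr: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)
    _agg: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range for N={self.n_nodes}")
            if i > j:
                raise ValueError("edges must be stored as sorted tuples")

    # ------------------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> list[set[int]]:
        """Per-node neighbor sets (the sets ∂i)."""
        if self._adjacency is None:
            adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
            for i, j in self.edges:
                adj[i].add(j)
                adj[j].add(i)
            self._adjacency = adj
        return self._adjacency

    @property
    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR neighbor structure ``(indptr, indices)``, neighbors sorted."""
        if self._csr is None:
            adj = self.adjacency
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            for i, nbrs in enumerate(adj):
                indptr[i + 1] = indptr[i] + len(nbrs)
            indices = np.empty(indptr[-1], dtype=np.int64)
            for i, nbrs in enumerate(adj):
                indices[indptr[i]: indptr[i + 1]] = sorted(nbrs)
            self._csr = (indptr, indices)
        return self._csr

    @property
    def degrees(self) -> np.ndarray:
        indptr, _ = self.csr
        return np.diff(indptr)

    @property
    def entry_rows(self) -> np.ndarray:
        """Row index (the node i) of every CSR entry j ∈ ∂i."""
        indptr, _ = self.csr
        return np.repeat(np.arange(self.n_nodes), np.diff(indptr))

    @property
    def aggregator(self) -> sp.csr_matrix:
        """Sparse (N × nnz) 0/1 matrix summing per-entry terms into per-node sums.

        Used to evaluate Σ_{j∈∂i} f(i, j) for all i in one sparse product,
        including degree-zero nodes (which correctly get an empty sum).
        """
        if self._agg is None:
            indptr, indices = self.csr
            nnz = len(indices)
            rows = self.entry_rows
            self._agg = sp.csr_matrix(
                (np.ones(nnz), (rows, np.arange(nnz))), shape=(self.n_nodes, nnz)
            )
        return self._agg

    def neighbors(self, i: int) -> np.ndarray:
        indptr, indices = self.csr
        return indices[indptr[i]: indptr[i + 1]]

    # ------------------------------------------------------------------
    @classmethod
    def from_nx(cls, g: nx.Graph, labels: list | None = None) -> "Network":
        edges = {(min(i, j), max(i, j)) for i, j in g.edges() if i != j}
        return cls(n_nodes=g.number_of_nodes(), edges=edges, labels=labels)

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def build_complete_tree(branching: int, depth: int) -> Network:
    """Complete ``branching``-ary tree of the given depth.

    Node count is ``Σ_{d=0..depth} branching**d``; e.g. branching 5, depth 4
    gives 781 nodes and 780 edges.
    """
    if branching < 1:
        raise ValueError(f"branching must be >= 1, got {branching}")
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    g = nx.balanced_tree(branching, depth) if branching > 1 else nx.path_graph(depth + 1)
    return Network.from_nx(g)


def build_er(n: int, mean_degree: float, seed: int) -> Network:
    """Erdős–Rényi G(n, p) graph with p chosen to hit the target mean degree."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0 <= mean_degree <= n - 1:
        raise ValueError(f"mean_degree must lie in [0, n-1], got {mean_degree}")
    p = mean_degree / (n - 1)
    g = nx.gnp_random_graph(n, p, seed=int(seed))
    return Network.from_nx(g)


def build_powerlaw_config(n: int, gamma: float, k_min: int, seed: int) -> Network:
    """Scale-free graph via the configuration model.

    Degrees are drawn i.i.d. from P(k) ∝ k^{-gamma} for k_min ≤ k ≤ n-1 (the
    degree sum is forced even), wired by random stub matching, then
    simplified: self-loops and parallel edges are dropped.
    """
    if gamma <= 2:
        raise ValueError(f"gamma must be > 2 for a well-behaved tail, got {gamma}")
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    rng = np.random.default_rng(seed)
    ks = np.arange(k_min, n, dtype=float)
    pmf = ks ** (-gamma)
    pmf /= pmf.sum()
    degrees = rng.choice(ks.astype(int), size=n, p=pmf)
    if degrees.sum() % 2 == 1:
        degrees[rng.integers(n)] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(seed))
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return Network.from_nx(g)


def build_random_regular(n: int, k: int, seed: int) -> Network:
    """Random k-regular graph on n nodes (requires n·k even, k < n)."""
    if n * k % 2 == 1:
        raise ValueError(f"n*k must be even, got n={n}, k={k}")
    if k >= n:
        raise ValueError(f"k must be < n, got k={k}, n={n}")
    g = nx.random_regular_graph(k, n, seed=int(seed))
    return Network.from_nx(g)


# ----------------------------------------------------------------------
# edge-list I/O
# ----------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    Lines starting with ``#`` or ``%`` are comments.  Node labels are mapped
    to contiguous indices (in first-appearance order); the original labels
    are kept in ``Network.labels``.  Self-loops and duplicate (undirected)
    edges are dropped.  The graph is treated as undirected.
    """
    path = Path(path)
    label_to_idx: dict[str, int] = {}
    labels: list[str] = []
    edges: set[tuple[int, int]] = set()

    def idx(label: str) -> int:
        if label not in label_to_idx:
            label_to_idx[label] = len(labels)
            labels.append(label)
        return label_to_idx[label]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "%")):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two whitespace-separated tokens, "
                    f"got {len(parts)}: {stripped!r}"
                )
            a, b = idx(parts[0]), idx(parts[1])
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))

    return Network(n_nodes=len(labels), edges=edges, labels=labels)


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write a network back out as a two-column edge list."""
    labels = network.labels or list(range(network.n_nodes))
    with open(path, "w") as fh:
        for i, j in sorted(network.edges):
            fh.write(f"{labels[i]} {labels[j]}\n")
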