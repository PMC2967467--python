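"""Binary graphs from synchronization matrices and small-world metrics.

A synchronization matrix is binarized either at a fixed SL threshold T
(an edge exists where SL strictly exceeds T) or at a fixed mean degree
K (the round(N*K/2) strongest pairs become edges, which equalizes edge
counts across subjects regardless of their mean SL).  The resulting
undirected simple graphs are characterized by the mean clustering
coefficient C and the harmonic-mean characteristic path length L, and
normalized against degree-preserving rewired surrogates:
gamma = C / C_s, lambda = L / L_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryGraph",
    "MetricsRecord",
    "graph_from_threshold",
    "graph_from_degree",
    "clustering_coefficient",
    "harmonic_path_length",
    "rewire_surrogate",
    "corrected_metrics",
    "theoretical_references",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph on vertices 0..n_vertices-1."""

    n_vertices: int
    edges: frozenset

    def __post_init__(self) -> None:
        norm = set()
        for (i, j) in self.edges:
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise ValueError(f"edge ({i},{j}) out of vertex range")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_vertices, self.n_vertices), dtype=bool)
        for (i, j) in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "BinaryGraph":
        return cls(n_vertices=g.number_of_nodes(),
                   edges=frozenset((int(u), int(v)) for u, v in g.edges()))


@dataclass(frozen=True)
class MetricsRecord:
    """Raw and surrogate-corrected small-world metrics at one level.

    ``lam`` is the corrected path length (lambda = L / L_s); ``n_inf_surrogates``
    counts surrogates whose harmonic L was undefined (edgeless graphs) and
    were excluded from L_s.
    """

    C: float
    L: float
    C_s: float
    L_s: float
    gamma: float
    lam: float
    n_surrogates: int
    n_inf_surrogates: int
    subject_id: str | None = None
    mode: str | None = None
    level: float | None = None


def _offdiag_upper(n: int):
    return np.triu_indices(n, k=1)


def graph_from_threshold(matrix, T: float) -> BinaryGraph:
    """Binarize at fixed threshold: edge (i, j) iff SL_ij > T (strict)."""
    if not 0.0 < T < 1.0:
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    v = np.asarray(matrix.values, dtype=float)
    n = v.shape[0]
    iu, ju = _offdiag_upper(n)
    keep = v[iu, ju] > T
    edges = frozenset(zip(iu[keep].tolist(), ju[keep].tolist()))
    return BinaryGraph(n_vertices=n, edges=edges)


def graph_from_degree(matrix, K: float) -> BinaryGraph:
    """Binarize at fixed mean degree: keep the round(N*K/2) strongest
    off-diagonal pairs as edges.

    Ties are broken deterministically: descending SL, then ascending
    (i, j) lexicographic order.  Two subjects binarized at the same K
    always receive the same edge count, whatever their mean SL.
    """
    v = np.asarray(matrix.values, dtype=float)
    n = v.shape[0]
    if not 0 < K < n:
        raise ValueError(f"mean degree K must lie in (0, N={n}), got {K}")
    n_edges = int(round(n * K / 2.0))
    iu, ju = _offdiag_upper(n)
    w = v[iu, ju]
    order = np.lexsort((ju, iu, -w))
    sel = order[:n_edges]
    edges = frozenset(zip(iu[sel].tolist(), ju[sel].tolist()))
    return BinaryGraph(n_vertices=n, edges=edges)


def clustering_coefficient(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """Mean clustering coefficient C and the per-vertex values.

    C_v is the fraction of a vertex's neighbor pairs that are themselves
    connected; vertices of degree < 2 contribute C_v = 0 and are kept in
    the global mean over all vertices.
    """
    a = g.adjacency().astype(np.float64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    per_vertex = np.zeros(g.n_vertices)
    ok = denom > 0
    per_vertex[ok] = triangles[ok] / denom[ok]
    return float(per_vertex.mean()) if g.n_vertices else 0.0, per_vertex


def harmonic_path_length(g: BinaryGraph) -> float:
    """Characteristic path length as the harmonic mean of shortest
    distances: L = n_pairs / sum(1/d_ij), disconnected pairs contributing
    zero inverse distance.

    An entirely edgeless graph has no finite distances at all and is
    flagged by returning ``math.inf``.
    """
    n = g.n_vertices
    if n < 2:
        return math.inf
    if g.n_edges == 0:
        return math.inf
    a = csr_matrix(g.adjacency().astype(np.int8))
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    iu, ju = _offdiag_upper(n)
    dv = d[iu, ju]
    inv = np.where(np.isfinite(dv), 1.0 / np.where(dv > 0, dv, 1.0), 0.0)
    total = inv.sum()
    n_pairs = n * (n - 1) / 2.0
    return float(n_pairs / total)


def rewire_surrogate(g: BinaryGraph, seed, swap_factor: int = 10) -> BinaryGraph:
    """Degree-preserving random surrogate via repeated double-edge swaps.

    Attempts ``swap_factor * E`` swaps (a,b)+(c,d) -> (a,d)+(c,b),
    rejecting any swap that would create a self-loop or duplicate edge,
    so the degree of every vertex is preserved exactly.  Graphs with no
    admissible swap (e.g. a star) are returned unchanged.
    """
    if g.n_edges < 2:
        return g
    rng = np.random.default_rng(seed)
    edges = [list(e) for e in sorted(g.edges)]
    edge_set = set(map(tuple, edges))
    n_attempts = swap_factor * len(edges)
    m = len(edges)
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(tuple(edges[e1]))
        edge_set.discard(tuple(edges[e2]))
        edges[e1] = list(new1)
        edges[e2] = list(new2)
        edge_set.add(new1)
        edge_set.add(new2)
    return BinaryGraph(n_vertices=g.n_vertices,
                       edges=frozenset(map(tuple, edges)))


def corrected_metrics(g: BinaryGraph, n_surrogates: int = 50, seed=0,
                      subject_id: str | None = None, mode: str | None = None,
                      level: float | None = None,
                      swap_factor: int = 10) -> MetricsRecord:
    """C, L and their surrogate-corrected ratios gamma and lambda.

    ``C_s`` and ``L_s`` are means over ``n_surrogates`` degree-preserving
    rewired surrogates of ``g``; surrogates with undefined (infinite) L
    are excluded from ``L_s`` and counted in ``n_inf_surrogates``.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    c, _ = clustering_coefficient(g)
    length = harmonic_path_length(g)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_surrogates)
    c_vals, l_vals = [], []
    n_inf = 0
    for child in child_seeds:
        s = rewire_surrogate(g, child, swap_factor=swap_factor)
        cs, _ = clustering_coefficient(s)
        ls = harmonic_path_length(s)
        c_vals.append(cs)
        if math.isfinite(ls):
            l_vals.append(ls)
        else:
            n_inf += 1
    c_s = float(np.mean(c_vals))
    l_s = float(np.mean(l_vals)) if l_vals else math.nan
    gamma = c / c_s if c_s > 0 else math.nan
    lam = length / l_s if (math.isfinite(length) and l_vals) else math.nan
    return MetricsRecord(C=c, L=length, C_s=c_s, L_s=l_s, gamma=gamma,
                         lam=lam, n_surrogates=n_surrogates,
                         n_inf_surrogates=n_inf, subject_id=subject_id,
                         mode=mode, level=level)


def theoretical_references(N: int, K: float) -> tuple[float, float, float, float]:
    """Reference C and L for ordered and random graphs of size N, mean
    degree K: returns (C_ordered, L_ordered, C_random, L_random) =
    (3/4, N/2K, K/N, ln N / ln K)."""
    if K <= 1:
        raise ValueError(f"K must exceed 1 (log base degenerate), got {K}")
    if N <= K:
        raise ValueError(f"need N > K, got N={N}, K={K}")
    return (0.75, N / (2.0 * K), K / N, math.log(N) / math.log(K))
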