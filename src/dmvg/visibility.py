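"""Visibility graphs and the directed multiplex visibility graph (DMVG).

Two data points ``(t_i, X_i)`` and ``(t_j, X_j)`` of a series are *mutually
visible* when the straight segment joining them passes strictly above every
intermediate point: for all ``k`` with ``t_i < t_k < t_j``,

    X_k < X_j + (X_i - X_j) * (t_j - t_k) / (t_j - t_i).

Ties block visibility (a point exactly on the chord is an obstruction).
Directing every edge forward in time turns the visibility graph into a
directed acyclic graph whose in/out degree asymmetry carries the signature of
time irreversibility. Stacking the per-variable directed graphs over the
shared node base of time points yields the DMVG.

Construction uses a running-max-slope scan: j is visible from i < j iff the
chord slope from i to j strictly exceeds the largest chord slope from i to
any intermediate point — an exact rearrangement of the criterion above. The
inner loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from numba import njit

from .panel import TimeSeriesPanel

__all__ = [
    "is_visible",
    "build_visibility_layer",
    "build_dmvg",
    "compute_degrees",
    "degree_table",
    "VisibilityGraph",
    "DirectedMultiplexVisibilityGraph",
    "DegreeTable",
]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _degree_scan(x, t, din, dout):  # pragma: no cover - exercised via wrappers
    T = x.shape[0]
    for i in range(T - 1):
        dout[i] += 1
        din[i + 1] += 1
        if i + 2 < T:
            max_slope = (x[i + 1] - x[i]) / (t[i + 1] - t[i])
            for j in range(i + 2, T):
                s = (x[j] - x[i]) / (t[j] - t[i])
                if s > max_slope:
                    dout[i] += 1
                    din[j] += 1
                    max_slope = s


@njit(cache=True)
def _edge_scan(x, t, src, dst):  # pragma: no cover - exercised via wrappers
    T = x.shape[0]
    m = 0
    for i in range(T - 1):
        src[m] = i
        dst[m] = i + 1
        m += 1
        if i + 2 < T:
            max_slope = (x[i + 1] - x[i]) / (t[i + 1] - t[i])
            for j in range(i + 2, T):
                s = (x[j] - x[i]) / (t[j] - t[i])
                if s > max_slope:
                    src[m] = i
                    dst[m] = j
                    m += 1
                    max_slope = s
    return m


def _layer_degrees(x: np.ndarray, t: np.ndarray):
    T = x.shape[0]
    din = np.zeros(T, dtype=np.int64)
    dout = np.zeros(T, dtype=np.int64)
    _degree_scan(np.ascontiguousarray(x, dtype=np.float64),
                 np.ascontiguousarray(t, dtype=np.float64), din, dout)
    return din, dout


def _layer_edges(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=np.float64)
    t = np.ascontiguousarray(t, dtype=np.float64)
    din, dout = _layer_degrees(x, t)
    m = int(dout.sum())
    src = np.empty(m, dtype=np.int64)
    dst = np.empty(m, dtype=np.int64)
    filled = _edge_scan(x, t, src, dst)
    assert filled == m
    return np.column_stack([src, dst])


# ---------------------------------------------------------------------------
# public point query
# ---------------------------------------------------------------------------

def is_visible(series, times, i: int, j: int) -> bool:
    """Whether data points ``i`` and ``j`` (0-based, ``i < j``) see each other.

    Evaluates the strict visibility criterion directly over every intermediate
    point; adjacent points are always visible.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    T = x.shape[0]
    if not (0 <= i < T and 0 <= j < T):
        raise IndexError(f"node index out of range: ({i}, {j}) for T={T}")
    if i >= j:
        raise ValueError(f"require i < j, got i={i}, j={j}")
    if j == i + 1:
        return True
    k = np.arange(i + 1, j)
    threshold = x[j] + (x[i] - x[j]) * (t[j] - t[k]) / (t[j] - t[i])
    return bool(np.all(x[k] < threshold))


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------

@dataclass
class VisibilityGraph:
    """A single-layer visibility graph over ``n_nodes`` time points.

    ``edges`` holds one row ``(i, j)`` with ``i < j`` per visible pair; in the
    directed variant each edge is oriented forward in time, ``i -> j``. The
    undirected variant has the identical edge set without orientation.
    """

    edges: np.ndarray  # (m, 2) int64, i < j
    n_nodes: int
    directed: bool = True

    def has_edge(self, i: int, j: int) -> bool:
        lo, hi = (i, j) if i < j else (j, i)
        mask = (self.edges[:, 0] == lo) & (self.edges[:, 1] == hi)
        return bool(mask.any())

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set:
        return {(int(a), int(b)) for a, b in self.edges}

    def to_networkx(self):
        """Export as a networkx (Di)Graph with nodes ``0..T-1``."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass
class DirectedMultiplexVisibilityGraph:
    """N visibility layers over a shared node base of T time points.

    Layer ``l`` is the directed visibility graph of variable ``l``; every edge
    points forward in time (``i -> j`` with ``i < j``).
    """

    layer_edges: List[np.ndarray]
    n_nodes: int
    layer_names: List[str]
    source_sample_id: str = ""

    @property
    def n_layers(self) -> int:
        return len(self.layer_edges)

    def layer(self, l: int) -> VisibilityGraph:
        return VisibilityGraph(self.layer_edges[l], self.n_nodes, directed=True)

    def has_edge(self, l: int, i: int, j: int) -> bool:
        return self.layer(l).has_edge(i, j)


@dataclass
class DegreeTable:
    """Per-layer, per-node directed degrees of one sample's DMVG.

    The undirected degree decomposes as ``d = din + dout``; the first node of
    every layer has ``din = 0`` and the last ``dout = 0``, all other nodes have
    both degrees >= 1 because adjacent points are always visible.
    """

    din: np.ndarray  # (n_layers, n_nodes)
    dout: np.ndarray

    def __post_init__(self) -> None:
        self.din = np.asarray(self.din, dtype=np.int64)
        self.dout = np.asarray(self.dout, dtype=np.int64)
        if self.din.shape != self.dout.shape or self.din.ndim != 2:
            raise ValueError("din and dout must be 2-D arrays of equal shape")

    @property
    def d(self) -> np.ndarray:
        return self.din + self.dout

    @property
    def n_layers(self) -> int:
        return self.din.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.din.shape[1]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_visibility_layer(series, times=None, directed: bool = True) -> VisibilityGraph:
    """Build the (directed) visibility graph of a univariate series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {x.shape[0]}")
    t = (np.arange(1, x.shape[0] + 1, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    if t.shape != x.shape or not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing and match the series")
    return VisibilityGraph(_layer_edges(x, t), n_nodes=x.shape[0], directed=directed)


def build_dmvg(panel: TimeSeriesPanel) -> DirectedMultiplexVisibilityGraph:
    """Build the directed multiplex visibility graph of a panel.

    Applies the visibility algorithm to each variable in turn; layers are
    independent and share the node base of time points.
    """
    edges = [_layer_edges(row, panel.time_indices) for row in panel.values]
    return DirectedMultiplexVisibilityGraph(
        layer_edges=edges,
        n_nodes=panel.n_times,
        layer_names=list(panel.variable_names),
        source_sample_id=panel.sample_id,
    )


def compute_degrees(g: DirectedMultiplexVisibilityGraph) -> DegreeTable:
    """In- and out-degrees of every node in every layer of a DMVG."""
    L, T = g.n_layers, g.n_nodes
    din = np.zeros((L, T), dtype=np.int64)
    dout = np.zeros((L, T), dtype=np.int64)
    for l, e in enumerate(g.layer_edges):
        if e.shape[0]:
            dout[l] = np.bincount(e[:, 0], minlength=T)
            din[l] = np.bincount(e[:, 1], minlength=T)
    return DegreeTable(din=din, dout=dout)


def degree_table(panel: TimeSeriesPanel) -> DegreeTable:
    """Degree table of a panel's DMVG without materialising edge lists.

    Equivalent to ``compute_degrees(build_dmvg(panel))`` but runs the degree
    scan directly; used on hot paths (surrogate testing) where only degrees
    are needed.
    """
    L, T = panel.n_variables, panel.n_times
    din = np.zeros((L, T), dtype=np.int64)
    dout = np.zeros((L, T), dtype=np.int64)
    t = panel.time_indices
    for l in range(L):
        a, b = _layer_degrees(panel.values[l], t)
        din[l] = a
        dout[l] = b
    return DegreeTable(din=din, dout=dout)
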