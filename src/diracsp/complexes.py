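"""Oriented 1-complexes: nodes, oriented edges and the boundary matrix.

A network ``G = (V, E)`` with ``N0`` nodes and ``N1`` edges is stored as an
:class:`OrientedComplex`.  Every edge carries an orientation (an ordered pair
``[r, s]``); the canonical convention orients each edge from the smaller to
the larger node label.  The signed node-by-edge incidence matrix ``B`` (the
boundary matrix) encodes both the discrete gradient ``B^T`` (node signal ->
edge differences) and the discrete divergence ``B`` (edge flows -> net
in/out-flow per node):

    B[r, e] = +1  if node r is the head of edge e = [s, r]
    B[r, e] = -1  if node r is the tail of edge e = [r, s]
    B[r, e] =  0  otherwise

All results of the signal-processing algorithms built on top of this module
are equivariant under re-orientation of the edges; :func:`flip_orientation`
exists so that this equivariance can be exercised and tested.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "OrientedComplex",
    "build_complex",
    "boundary_matrix",
    "flip_orientation",
    "betti_numbers",
]


class OrientedComplex:
    """A graph with oriented edges and its boundary matrix.

    Parameters
    ----------
    node_ids : sequence of int
        Distinct integer node labels, in the order defining the matrix rows.
    edges : sequence of (int, int)
        Ordered node pairs ``(tail, head)``; the pair order is the stored
        orientation.  Self-loops and duplicate undirected edges are rejected.

    Notes
    -----
    User-facing node labels are arbitrary integers; internally they map to
    contiguous 0-based indices through ``node_index``.  Use
    :func:`build_complex` to obtain the canonical (sorted, small-to-large
    oriented) complex from a raw edge list.
    """

    def __init__(self, node_ids: Sequence[int], edges: Sequence[tuple[int, int]]):
        node_ids = [int(v) for v in node_ids]
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node ids")
        if len(node_ids) == 0:
            raise ValueError("empty complex: no nodes")
        self.node_ids: tuple[int, ...] = tuple(node_ids)
        self.node_index: dict[int, int] = {v: i for i, v in enumerate(self.node_ids)}

        seen: set[frozenset[int]] = set()
        stored: list[tuple[int, int]] = []
        for pair in edges:
            r, s = (int(pair[0]), int(pair[1]))
            if r == s:
                raise ValueError(f"self-loop on node {r}")
            if r not in self.node_index or s not in self.node_index:
                raise ValueError(f"edge ({r},{s}) references unknown node")
            key = frozenset((r, s))
            if key in seen:
                raise ValueError(f"duplicate undirected edge ({r},{s})")
            seen.add(key)
            stored.append((r, s))
        self.edges: tuple[tuple[int, int], ...] = tuple(stored)
        self.edge_index: dict[frozenset[int], int] = {
            frozenset(e): i for i, e in enumerate(self.edges)
        }
        self._boundary = self._build_boundary()

    def _build_boundary(self) -> sp.csc_matrix:
        n0, n1 = self.n_nodes, self.n_edges
        rows, cols, vals = [], [], []
        for j, (r, s) in enumerate(self.edges):
            rows.append(self.node_index[r])
            cols.append(j)
            vals.append(-1)  # tail
            rows.append(self.node_index[s])
            cols.append(j)
            vals.append(1)  # head
        return sp.csc_matrix(
            (np.asarray(vals, dtype=np.int8), (rows, cols)), shape=(n0, n1)
        )

    # -- basic sizes -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_simplices(self) -> int:
        """Total number of simplices N = N0 + N1 (spinor length)."""
        return self.n_nodes + self.n_edges

    @property
    def boundary(self) -> sp.csc_matrix:
        """The N0 x N1 signed incidence (boundary) matrix B."""
        return self._boundary

    def boundary_dense(self) -> np.ndarray:
        return self._boundary.toarray().astype(float)

    # -- helpers -----------------------------------------------------
    def edge_key(self, edge: tuple[int, int]) -> int:
        """Column index of an edge given in either orientation."""
        key = frozenset((int(edge[0]), int(edge[1])))
        if key not in self.edge_index:
            raise KeyError(f"unknown edge {tuple(edge)}")
        return self.edge_index[key]

    def edge_sign(self, edge: tuple[int, int]) -> int:
        """+1 if ``edge`` matches the stored orientation, -1 if reversed."""
        j = self.edge_key(edge)
        return 1 if self.edges[j] == (int(edge[0]), int(edge[1])) else -1

    def __repr__(self) -> str:  # pragma: no cover
        return f"OrientedComplex(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OrientedComplex)
            and self.node_ids == other.node_ids
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.node_ids, self.edges))


def build_complex(
    edge_list: Iterable[Sequence[int]],
    node_ids: Sequence[int] | None = None,
) -> OrientedComplex:
    """Build the canonically oriented complex from a raw edge list.

    Edges are re-oriented small-label-to-large-label and sorted
    lexicographically; nodes are the sorted union of the endpoint labels and
    any explicitly supplied ``node_ids`` (which may add isolated nodes).
    """
    edges = []
    for pair in edge_list:
        r, s = int(pair[0]), int(pair[1])
        if r == s:
            raise ValueError(f"self-loop on node {r}")
        edges.append((min(r, s), max(r, s)))
    if not edges and not node_ids:
        raise ValueError("empty edge list and no node ids")
    if len(set(map(frozenset, edges))) != len(edges):
        raise ValueError("duplicate undirected edge in edge list")
    nodes = set(node_ids or []) | {v for e in edges for v in e}
    return OrientedComplex(sorted(nodes), sorted(edges))


def boundary_matrix(c: OrientedComplex) -> sp.csc_matrix:
    """The boundary matrix B of the complex (one +1 and one -1 per column)."""
    return c.boundary


def flip_orientation(
    c: OrientedComplex, edge_subset: Iterable[Sequence[int]]
) -> OrientedComplex:
    """Return a copy of ``c`` with the listed edges stored in reversed
    orientation (their boundary columns negated).

    The graph Laplacian ``L0`` and the spectrum of the Dirac operator are
    invariant under any such flip; edge-signal entries transform by a sign.
    """
    flips = set()
    for pair in edge_subset:
        flips.add(c.edge_key((int(pair[0]), int(pair[1]))))
    new_edges = [
        (s, r) if j in flips else (r, s) for j, (r, s) in enumerate(c.edges)
    ]
    return OrientedComplex(c.node_ids, new_edges)


def betti_numbers(c: OrientedComplex) -> tuple[int, int]:
    """Betti numbers (beta0, beta1): connected components and independent
    cycles.  ``beta0 = N0 - rank(B)``, ``beta1 = N1 - rank(B)``."""
    if c.n_edges == 0:
        return c.n_nodes, 0
    adj = abs(c.boundary) @ abs(c.boundary).T
    beta0, _ = connected_components(adj, directed=False)
    rank = c.n_nodes - beta0
    return beta0, c.n_edges - rank
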