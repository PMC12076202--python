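"""Topological spinors: joint node + edge signal vectors.

The state of a network signal is the direct sum of a node signal (0-cochain)
``chi`` and an edge signal (1-cochain) ``phi``, stacked node-block-first into
one vector ``psi`` of length ``N = N0 + N1``.
"""

from __future__ import annotations

import numpy as np

from .complexes import OrientedComplex

__all__ = ["TopologicalSpinor", "make_spinor", "split_spinor"]


class TopologicalSpinor:
    """A real vector on the simplices of a complex (nodes first, then edges)."""

    __slots__ = ("values", "complex")

    def __init__(self, values: np.ndarray, complex: OrientedComplex):
        values = np.asarray(values, dtype=float).ravel()
        if values.shape[0] != complex.n_simplices:
            raise ValueError(
                f"spinor length {values.shape[0]} != N0+N1 = {complex.n_simplices}"
            )
        self.values = values
        self.complex = complex

    @property
    def chi(self) -> np.ndarray:
        """Node block (length N0)."""
        return self.values[: self.complex.n_nodes]

    @property
    def phi(self) -> np.ndarray:
        """Edge block (length N1)."""
        return self.values[self.complex.n_nodes :]

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def copy(self) -> "TopologicalSpinor":
        return TopologicalSpinor(self.values.copy(), self.complex)

    # minimal vector arithmetic; results stay attached to the complex
    def _check(self, other: "TopologicalSpinor") -> None:
        if other.complex is not self.complex and other.complex != self.complex:
            raise ValueError("spinors live on different complexes")

    def __add__(self, other: "TopologicalSpinor") -> "TopologicalSpinor":
        self._check(other)
        return TopologicalSpinor(self.values + other.values, self.complex)

    def __sub__(self, other: "TopologicalSpinor") -> "TopologicalSpinor":
        self._check(other)
        return TopologicalSpinor(self.values - other.values, self.complex)

    def __mul__(self, a: float) -> "TopologicalSpinor":
        return TopologicalSpinor(self.values * float(a), self.complex)

    __rmul__ = __mul__

    def __neg__(self) -> "TopologicalSpinor":
        return TopologicalSpinor(-self.values, self.complex)

    def dot(self, other: "TopologicalSpinor") -> float:
        self._check(other)
        return float(self.values @ other.values)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TopologicalSpinor(N0={self.complex.n_nodes}, "
            f"N1={self.complex.n_edges}, norm={self.norm():.4g})"
        )


def make_spinor(
    chi: np.ndarray, phi: np.ndarray, c: OrientedComplex
) -> TopologicalSpinor:
    """Stack a node vector and an edge vector into one spinor."""
    chi = np.asarray(chi, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    if chi.shape[0] != c.n_nodes:
        raise ValueError(f"node block length {chi.shape[0]} != N0 = {c.n_nodes}")
    if phi.shape[0] != c.n_edges:
        raise ValueError(f"edge block length {phi.shape[0]} != N1 = {c.n_edges}")
    return TopologicalSpinor(np.concatenate([chi, phi]), c)


def split_spinor(psi: TopologicalSpinor) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`make_spinor`: return (node block, edge block)."""
    return psi.chi.copy(), psi.phi.copy()
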