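"""The Dirac operator, gamma matrix and Hodge Laplacians of a network.

The topological Dirac operator couples node and edge signals through the
boundary matrix B:

    D = [[0,   B ],
         [B^T, 0 ]]

Its square is the block-diagonal (Gauss-Bonnet) Laplacian diag(L0, L1) with
L0 = B B^T the graph Laplacian and L1 = B^T B the first-order (edge) Hodge
Laplacian, so D acts as a square root of the Laplacian.  The diagonal gamma
matrix (+1 on the node block, -1 on the edge block) defines the massive
Hamiltonian H = D + m*gamma whose eigenvalue problem is the stationary
topological Dirac equation.

A :class:`DiracSystem` bundles these operators for one complex and caches the
singular value decomposition of B, from which the full eigenstructure of
H = D + m*gamma follows in closed form for every mass m (see
:mod:`diracsp.spectrum`).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .complexes import OrientedComplex, betti_numbers

__all__ = ["DiracSystem", "dirac_system"]

#: singular values below this fraction of the largest are treated as zero
HARMONIC_RTOL = 1e-10


class DiracSystem:
    """Operator algebra (B, D, gamma, L0, L1) attached to one complex.

    Matrices are held sparse; dense copies are materialised on demand for
    eigen-decompositions (the networks targeted here are small enough that a
    full decomposition is the natural tool).  Linear solves elsewhere switch
    between a direct factorization and conjugate gradients on size.
    """

    def __init__(self, complex: OrientedComplex):
        self.complex = complex
        n0, n1 = complex.n_nodes, complex.n_edges
        B = complex.boundary.astype(float).tocsr()
        self.B: sp.csr_matrix = B
        self.L0: sp.csr_matrix = (B @ B.T).tocsr()
        self.L1: sp.csr_matrix = (B.T @ B).tocsr()
        self.D: sp.csr_matrix = sp.bmat(
            [[None, B], [B.T, None]], format="csr"
        )
        self.gamma_diag: np.ndarray = np.concatenate(
            [np.ones(n0), -np.ones(n1)]
        )
        self.gamma: sp.dia_matrix = sp.diags(self.gamma_diag)
        self._svd: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._eig_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- sizes -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.complex.n_nodes

    @property
    def n_edges(self) -> int:
        return self.complex.n_edges

    @property
    def n(self) -> int:
        return self.complex.n_simplices

    # -- dense views -------------------------------------------------
    def dirac_dense(self) -> np.ndarray:
        return self.D.toarray()

    def hamiltonian(self, m: float) -> sp.csr_matrix:
        """H = D + m * gamma as a sparse matrix."""
        return (self.D + float(m) * self.gamma).tocsr()

    def hamiltonian_dense(self, m: float) -> np.ndarray:
        return self.D.toarray() + float(m) * np.diag(self.gamma_diag)

    # -- SVD of the boundary matrix ----------------------------------
    def boundary_svd(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full SVD ``B = U diag(s) Vt`` (cached), with sign-fixed singular
        vectors: in each column of U the largest-magnitude entry is positive
        (ties broken by lowest index), and V's sign follows U through the
        pairing B v = s u; null-space columns are sign-fixed independently."""
        if self._svd is None:
            U, s, Vt = np.linalg.svd(self.complex.boundary_dense(), full_matrices=True)
            r = int(np.sum(s > HARMONIC_RTOL * s[0])) if s.size else 0
            for j in range(U.shape[1]):
                col = U[:, j]
                k = int(np.argmax(np.abs(col)))
                if col[k] < 0:
                    U[:, j] = -col
                    if j < r:
                        Vt[j, :] = -Vt[j, :]
            for j in range(r, Vt.shape[0]):
                row = Vt[j, :]
                k = int(np.argmax(np.abs(row)))
                if row[k] < 0:
                    Vt[j, :] = -row
            self._svd = (U, s, Vt)
        return self._svd

    @property
    def rank(self) -> int:
        """Rank of B (= number of positive Dirac eigenvalues)."""
        _, s, _ = self.boundary_svd()
        if s.size == 0:
            return 0
        return int(np.sum(s > HARMONIC_RTOL * s[0]))

    @property
    def lambda_max(self) -> float:
        """Largest eigenvalue magnitude of D = largest singular value of B.

        Serves as the default bound for the mass sweep.
        """
        _, s, _ = self.boundary_svd()
        return float(s[0]) if s.size else 0.0

    def betti_numbers(self) -> tuple[int, int]:
        return betti_numbers(self.complex)

    # -- eigenbasis of H = D + m*gamma -------------------------------
    def eigenbasis(self, m: float) -> tuple[np.ndarray, np.ndarray]:
        """Energies (ascending) and orthonormal eigenvector matrix of
        H = D + m*gamma, built from the SVD of B (cached per mass)."""
        m = float(m)
        if m not in self._eig_cache:
            from .spectrum import _eigenbasis_from_svd

            self._eig_cache[m] = _eigenbasis_from_svd(self, m)
        return self._eig_cache[m]

    def harmonic_basis(self) -> np.ndarray:
        """Orthonormal basis of the kernel of D, node-supported columns
        first (count beta0), then edge/cycle-supported columns (beta1)."""
        U, s, Vt = self.boundary_svd()
        r = self.rank
        n0, n1 = self.n_nodes, self.n_edges
        cols = []
        for j in range(r, n0):
            h = np.zeros(self.n)
            h[:n0] = U[:, j]
            cols.append(h)
        for j in range(r, n1):
            h = np.zeros(self.n)
            h[n0:] = Vt[j, :]
            cols.append(h)
        if not cols:
            return np.zeros((self.n, 0))
        return np.column_stack(cols)

    def nonharmonic_projector_apply(self, x: np.ndarray) -> np.ndarray:
        """Apply the orthogonal projector onto the column space of D
        (``D D^+``), i.e. remove the harmonic component of ``x``."""
        Hb = self.harmonic_basis()
        if Hb.shape[1] == 0:
            return np.asarray(x, dtype=float).copy()
        x = np.asarray(x, dtype=float)
        return x - Hb @ (Hb.T @ x)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiracSystem(N0={self.n_nodes}, N1={self.n_edges})"


def dirac_system(c: OrientedComplex) -> DiracSystem:
    """Construct the Dirac operator algebra for a complex."""
    return DiracSystem(c)
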