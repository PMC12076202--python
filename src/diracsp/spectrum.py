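"""Eigenstructure of the Dirac operator and of the massive Dirac equation.

For a network with boundary matrix ``B = U diag(s) V^T`` (SVD), the Dirac
operator ``D`` has eigenvalues ``+/- lambda`` for every positive singular
value ``lambda`` of B, plus a zero eigenvalue of multiplicity
``beta0 + beta1`` whose eigenspace splits into node-supported (connected
component indicators, beta0 of them) and edge-supported (cycle flows, beta1)
harmonic vectors.

Adding a mass term gives the Hamiltonian ``H = D + m*gamma`` whose
eigenstates obey the relativistic dispersion relation ``E^2 = m^2 +
lambda^2``.  For ``lambda > 0`` the two states are

    psi_+ = C_+ ( u_lambda,            lambda/(|E|+m) v_lambda )   E = +sqrt(m^2+lambda^2)
    psi_- = C_- ( lambda/(|E|+m) u_lambda,  -v_lambda         )   E = -sqrt(m^2+lambda^2)

with C_+- fixing unit Euclidean norm; the mass therefore tunes the relative
scale of the node and edge blocks.  Harmonic states are mass-independent:
``(u_0, 0)`` at energy ``E = +m`` (degeneracy beta0) and ``(0, v_0)`` at
``E = -m`` (degeneracy beta1).  Both branches are verified by the residual
``||(H - E) psi||``, which is the authoritative check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import DiracSystem
from .spinor import TopologicalSpinor

__all__ = [
    "DiracEigenstate",
    "dirac_spectrum",
    "dirac_equation_eigenstates",
    "dispersion_energy",
]


@dataclass(frozen=True)
class DiracEigenstate:
    """One unit-norm eigenpair of H = D + m*gamma.

    Attributes
    ----------
    energy : float
        Eigenvalue E of H.
    lam : float
        The underlying nonnegative singular value of B (0 for harmonic).
    mass : float
        The mass m of the Hamiltonian.
    psi : TopologicalSpinor
        Unit-norm eigenvector.
    kind : str
        One of ``nonharmonic+``, ``nonharmonic-``, ``harmonic-node``,
        ``harmonic-cycle``.
    """

    energy: float
    lam: float
    mass: float
    psi: TopologicalSpinor
    kind: str

    def residual(self, sys: DiracSystem) -> float:
        """``||(H - E I) psi||_2`` — zero (to solver tolerance) by design."""
        v = self.psi.values
        hv = sys.D @ v + self.mass * (sys.gamma_diag * v)
        return float(np.linalg.norm(hv - self.energy * v))


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry positive (ties: lowest index)."""
    k = int(np.argmax(np.abs(v)))
    return -v if v[k] < 0 else v


def dispersion_energy(lam: float, m: float, branch: int = +1) -> float:
    """Relativistic dispersion relation ``E = +/- sqrt(m^2 + lambda^2)``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if branch not in (+1, -1):
        raise ValueError("branch must be +1 or -1")
    return branch * float(np.hypot(lam, m))


def dirac_equation_eigenstates(sys: DiracSystem, m: float) -> list[DiracEigenstate]:
    """All N eigenstates of H = D + m*gamma, energy-ascending.

    Negative masses are allowed (equivalent to flipping the sign of gamma).
    At ``m = 0`` the states coincide with the eigenvectors of D itself.
    """
    m = float(m)
    U, s, Vt = sys.boundary_svd()
    r = sys.rank
    n0, n1 = sys.n_nodes, sys.n_edges
    states: list[DiracEigenstate] = []

    for i in range(r):
        lam = float(s[i])
        u = U[:, i]
        v = Vt[i, :]
        e_abs = float(np.hypot(lam, m))
        c = lam / (e_abs + m)  # positive for lam > 0, any real m
        plus = np.concatenate([u, c * v])
        minus = np.concatenate([c * u, -v])
        plus = _fix_sign(plus / np.linalg.norm(plus))
        minus = _fix_sign(minus / np.linalg.norm(minus))
        states.append(
            DiracEigenstate(+e_abs, lam, m, TopologicalSpinor(plus, sys.complex), "nonharmonic+")
        )
        states.append(
            DiracEigenstate(-e_abs, lam, m, TopologicalSpinor(minus, sys.complex), "nonharmonic-")
        )

    for j in range(r, n0):  # beta0 node-harmonic states at E = +m
        h = np.zeros(sys.n)
        h[:n0] = U[:, j]
        states.append(
            DiracEigenstate(+m, 0.0, m, TopologicalSpinor(_fix_sign(h), sys.complex), "harmonic-node")
        )
    for j in range(r, n1):  # beta1 cycle-harmonic states at E = -m
        h = np.zeros(sys.n)
        h[n0:] = Vt[j, :]
        states.append(
            DiracEigenstate(-m, 0.0, m, TopologicalSpinor(_fix_sign(h), sys.complex), "harmonic-cycle")
        )

    states.sort(key=lambda st: st.energy)
    return states


def dirac_spectrum(sys: DiracSystem) -> list[tuple[float, np.ndarray]]:
    """Full orthonormal eigenbasis of the (massless) Dirac operator D.

    Eigenvalues ascending; zero-eigenvalue vectors are returned in the basis
    where each is supported only on nodes or only on edges.
    """
    return [(st.energy, st.psi.values) for st in dirac_equation_eigenstates(sys, 0.0)]


def _eigenbasis_from_svd(sys: DiracSystem, m: float) -> tuple[np.ndarray, np.ndarray]:
    """(energies, Q) with Q orthonormal columns: H = Q diag(energies) Q^T."""
    states = dirac_equation_eigenstates(sys, m)
    w = np.array([st.energy for st in states])
    Q = np.column_stack([st.psi.values for st in states])
    return w, Q
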