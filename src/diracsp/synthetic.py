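"""Synthetic networks, signals and noise for end-to-end experiments.

Everything needed to exercise the denoisers without external data:

* the 1-skeleton of the two-dimensional Network Geometry with Flavor (NGF)
  growth model with flavor s = -1 and no fitness (beta = 0) — a growing
  simplicial complex that serves as the benchmark network;
* unit-norm true signals built from eigenstates (or mixtures of
  eigenstates) of the topological Dirac equation;
* the projected-Gaussian noise model: i.i.d. Gaussian components with the
  harmonic part filtered out and the result scaled by 1/sqrt(rank D), so
  noise lives entirely in the non-harmonic subspace, the harmonic content
  of the true signal is untouched, and the noise level alpha is the
  expected noise-to-signal ratio on a unit-norm true signal;
* the edge-flow-to-spinor construction used for drifter-style data, which
  manufactures a joint node+edge signal from an edge flow via
  ``psi = C (sigma + D sigma)`` with ``sigma = (0, theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .complexes import OrientedComplex, build_complex
from .operators import DiracSystem
from .spectrum import DiracEigenstate, dirac_equation_eigenstates
from .spinor import TopologicalSpinor

__all__ = [
    "NoiseSpec",
    "SignalSpec",
    "ngf_network",
    "add_noise",
    "sample_signal",
    "edge_flow_to_spinor",
    "random_connected_graph",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Projected-Gaussian noise parameters.

    ``alpha`` is the per-component standard deviation; ``alpha1``/``alpha2``
    optionally override it on the node/edge blocks (set both to use
    block-specific noise levels).
    """

    alpha: float | None = None
    alpha1: float | None = None
    alpha2: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.alpha is None and (self.alpha1 is None or self.alpha2 is None):
            raise ValueError("give alpha, or both alpha1 and alpha2")
        for a in (self.alpha, self.alpha1, self.alpha2):
            if a is not None and a < 0:
                raise ValueError("noise standard deviations must be nonnegative")

    def block_sigmas(self) -> tuple[float, float]:
        a1 = self.alpha1 if self.alpha1 is not None else self.alpha
        a2 = self.alpha2 if self.alpha2 is not None else self.alpha
        return float(a1), float(a2)


@dataclass(frozen=True)
class SignalSpec:
    """True-signal recipe: one eigenstate or a mixture of eigenstates.

    ``selector`` picks states from the energy-ascending eigenstate list:
    an int is an index, a float matches the nearest energy, the string
    ``"random-nonharmonic"`` draws uniformly among nonharmonic states.  For
    ``kind="mixture"`` give a sequence of selectors and ``weights`` of the
    same length.  The generated signal always has unit Euclidean norm.
    """

    kind: str = "eigenstate"
    mass: float = 0.0
    selector: object = "random-nonharmonic"
    weights: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("eigenstate", "mixture"):
            raise ValueError("kind must be 'eigenstate' or 'mixture'")
        if self.kind == "mixture" and self.weights is None:
            raise ValueError("mixture requires weights")


def ngf_network(
    n_nodes: int, seed: int | np.random.Generator | None = None
) -> OrientedComplex:
    """Grow the 1-skeleton of the 2d NGF model (flavor s=-1, beta=0).

    Start from a triangle; at each step pick an *unsaturated* edge uniformly
    at random, attach a new node to both its endpoints, and mark the chosen
    edge saturated (with flavor -1 each edge hosts at most one glued
    triangle beyond its first); the two new edges start unsaturated.  Node
    labels are 0..n_nodes-1 in order of arrival.  The edge count is
    deterministic: ``N1 = 2 * N0 - 3``.
    """
    if n_nodes < 3:
        raise ValueError("the NGF skeleton needs at least 3 nodes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edges: list[tuple[int, int]] = [(0, 1), (0, 2), (1, 2)]
    unsaturated = [0, 1, 2]
    for new in range(3, n_nodes):
        pick = int(rng.integers(len(unsaturated)))
        j = unsaturated.pop(pick)
        r, s = edges[j]
        edges.append((r, new))
        edges.append((s, new))
        unsaturated.extend([len(edges) - 2, len(edges) - 1])
    return build_complex(edges)


def add_noise(
    psi: TopologicalSpinor,
    spec: NoiseSpec,
    sys: DiracSystem,
    rng: np.random.Generator | None = None,
) -> TopologicalSpinor:
    """Corrupt a true signal with projected Gaussian noise.

    Draws i.i.d. zero-mean Gaussians (standard deviation ``alpha``, or
    ``alpha1`` on nodes / ``alpha2`` on edges), removes their harmonic
    component with the orthogonal projector onto the column space of D,
    scales by ``1/sqrt(rank D)`` so that ``E||eps||^2 = alpha^2`` under
    uniform noise, and adds the result to ``psi``.  Harmonic projections of
    the noisy and true signal coincide exactly.
    """
    if psi.complex != sys.complex:
        raise ValueError("signal and system live on different complexes")
    a1, a2 = spec.block_sigmas()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = np.concatenate(
        [
            a1 * rng.standard_normal(sys.n_nodes),
            a2 * rng.standard_normal(sys.n_edges),
        ]
    )
    rank_d = 2 * sys.rank
    if rank_d == 0:
        raise ValueError("the Dirac operator has rank 0: no non-harmonic subspace")
    eps = sys.nonharmonic_projector_apply(x) / np.sqrt(rank_d)
    return TopologicalSpinor(psi.values + eps, sys.complex)


def _resolve_selector(
    states: list[DiracEigenstate], selector, rng: np.random.Generator
) -> int:
    if isinstance(selector, (int, np.integer)) and not isinstance(selector, bool):
        if not 0 <= selector < len(states):
            raise ValueError(f"state index {selector} out of range 0..{len(states)-1}")
        return int(selector)
    if isinstance(selector, float):
        energies = np.array([st.energy for st in states])
        return int(np.argmin(np.abs(energies - selector)))
    if selector == "random-nonharmonic":
        idx = [i for i, st in enumerate(states) if st.kind.startswith("nonharmonic")]
        if not idx:
            raise ValueError("no nonharmonic states on this complex")
        return int(rng.choice(idx))
    raise ValueError(f"cannot resolve state selector {selector!r}")


def sample_signal(
    sys: DiracSystem,
    spec: SignalSpec,
    rng: np.random.Generator | None = None,
) -> tuple[TopologicalSpinor, dict]:
    """Generate a unit-norm true signal and its ground-truth metadata.

    Returns ``(psi, meta)`` where ``meta`` records the mass and, per
    selected state, the energy, singular value lambda and kind — the ground
    truth recovery tests compare against.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    states = dirac_equation_eigenstates(sys, spec.mass)
    if spec.kind == "eigenstate":
        i = _resolve_selector(states, spec.selector, rng)
        st = states[i]
        meta = {
            "mass": spec.mass,
            "energy": st.energy,
            "lambda": st.lam,
            "kind": st.kind,
            "index": i,
        }
        return st.psi.copy(), meta
    # mixture
    selectors = list(spec.selector)
    weights = np.asarray(spec.weights, dtype=float)
    if len(selectors) != weights.shape[0]:
        raise ValueError("selectors and weights must have the same length")
    idx = [_resolve_selector(states, s, rng) for s in selectors]
    if len(set(idx)) != len(idx):
        raise ValueError("mixture selectors resolve to duplicate states")
    total = np.zeros(sys.n)
    for i, w in zip(idx, weights):
        total += w * states[i].psi.values
    nrm = np.linalg.norm(total)
    if nrm == 0.0:
        raise ValueError("mixture weights produce a zero signal")
    total /= nrm
    meta = {
        "mass": spec.mass,
        "energies": [states[i].energy for i in idx],
        "lambdas": [states[i].lam for i in idx],
        "kinds": [states[i].kind for i in idx],
        "indices": idx,
        "weights": (weights / nrm).tolist(),
    }
    return TopologicalSpinor(total, sys.complex), meta


def edge_flow_to_spinor(theta: np.ndarray, sys: DiracSystem) -> TopologicalSpinor:
    """Build a unit-norm joint signal from a pure edge flow.

    With ``sigma = (0, theta)``, returns ``psi = C (sigma + D sigma)``: the
    node block is the (scaled) divergence ``C * B theta`` and the edge block
    ``C * theta``, with C enforcing unit norm.  Divergence-free flows give a
    zero node block.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != sys.n_edges:
        raise ValueError(f"edge flow length {theta.shape[0]} != N1 = {sys.n_edges}")
    vec = np.concatenate([sys.B @ theta, theta])
    nrm = np.linalg.norm(vec)
    if nrm == 0.0:
        raise ValueError("zero edge flow cannot be normalized")
    return TopologicalSpinor(vec / nrm, sys.complex)


def random_connected_graph(
    n_nodes: int, rng: np.random.Generator, extra_edge_prob: float = 0.15
) -> OrientedComplex:
    """A random connected graph for property tests: a uniform spanning tree
    plus Bernoulli extra edges (so beta1 varies)."""
    seed = int(rng.integers(2**31))
    g = nx.random_labeled_tree(n_nodes, seed=seed)
    edges = {tuple(sorted(e)) for e in g.edges}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if (i, j) not in edges and rng.random() < extra_edge_prob:
                edges.add((i, j))
    return build_complex(sorted(edges))
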