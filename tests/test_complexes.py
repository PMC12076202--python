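"""Oriented complex, boundary matrix and spinor block arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diracsp import (
    betti_numbers,
    build_complex,
    dirac_system,
    flip_orientation,
    make_spinor,
    random_connected_graph,
    split_spinor,
)
from diracsp.spinor import TopologicalSpinor


class TestBuildComplex:
    def test_reversed_input_pair_is_canonicalized(self):
        c = build_complex([[2, 1]])
        assert c.node_ids == (1, 2)
        assert c.edges == ((1, 2),)
        np.testing.assert_array_equal(c.boundary_dense().ravel(), [-1.0, 1.0])

    def test_triangle_counts(self, triangle):
        assert triangle.n_nodes == 3
        assert triangle.n_edges == 3
        B = triangle.boundary_dense()
        assert np.all((B == 1).sum(axis=0) == 1)
        assert np.all((B == -1).sum(axis=0) == 1)

    @pytest.mark.parametrize(
        "edges,match",
        [
            ([[1, 1]], "self-loop"),
            ([[1, 2], [2, 1]], "duplicate"),
            ([], "empty"),
        ],
    )
    def test_invalid_edge_lists_rejected(self, edges, match):
        with pytest.raises(ValueError, match=match):
            build_complex(edges)

    def test_isolated_nodes_allowed(self):
        c = build_complex([[1, 2]], node_ids=[1, 2, 7])
        assert c.n_nodes == 3
        assert betti_numbers(c) == (2, 0)


class TestBoundaryMatrix:
    def test_path_boundary_entries(self, path3):
        expected = np.array([[-1, 0], [1, -1], [0, 1]], dtype=float)
        np.testing.assert_array_equal(path3.boundary_dense(), expected)

    @given(seed=st.integers(0, 10_000), n=st.integers(2, 25))
    @settings(max_examples=30, deadline=None)
    def test_columns_sum_to_zero(self, seed, n):
        c = random_connected_graph(n, np.random.default_rng(seed))
        assert np.all(np.asarray(c.boundary.sum(axis=0)).ravel() == 0)


class TestDiracSystem:
    def test_single_edge_operator_and_spectrum(self, single_edge):
        sys = dirac_system(single_edge)
        D = sys.dirac_dense()
        np.testing.assert_array_equal(
            D, [[0, 0, -1], [0, 0, 1], [-1, 1, 0]]
        )
        w = np.linalg.eigvalsh(D)
        np.testing.assert_allclose(w, [-np.sqrt(2), 0, np.sqrt(2)], atol=1e-12)

    def test_triangle_laplacian_and_dirac_eigenvalues(self, triangle):
        sys = dirac_system(triangle)
        mu = np.sort(np.linalg.eigvalsh(sys.L0.toarray()))
        np.testing.assert_allclose(mu, [0, 3, 3], atol=1e-12)
        w = np.sort(np.linalg.eigvalsh(sys.dirac_dense()))
        np.testing.assert_allclose(
            w, [-np.sqrt(3), -np.sqrt(3), 0, 0, np.sqrt(3), np.sqrt(3)], atol=1e-12
        )

    def test_lambda_max_is_sqrt_of_l0_top_eigenvalue(self, ngf20_system):
        mu_max = np.linalg.eigvalsh(ngf20_system.L0.toarray())[-1]
        assert ngf20_system.lambda_max == pytest.approx(np.sqrt(mu_max), abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_dirac_squares_to_gauss_bonnet_laplacian(self, seed):
        rng = np.random.default_rng(seed)
        c = random_connected_graph(int(rng.integers(2, 30)), rng)
        sys = dirac_system(c)
        D2 = (sys.D @ sys.D).toarray()
        block = np.zeros_like(D2)
        n0 = sys.n_nodes
        block[:n0, :n0] = sys.L0.toarray()
        block[n0:, n0:] = sys.L1.toarray()
        assert np.max(np.abs(D2 - block)) < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_gamma_anticommutes_with_dirac(self, seed):
        rng = np.random.default_rng(seed)
        sys = dirac_system(random_connected_graph(int(rng.integers(2, 20)), rng))
        G = np.diag(sys.gamma_diag)
        D = sys.dirac_dense()
        assert np.max(np.abs(G @ G - np.eye(sys.n))) == 0
        assert np.max(np.abs(G @ D @ G + D)) < 1e-14


class TestBettiNumbers:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([[1, 2], [2, 3]], (1, 0)),
            ([[1, 2], [2, 3], [1, 3]], (1, 1)),
            ([[1, 2], [3, 4]], (2, 0)),
        ],
    )
    def test_known_graphs(self, edges, expected):
        assert betti_numbers(build_complex(edges)) == expected

    def test_zero_eigenvalue_multiplicity_is_betti_sum(self, rng):
        for _ in range(10):
            c = random_connected_graph(int(rng.integers(3, 25)), rng)
            sys = dirac_system(c)
            w = np.linalg.eigvalsh(sys.dirac_dense())
            n_zero = int(np.sum(np.abs(w) < 1e-9))
            assert n_zero == sum(betti_numbers(c))


class TestFlipOrientation:
    def test_single_edge_column_negated(self, single_edge):
        flipped = flip_orientation(single_edge, [(1, 2)])
        np.testing.assert_array_equal(flipped.boundary_dense().ravel(), [1.0, -1.0])

    def test_flip_is_involution(self, triangle):
        once = flip_orientation(triangle, [(1, 2), (2, 3)])
        twice = flip_orientation(once, [(1, 2), (2, 3)])
        assert twice == triangle

    def test_flip_all_negates_boundary(self, triangle):
        flipped = flip_orientation(triangle, triangle.edges)
        np.testing.assert_array_equal(
            flipped.boundary_dense(), -triangle.boundary_dense()
        )

    def test_unknown_edge_rejected(self, triangle):
        with pytest.raises(KeyError):
            flip_orientation(triangle, [(1, 9)])

    def test_l0_unchanged_l1_conjugated_spectrum_invariant(self, rng):
        c = random_connected_graph(12, rng)
        sys = dirac_system(c)
        subset = [e for i, e in enumerate(c.edges) if i % 3 == 0]
        flipped_sys = dirac_system(flip_orientation(c, subset))
        np.testing.assert_allclose(
            sys.L0.toarray(), flipped_sys.L0.toarray(), atol=1e-14
        )
        signs = np.array(
            [-1.0 if e in [tuple(s) for s in subset] else 1.0 for e in c.edges]
        )
        S = np.diag(signs)
        np.testing.assert_allclose(
            flipped_sys.L1.toarray(), S @ sys.L1.toarray() @ S, atol=1e-14
        )
        np.testing.assert_allclose(
            np.linalg.eigvalsh(sys.dirac_dense()),
            np.linalg.eigvalsh(flipped_sys.dirac_dense()),
            atol=1e-10,
        )


class TestSpinor:
    def test_make_and_split_round_trip(self, single_edge):
        psi = make_spinor([1.0, 2.0], [3.0], single_edge)
        np.testing.assert_array_equal(psi.values, [1, 2, 3])
        chi, phi = split_spinor(psi)
        np.testing.assert_array_equal(chi, [1, 2])
        np.testing.assert_array_equal(phi, [3])

    def test_zero_spinor_norm(self, single_edge):
        psi = make_spinor([0, 0], [0], single_edge)
        assert psi.norm() == 0.0

    @pytest.mark.parametrize("chi,phi", [([1.0], [1.0]), ([1.0, 2.0], [1.0, 2.0])])
    def test_block_length_mismatch_rejected(self, single_edge, chi, phi):
        with pytest.raises(ValueError):
            make_spinor(chi, phi, single_edge)

    def test_spinor_length_must_match_complex(self, single_edge):
        with pytest.raises(ValueError):
            TopologicalSpinor(np.zeros(5), single_edge)
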