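"""Subspaces, principal angles, the geodesic kernel, SDM and ROD."""

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.linalg import subspace_angles

from hetero_har.gfk import (
    Subspace,
    geodesic_kernel,
    kernel_dot,
    pca_basis,
    principal_angles,
    rod,
    select_dimension,
)


def _axis_subspace(D, cols):
    basis = np.eye(D)[:, cols]
    comp = np.eye(D)[:, [j for j in range(D) if j not in cols]]
    return Subspace(basis=basis, complement=comp)


def _random_subspace(D, d, rng):
    q, _ = np.linalg.qr(rng.normal(size=(D, D)))
    return Subspace(basis=q[:, :d], complement=q[:, d:])


def _quadrature_G(dec, PS, nodes=2001):
    """Composite-Simpson oracle for the flow integral, independent of the
    closed form."""
    ts = np.linspace(0.0, 1.0, nodes)
    A = PS.basis @ dec.U1
    B = PS.complement @ dec.U2
    vals = []
    for t in ts:
        phi = A @ np.diag(np.cos(t * dec.angles)) - B @ np.diag(
            np.sin(t * dec.angles)
        )
        vals.append(phi @ phi.T)
    return simpson(np.array(vals), x=ts, axis=0)


class TestPcaBasis:
    def test_exact_planar_data_is_captured(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(40, 2))
        plane = rng.normal(size=(2, 5))
        X = coords @ plane
        sub = pca_basis(X, 2)
        Xc = X - X.mean(axis=0)
        residual = Xc - (Xc @ sub.basis) @ sub.basis.T
        assert np.linalg.norm(residual) < 1e-10

    def test_orthonormality_invariants(self):
        rng = np.random.default_rng(1)
        sub = pca_basis(rng.normal(size=(30, 8)), 3)
        assert np.linalg.norm(sub.basis.T @ sub.basis - np.eye(3)) < 1e-10
        assert np.linalg.norm(sub.complement.T @ sub.basis) < 1e-10

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        sub = pca_basis(X, 3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        oracle = evecs[:, np.argsort(evals)[::-1][:3]]
        assert np.max(subspace_angles(sub.basis, oracle)) < 1e-8

    def test_dimension_out_of_range_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError):
            pca_basis(X, 5)
        with pytest.raises(ValueError):
            pca_basis(X, 0)


class TestPrincipalAngles:
    def test_identical_subspaces_give_zero_angles(self):
        rng = np.random.default_rng(3)
        P = _random_subspace(10, 3, rng)
        dec = principal_angles(P, P)
        assert np.allclose(dec.angles, 0.0, atol=1e-7)

    def test_orthogonal_axis_planes_give_right_angle(self):
        PS = _axis_subspace(4, [0])
        PT = _axis_subspace(4, [1])
        dec = principal_angles(PS, PT)
        assert np.isclose(dec.angles[0], np.pi / 2)

    def test_planar_rotation_recovers_the_angle(self):
        gamma = 0.3
        PS = _axis_subspace(4, [0])
        target = np.zeros((4, 1))
        target[0, 0], target[1, 0] = np.cos(gamma), np.sin(gamma)
        from scipy.linalg import null_space

        PT = Subspace(basis=target, complement=null_space(target.T))
        dec = principal_angles(PS, PT)
        assert np.isclose(dec.angles[0], gamma, atol=1e-10)

    def test_angles_nondecreasing_and_match_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            PS = _random_subspace(12, 4, rng)
            PT = _random_subspace(12, 4, rng)
            dec = principal_angles(PS, PT)
            assert np.all(np.diff(dec.angles) >= -1e-12)
            assert np.all((dec.angles >= 0) & (dec.angles <= np.pi / 2 + 1e-12))
            oracle = np.sort(subspace_angles(PS.basis, PT.basis))
            np.testing.assert_allclose(dec.angles, oracle, atol=1e-8)

    def test_sign_convention_reaches_target_at_t_one(self):
        # phi(1) must equal the target basis rotated by V.
        rng = np.random.default_rng(5)
        PS = _random_subspace(8, 2, rng)
        PT = _random_subspace(8, 2, rng)
        dec = principal_angles(PS, PT)
        phi1 = PS.basis @ dec.U1 @ dec.gamma - PS.complement @ dec.U2 @ dec.sigma
        assert np.allclose(phi1, PT.basis @ dec.V, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            principal_angles(_random_subspace(8, 2, rng), _random_subspace(8, 3, rng))


class TestGeodesicKernel:
    def test_zero_angles_give_projection_onto_shared_subspace(self):
        rng = np.random.default_rng(7)
        P = _random_subspace(9, 3, rng)
        kern = geodesic_kernel(principal_angles(P, P), P)
        assert np.allclose(kern.G, P.basis @ P.basis.T, atol=1e-7)

    def test_closed_form_matches_simpson_quadrature(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            D = int(rng.integers(6, 21))
            d = int(rng.integers(1, D // 2 + 1))
            PS = _random_subspace(D, d, rng)
            PT = _random_subspace(D, d, rng)
            dec = principal_angles(PS, PT)
            kern = geodesic_kernel(dec, PS)
            assert np.max(np.abs(kern.G - _quadrature_G(dec, PS))) < 1e-8

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(9)
        PS = _random_subspace(10, 3, rng)
        PT = _random_subspace(10, 3, rng)
        kern = geodesic_kernel(principal_angles(PS, PT), PS)
        assert np.linalg.norm(kern.G - kern.G.T) < 1e-10
        assert np.linalg.eigvalsh(kern.G).min() > -1e-8


class TestKernelDot:
    def test_identity_kernel_is_gram_matrix(self):
        rng = np.random.default_rng(10)
        X, Y = rng.normal(size=(5, 4)), rng.normal(size=(7, 4))
        assert np.allclose(kernel_dot(np.eye(4), X, Y), X @ Y.T)

    def test_self_kernel_is_symmetric_psd(self):
        rng = np.random.default_rng(11)
        PS = _random_subspace(6, 2, rng)
        PT = _random_subspace(6, 2, rng)
        kern = geodesic_kernel(principal_angles(PS, PT), PS)
        X = rng.normal(size=(8, 6))
        K = kernel_dot(kern, X, X)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_matches_entrywise_loop(self):
        rng = np.random.default_rng(12)
        G = rng.normal(size=(4, 4))
        X, Y = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        K = kernel_dot(G, X, Y)
        for i in range(3):
            for j in range(2):
                assert np.isclose(K[i, j], X[i] @ G @ Y[j])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_dot(np.eye(3), np.zeros((2, 4)), np.zeros((2, 3)))


class TestSelectDimension:
    def test_identical_domains_have_zero_disagreement(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 12))
        profile = select_dimension(X, X.copy(), d_max=5)
        assert np.allclose(profile.disagreement, 0.0, atol=1e-6)
        assert profile.d_star == 5

    def test_disagreement_is_bounded(self):
        rng = np.random.default_rng(14)
        profile = select_dimension(
            rng.normal(size=(60, 15)), rng.normal(size=(60, 15)), d_max=7
        )
        assert np.all((profile.disagreement >= 0) & (profile.disagreement <= 1))

    def test_matches_compositional_oracle(self):
        # Assemble the profile independently from pca_basis + scipy angles.
        rng = np.random.default_rng(15)
        XS = rng.normal(size=(200, 20))
        XT = rng.normal(size=(200, 20)) + 0.5
        profile = select_dimension(XS, XT, d_max=5)
        for d in range(1, 6):
            BS = pca_basis(XS, d).basis
            BT = pca_basis(XT, d).basis
            BC = pca_basis(np.vstack([XS, XT]), d).basis
            alpha = np.max(subspace_angles(BS, BC))
            beta = np.max(subspace_angles(BT, BC))
            want = 0.5 * (np.sin(alpha) + np.sin(beta))
            assert np.isclose(profile.disagreement[d - 1], want, atol=1e-8)

    def test_invalid_d_max_rejected(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(10, 20))
        with pytest.raises(ValueError):
            select_dimension(X, X, d_max=0)
        with pytest.raises(ValueError):
            select_dimension(X, X, d_max=6)  # exceeds floor((n-1)/2)


class TestRod:
    def test_identical_domains_have_zero_rod(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(80, 10))
        assert rod(X, X.copy(), 3).value < 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(18)
        XS = rng.normal(size=(60, 8))
        XT = rng.normal(size=(60, 8)) @ np.diag(rng.uniform(0.5, 2.0, 8))
        assert abs(rod(XS, XT, 3).value - rod(XT, XS, 3).value) < 1e-10

    def test_increases_with_mean_shift(self):
        # Targets at growing mean shift (after a shared random rotation so
        # the shift moves the subspaces); the median ROD must be ordered.
        shifts = [0.5, 1.0, 2.0]
        medians = []
        rods = {s: [] for s in shifts}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            D = 10
            q, _ = np.linalg.qr(rng.normal(size=(D, D)))
            base = rng.normal(size=(300, D)) * np.linspace(2.0, 0.5, D)
            XS = base @ q.T
            for s in shifts:
                shift = np.zeros(D)
                shift[0] = s * 2.0  # in units of the largest axis SD
                XT = (rng.normal(size=(300, D)) * np.linspace(2.0, 0.5, D) + shift) @ q.T
                rods[s].append(rod(XS, XT, 3).value)
        medians = [np.median(rods[s]) for s in shifts]
        assert medians[0] < medians[1] < medians[2]

    def test_degenerate_variance_is_floored(self):
        X = np.zeros((20, 6))
        X[:, 0] = np.arange(20)
        out = rod(X, X + 1e-15, 1)
        assert np.isfinite(out.value)
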