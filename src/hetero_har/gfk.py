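"""Geodesic flow kernel on the Grassmann manifold.

Source and target feature clouds are summarized by d-dimensional PCA
subspaces of R^D.  The geodesic between them on the Grassmannian,
phi(t) = P_S U1 Gamma(t) - R_S U2 Sigma(t), interpolates the two subspaces;
projecting features onto *every* intermediate subspace and taking inner
products yields the closed-form kernel

    G = integral_0^1 phi(t) phi(t)^T dt = Omega Lambda Omega^T,

with Omega = [P_S U1, R_S U2] and Lambda built from the principal angles
theta_i between the subspaces:

    a_i = 1/2 + sin(2 theta_i) / (4 theta_i)
    b_i = (cos(2 theta_i) - 1) / (4 theta_i)
    c_i = 1/2 - sin(2 theta_i) / (4 theta_i)

(with a_i -> 1, b_i, c_i -> 0 as theta_i -> 0).  The subspace dimension d is
chosen with the subspace disagreement measure
D(d) = 0.5 [sin alpha_d + sin beta_d], and candidate source domains are
ranked with the rank-of-domain (ROD) metric: principal angles weighted by
the symmetrized KL divergence of the per-direction projected marginals
under a Gaussian approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TINY_ANGLE = 1e-12


@dataclass
class Subspace:
    """Orthonormal basis P (D x d) and its orthogonal complement R (D x (D-d))."""

    basis: np.ndarray
    complement: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.basis, dtype=float)
        R = np.asarray(self.complement, dtype=float)
        self.basis, self.complement = P, R
        d = P.shape[1]
        if np.linalg.norm(P.T @ P - np.eye(d)) >= 1e-8:
            raise ValueError("basis columns are not orthonormal")
        if R.size and np.linalg.norm(R.T @ P) >= 1e-8:
            raise ValueError("complement is not orthogonal to the basis")

    @property
    def D(self) -> int:
        return self.basis.shape[0]

    @property
    def d(self) -> int:
        return self.basis.shape[1]


@dataclass
class PrincipalAngleDecomposition:
    """SVD factors and principal angles between two d-dim subspaces of R^D.

    ``U1`` (d x d), ``U2`` ((D-d) x d) and ``V`` (d x d) satisfy
    P_S^T P_T = U1 Gamma V^T and R_S^T P_T = -U2 Sigma V^T with
    Gamma = diag(cos theta), Sigma = diag(sin theta) and nondecreasing
    angles in [0, pi/2].
    """

    U1: np.ndarray
    U2: np.ndarray
    V: np.ndarray
    angles: np.ndarray

    @property
    def gamma(self) -> np.ndarray:
        return np.diag(np.cos(self.angles))

    @property
    def sigma(self) -> np.ndarray:
        return np.diag(np.sin(self.angles))


@dataclass
class GeodesicKernel:
    """D x D symmetric PSD kernel matrix with its generating decomposition."""

    G: np.ndarray
    decomposition: PrincipalAngleDecomposition


@dataclass
class SDMProfile:
    """Subspace disagreement D(d) for d = 1..d_max and the selected d*."""

    d_values: np.ndarray
    disagreement: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    d_star: int


@dataclass
class RODScore:
    """Rank-of-domain value for an ordered pair; lower adapts better."""

    value: float
    d: int


def _fix_signs(Vt: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| entry of each row positive."""
    idx = np.argmax(np.abs(Vt), axis=1)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), idx])
    signs[signs == 0] = 1.0
    return Vt * signs[:, None]


def pca_basis(X: np.ndarray, d: int) -> Subspace:
    """Top-d principal directions of the column-centered X, plus complement."""
    X = np.asarray(X, dtype=float)
    n, D = X.shape
    if not 1 <= d <= min(n - 1, D):
        raise ValueError(f"d={d} out of range for ({n}, {D}) data")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=True)
    Vt = _fix_signs(Vt)
    return Subspace(basis=Vt[:d].T, complement=Vt[d:].T)


def principal_angles(PS: Subspace, PT: Subspace) -> PrincipalAngleDecomposition:
    """Principal-angle SVDs between equal-dimension subspaces.

    Requires d <= D - d so that U2 can carry d columns.  Singular values are
    clipped to [0, 1] before arccos; degenerate (zero-sine) directions of U2
    are completed to an orthonormal set deterministically.
    """
    if PS.D != PT.D:
        raise ValueError("subspaces live in different ambient dimensions")
    if PS.d != PT.d:
        raise ValueError("subspaces have different dimensions")
    d, D = PS.d, PS.D
    if d > D - d:
        raise ValueError("need d <= D - d for the complement factor")
    U1, s, Vt = np.linalg.svd(PS.basis.T @ PT.basis)
    s = np.clip(s, 0.0, 1.0)
    angles = np.arccos(s)  # ascending (singular values descend)
    V = Vt.T
    sines = np.sin(angles)
    M2 = PS.complement.T @ (PT.basis @ V)  # = -U2 Sigma
    U2 = np.zeros((D - d, d))
    good = sines > 1e-7
    U2[:, good] = -M2[:, good] / sines[good]
    if not good.all():
        # Complete degenerate columns (theta ~ 0 contributes nothing to the
        # flow) with a deterministic orthonormal fill.
        basis = U2[:, good]
        for j in np.where(~good)[0]:
            for k in range(D - d):
                cand = np.zeros(D - d)
                cand[k] = 1.0
                if basis.size:
                    cand = cand - basis @ (basis.T @ cand)
                norm = np.linalg.norm(cand)
                if norm > 1e-6:
                    U2[:, j] = cand / norm
                    basis = np.column_stack([basis, U2[:, j]])
                    break
    return PrincipalAngleDecomposition(U1=U1, U2=U2, V=V, angles=angles)


def _lambda_entries(angles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.asarray(angles, dtype=float)
    a = np.ones_like(theta)
    b = np.zeros_like(theta)
    c = np.zeros_like(theta)
    big = theta > _TINY_ANGLE
    th = theta[big]
    a[big] = 0.5 + np.sin(2 * th) / (4 * th)
    b[big] = (np.cos(2 * th) - 1) / (4 * th)
    c[big] = 0.5 - np.sin(2 * th) / (4 * th)
    return a, b, c


def geodesic_kernel(
    dec: PrincipalAngleDecomposition, PS: Subspace
) -> GeodesicKernel:
    """Closed-form G = Omega Lambda Omega^T of the geodesic flow kernel."""
    a, b, c = _lambda_entries(dec.angles)
    d = dec.angles.size
    omega = np.hstack([PS.basis @ dec.U1, PS.complement @ dec.U2])
    lam = np.zeros((2 * d, 2 * d))
    lam[:d, :d] = np.diag(a)
    lam[:d, d:] = np.diag(b)
    lam[d:, :d] = np.diag(b)
    lam[d:, d:] = np.diag(c)
    G = omega @ lam @ omega.T
    G = 0.5 * (G + G.T)
    return GeodesicKernel(G=G, decomposition=dec)


def kernel_dot(G: GeodesicKernel | np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Kernel matrix with entries x_i^T G y_j."""
    mat = G.G if isinstance(G, GeodesicKernel) else np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != mat.shape[0] or Y.shape[1] != mat.shape[1]:
        raise ValueError("feature dimension does not match the kernel")
    return X @ mat @ Y.T


def _largest_angle(P1: np.ndarray, P2: np.ndarray) -> float:
    s = np.linalg.svd(P1.T @ P2, compute_uv=False)
    return float(np.arccos(np.clip(s.min(), 0.0, 1.0)))


def select_dimension(
    XS: np.ndarray, XT: np.ndarray, d_max: int
) -> SDMProfile:
    """Subspace disagreement profile and greedy dimension selection.

    For each d, alpha_d / beta_d are the largest principal angles between
    the source / target PCA subspace and the PCA subspace of the pooled
    data.  d* is the smallest d with D(d) >= 1 - 1e-6, else d_max.
    """
    XS = np.asarray(XS, dtype=float)
    XT = np.asarray(XT, dtype=float)
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    nS, D = XS.shape
    nT = XT.shape[0]
    cap = min(D, nS - 1, nT - 1) // 2
    if d_max > cap:
        raise ValueError(f"d_max={d_max} exceeds floor(min(D, nS-1, nT-1)/2)={cap}")
    BS = pca_basis(XS, d_max).basis
    BT = pca_basis(XT, d_max).basis
    BC = pca_basis(np.vstack([XS, XT]), d_max).basis
    ds = np.arange(1, d_max + 1)
    alpha = np.array([_largest_angle(BS[:, :d], BC[:, :d]) for d in ds])
    beta = np.array([_largest_angle(BT[:, :d], BC[:, :d]) for d in ds])
    disagreement = 0.5 * (np.sin(alpha) + np.sin(beta))
    hit = np.where(disagreement >= 1 - 1e-6)[0]
    d_star = int(ds[hit[0]]) if hit.size else int(d_max)
    return SDMProfile(
        d_values=ds, disagreement=disagreement, alpha=alpha, beta=beta, d_star=d_star
    )


def _sym_kl_gauss(mu0: float, var0: float, mu1: float, var1: float) -> float:
    delta2 = (mu0 - mu1) ** 2
    return float(
        (var0 + delta2) / (2 * var1) + (var1 + delta2) / (2 * var0) - 1.0
    )


def rod(XS: np.ndarray, XT: np.ndarray, d: int) -> RODScore:
    """Rank of domain: angle-weighted symmetrized KL of projected marginals.

    R(S,T) = (1/d) sum_i theta_i [KL(S_i || T_i) + KL(T_i || S_i)] where
    S_i / T_i are Gaussians fitted to the source / target data projected on
    the i-th aligned principal directions (P_S U1 e_i and P_T V e_i).
    Variances are floored at 1e-12.
    """
    XS = np.asarray(XS, dtype=float)
    XT = np.asarray(XT, dtype=float)
    BS = pca_basis(XS, d).basis
    BT = pca_basis(XT, d).basis
    U1, s, Vt = np.linalg.svd(BS.T @ BT)
    angles = np.arccos(np.clip(s, 0.0, 1.0))
    proj_s = XS @ (BS @ U1)
    proj_t = XT @ (BT @ Vt.T)
    total = 0.0
    for i in range(d):
        mu_s, var_s = float(proj_s[:, i].mean()), max(float(proj_s[:, i].var()), 1e-12)
        mu_t, var_t = float(proj_t[:, i].mean()), max(float(proj_t[:, i].var()), 1e-12)
        total += angles[i] * _sym_kl_gauss(mu_s, var_s, mu_t, var_t)
    return RODScore(value=total / d, d=d)
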