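"""jPCA: skew-symmetric linear dynamics fit to peri-acoustic-onset activity.

Trial-averaged, soft-normalized (10 Hz offset), condition-centered firing
rates over a short epoch around acoustic onset are reduced to k = 6
dimensions by PCA (conditions stacked), sampled every 10 ms.  The rotatory
dynamics model

    x' = M_skew x,     M_skew = -M_skew^T

is fit by least squares over the k(k-1)/2-dimensional antisymmetric basis in
closed form (an unconstrained fit M_full is kept as the nested reference;
R^2(M_full) >= R^2(M_skew) always).  Derivatives are forward differences
paired with the left sample; per-condition boundary samples are dropped.

Because M_skew is normal with purely imaginary eigenvalues, its eigenvectors
come in conjugate pairs defining mutually orthogonal 2-D planes; planes are
ordered by |eigenvalue|, the rotation frequency of a plane is
|imag eigenvalue| / 2 pi, and a fresh 2x2 skew fit within the first plane
gives the in-plane goodness of fit.  The basis within the top plane is
rotated so the conditions are maximally spread along jPC1 at the epoch
start, with the majority of conditions starting positive on jPC1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RateTensor, center_across_conditions

__all__ = [
    "StateTrajectories",
    "JPCAResult",
    "prepare_states",
    "fit_skew_dynamics",
    "skew_from_params",
    "orient_plane",
    "orthogonalized_jpca",
]


@dataclass
class StateTrajectories:
    X: list[np.ndarray]               # per condition, (T, k) PCA scores
    dX: list[np.ndarray]              # per condition, (T-1, k)
    dt: float
    pca_basis: np.ndarray             # (U, k)
    variance_captured: float
    conditions: tuple[str, ...] = ()

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.vstack([xc[:-1] for xc in self.X])
        dx = np.vstack(self.dX)
        return x, dx


@dataclass
class JPCAResult:
    M_skew: np.ndarray                # (k, k), M = -M^T
    M_full: np.ndarray                # unconstrained reference fit
    planes: list[np.ndarray]          # 2-column orthonormal bases, ordered
    frequencies: np.ndarray           # Hz per plane
    R2_full: float                    # k x k skew fit
    R2_unconstrained: float
    R2_plane: float                   # 2 x 2 skew fit within plane 1
    projections: list[np.ndarray]     # per condition, (T, 2) in oriented plane 1
    pca_basis: np.ndarray
    meta: dict = field(default_factory=dict)

    def plane_in_unit_space(self, plane: int = 0) -> np.ndarray:
        return self.pca_basis @ self.planes[plane]


def prepare_states(tensor: RateTensor, k: int = 6, dt: float = 0.010,
                   ) -> StateTrajectories:
    """PCA-reduce a centered rate tensor to per-condition state trajectories."""
    if not tensor.centered:
        raise ValueError("tensor must be condition-centered before jPCA")
    if tensor.normalization is None:
        warnings.warn("tensor is not soft-normalized", RuntimeWarning)
    stride = dt / tensor.bin
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError("dt must be an integer multiple of the tensor bin")
    stride = int(round(stride))
    rates = tensor.rates[:, :, ::stride]          # (U, C, T)
    n_u, n_c, n_t = rates.shape
    if n_t < 2:
        raise ValueError("need >= 2 samples per condition")
    k = min(k, n_u, n_c * n_t)
    stacked = rates.transpose(1, 2, 0).reshape(-1, n_u)   # (C*T, U)
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    basis = vt[:k].T                               # (U, k)
    var_cap = float(np.sum(s[:k] ** 2) / np.sum(s ** 2)) if s.size else 0.0
    xs, dxs = [], []
    for c in range(n_c):
        scores = rates[:, c, :].T @ basis          # (T, k)
        xs.append(scores)
        dxs.append(np.diff(scores, axis=0) / dt)
    return StateTrajectories(X=xs, dX=dxs, dt=dt, pca_basis=basis,
                             variance_captured=var_cap,
                             conditions=tensor.conditions)


def skew_from_params(theta: np.ndarray, k: int) -> np.ndarray:
    """Map k(k-1)/2 parameters to a skew-symmetric matrix (upper triangle)."""
    m = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    m[iu] = theta
    return m - m.T


def _fit_skew(x: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Closed-form least squares of dx ~ x M^T over skew-symmetric M."""
    k = x.shape[1]
    iu = np.triu_indices(k, 1)
    n_par = len(iu[0])
    # columns of the design are vec(x @ B_a^T) for each antisymmetric basis B_a
    design = np.empty((x.shape[0] * k, n_par))
    for a, (i, j) in enumerate(zip(*iu)):
        # basis B = e_i e_j^T - e_j e_i^T, so X B^T sends col j of X to
        # col i and -col i of X to col j
        contrib = np.zeros((x.shape[0], k))
        contrib[:, i] = x[:, j]
        contrib[:, j] = -x[:, i]
        design[:, a] = contrib.ravel()
    theta, *_ = np.linalg.lstsq(design, dx.ravel(), rcond=None)
    return skew_from_params(theta, k)


def _r2(x: np.ndarray, dx: np.ndarray, m: np.ndarray) -> float:
    resid = dx - x @ m.T
    sst = float(np.sum((dx - dx.mean(axis=0)) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / sst


def fit_skew_dynamics(traj: StateTrajectories) -> JPCAResult:
    """Fit skew-symmetric (and unconstrained) linear dynamics; extract planes."""
    x, dx = traj.stacked()
    k = x.shape[1]
    gram = x.T @ x
    if np.linalg.matrix_rank(gram) < k:
        warnings.warn("singular normal equations; adding 1e-10 ridge",
                      RuntimeWarning)
        gram = gram + 1e-10 * np.eye(k)
    m_skew = _fit_skew(x, dx)
    m_full = np.linalg.solve(gram, x.T @ dx).T
    r2_skew = _r2(x, dx, m_skew)
    r2_full = _r2(x, dx, m_full)

    eigval, eigvec = np.linalg.eig(m_skew)
    order = np.argsort(-np.abs(eigval.imag))
    planes, freqs = [], []
    used = np.zeros(k, dtype=bool)
    for idx in order:
        if used[idx] or abs(eigval[idx].imag) < 1e-12:
            continue
        v = eigvec[:, idx]
        q, _ = np.linalg.qr(np.column_stack([v.real, v.imag]))
        planes.append(q)
        freqs.append(abs(eigval[idx].imag) / (2 * np.pi))
        # mark this eigenvalue and its conjugate partner
        used[idx] = True
        partner = np.argmin(np.abs(eigval - np.conj(eigval[idx]))
                            + 1e18 * used)
        used[partner] = True

    if planes:
        p1 = planes[0]
        xp = x @ p1
        dxp = dx @ p1
        r2_plane = _r2(xp, dxp, _fit_skew(xp, dxp))
    else:
        r2_plane = 0.0

    result = JPCAResult(
        M_skew=m_skew, M_full=m_full, planes=planes,
        frequencies=np.asarray(freqs), R2_full=r2_skew,
        R2_unconstrained=r2_full, R2_plane=r2_plane,
        projections=[], pca_basis=traj.pca_basis,
    )
    if planes:
        orient_plane(result, traj)
    return result


def orient_plane(result: JPCAResult, traj: StateTrajectories) -> np.ndarray:
    """Rotate plane 1 so conditions are maximally spread along jPC1 at epoch
    start, with most conditions starting positive; fills
    ``result.projections`` and returns the oriented (k, 2) plane basis."""
    if not result.planes:
        raise ValueError("no rotation plane found")
    p1 = result.planes[0]
    starts = np.stack([xc[0] @ p1 for xc in traj.X])       # (C, 2)
    centered = starts - starts.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0):
        warnings.warn("conditions coincide at epoch start; plane orientation "
                      "is arbitrary", RuntimeWarning)
        rot = np.eye(2)
    else:
        w, v = np.linalg.eigh(cov)
        jpc1 = v[:, np.argmax(w)]
        if np.mean(starts @ jpc1 >= 0) < 0.5:              # sign convention
            jpc1 = -jpc1
        jpc2 = np.array([-jpc1[1], jpc1[0]])
        # keep the in-plane rotation sense of the data counterclockwise
        x, dx = traj.stacked()
        if float(np.mean((x @ p1 @ jpc1) * (dx @ p1 @ jpc2)
                         - (x @ p1 @ jpc2) * (dx @ p1 @ jpc1))) < 0:
            jpc2 = -jpc2
        rot = np.column_stack([jpc1, jpc2])
    oriented = p1 @ rot
    result.planes[0] = oriented
    result.projections = [xc @ oriented for xc in traj.X]
    return oriented


def orthogonalized_jpca(tensor: RateTensor, cis_axis: np.ndarray,
                        k: int = 6, dt: float = 0.010) -> JPCAResult:
    """jPCA on the orthogonal complement of the CIS_1 axis.

    Firing rates are projected into the (units - 1)-dimensional null space of
    the condition-invariant axis before state preparation, so the resulting
    jPC plane is exactly orthogonal to CIS_1; used for joint
    [CIS_1, jPC1, jPC2] state-space visualization.  The returned
    ``pca_basis`` is expressed back in unit space.
    """
    axis = np.asarray(cis_axis, dtype=float).ravel()
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("zero CIS axis")
    if abs(nrm - 1.0) > 1e-8:
        warnings.warn("CIS axis not unit norm; normalizing", RuntimeWarning)
        axis = axis / nrm
    n_u = tensor.rates.shape[0]
    if axis.size != n_u:
        raise ValueError("axis dimension mismatch")
    # orthonormal basis of the complement via full QR
    q, _ = np.linalg.qr(np.column_stack([axis, np.eye(n_u)]))
    null_basis = q[:, 1:n_u]                       # (U, U-1)
    projected = np.einsum("un,uct->nct", null_basis, tensor.rates)
    if float(np.sum(projected ** 2)) < 1e-12 * max(float(np.sum(tensor.rates ** 2)), 1e-30):
        raise ValueError("activity is confined to the CIS axis; nothing to fit")
    proj_tensor = RateTensor(
        rates=projected, time=tensor.time.copy(), conditions=tensor.conditions,
        alignment=tensor.alignment, bin=tensor.bin, kernel_sd=tensor.kernel_sd,
        normalization=dict(tensor.normalization) if tensor.normalization else
        {"offset": 0.0, "ranges": np.ones(n_u - 1)},
        centered=tensor.centered, condition_mean=None,
    )
    if not proj_tensor.centered:
        proj_tensor = center_across_conditions(proj_tensor)
    traj = prepare_states(proj_tensor, k=k, dt=dt)
    result = fit_skew_dynamics(traj)
    result.pca_basis = null_basis @ traj.pca_basis     # back to unit space
    result.meta["cis_axis"] = axis
    return result
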