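"""Demixed PCA of trial-averaged activity: condition-invariant vs
condition-dependent components.

The centered data tensor X (units x conditions x time, soft-normalized and
restricted to a movement-initiation epoch) is split into two marginalizations
that reconstruct it exactly:

    X_CI[u,c,t] = mean over conditions of X[u,.,t]     (time-only structure)
    X_CD        = X - X_CI                             (condition and
                                                        condition x time)

For each marginalization the method solves a reduced-rank ridge regression,
min ||X_m - F_m D_m X||^2 + mu ||F_m D_m||^2 over rank-q maps: with
A = X_m X^T (X X^T + mu I)^-1, the optimum is F_m = U_q (top left singular
vectors of A X) and D_m = U_q^T A.  Components from both marginalizations
compete for a fixed total budget (default 8) ranked by explained variance.
Encoder axes within one marginalization are orthonormal; CI and CD axes are
not constrained to be orthogonal, so their pairwise angles and a Kendall
rank-correlation test on electrode weightings are reported separately.

A component's condition-invariance is quantified by projecting each
marginalization onto its decoder axis: because the CI/CD cross term vanishes
exactly, ||d X||^2 = ||d X_CI||^2 + ||d X_CD||^2, and the CI fraction is the
first share of that split.  The leading CI component's condition x time
projection is the condition-invariant signal (CIS_1) time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import RateTensor

__all__ = [
    "DPCAConfig",
    "DPCAResult",
    "marginalize",
    "fit_dpca",
    "optimize_regularization",
    "axis_orthogonality",
    "encoder_orthogonality",
    "subspace_angle",
]


@dataclass
class DPCAConfig:
    n_components: int = 8
    reg: float = 1e-6            # ridge scale, times total variance
    epoch: tuple[float, float] = (-0.2, 0.4)   # relative to the go cue
    kernel_sd: float = 0.028
    soft_offset: float = 5.0


@dataclass
class DPCAResult:
    decoder: np.ndarray               # (n_comp, U)
    encoder: np.ndarray               # (U, n_comp), unit columns
    marginalization: list[str]        # "CI" or "CD" per component
    share: np.ndarray                 # total-variance share per component
    ci_share: np.ndarray              # CI part of each component's share
    cd_share: np.ndarray
    cis_timecourses: np.ndarray       # (C, T) projection on leading CI comp
    conditions: tuple[str, ...]
    time: np.ndarray
    reg: float
    meta: dict = field(default_factory=dict)

    @property
    def ci_fraction(self) -> np.ndarray:
        """Per-component CI variance over (CI + CD) variance along its axis."""
        tot = self.ci_share + self.cd_share
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.ci_share / tot, 0.0)

    def leading_ci_component(self) -> int:
        idx = [i for i, m in enumerate(self.marginalization) if m == "CI"]
        if not idx:
            raise ValueError("no CI component found")
        return idx[int(np.argmax(self.share[idx]))]


def marginalize(tensor: RateTensor | np.ndarray) -> dict[str, np.ndarray]:
    """Split centered data into exact CI + CD parts.

    Returns ``{"X": centered, "CI": ..., "CD": ...}``, each units x
    conditions x time; CI + CD reconstructs the centered data exactly.
    """
    rates = tensor.rates if isinstance(tensor, RateTensor) else np.asarray(tensor)
    if rates.ndim != 3:
        raise ValueError("expected units x conditions x time")
    if rates.shape[1] == 1:
        warnings.warn("single condition: CD marginalization is identically 0",
                      RuntimeWarning)
    x = rates - rates.mean(axis=(1, 2), keepdims=True)     # per-unit grand mean
    x_ci = np.broadcast_to(x.mean(axis=1, keepdims=True), x.shape).copy()
    return {"X": x, "CI": x_ci, "CD": x - x_ci}


def _reduced_rank_components(x_m: np.ndarray, x: np.ndarray, mu: float,
                             q: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-q encoder/decoder of the reduced-rank ridge regression."""
    n = x.shape[0]
    gram = x @ x.T
    # pinv tolerates rank-deficient data when the ridge is zero
    a = x_m @ x.T @ np.linalg.pinv(gram + mu * np.eye(n),
                                   rcond=1e-12, hermitian=True)
    m = a @ x
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    rank = int(np.sum(s > max(s[0], 1e-300) * 1e-10)) if s.size else 0
    if rank < q:
        warnings.warn(f"marginalization rank {rank} < requested {q} "
                      "components; reducing", RuntimeWarning)
        q = max(rank, 0)
    f = u[:, :q]
    d = f.T @ a
    return f, d


def fit_dpca(tensor: RateTensor | np.ndarray,
             config: DPCAConfig | None = None,
             conditions: tuple[str, ...] | None = None,
             time: np.ndarray | None = None) -> DPCAResult:
    """Fit demixed PCA and allocate components across marginalizations.

    Up to ``n_components`` are extracted per marginalization; the pooled set
    is ranked by explained total variance and the top ``n_components``
    overall are kept, each tagged CI or CD.
    """
    config = config or DPCAConfig()
    if isinstance(tensor, RateTensor):
        conditions = tensor.conditions
        time = tensor.time
        if tensor.normalization is None:
            warnings.warn("tensor is not soft-normalized; high-rate units "
                          "will dominate", RuntimeWarning)
    parts = marginalize(tensor)
    n_u, n_c, n_t = parts["X"].shape
    x = parts["X"].reshape(n_u, -1)
    ss_total = float(np.sum(x * x))
    if ss_total == 0:
        raise ValueError("data tensor has zero variance")
    mu = config.reg * ss_total
    flat = {m: parts[m].reshape(n_u, -1) for m in ("CI", "CD")}

    comps = []    # (share, marg, f, d, ci_part, cd_part)
    for marg in ("CI", "CD"):
        q = min(config.n_components, n_u, flat[marg].shape[1])
        f, d = _reduced_rank_components(flat[marg], x, mu, q)
        for i in range(f.shape[1]):
            di = d[i]
            ci_part = float(np.sum((di @ flat["CI"]) ** 2)) / ss_total
            cd_part = float(np.sum((di @ flat["CD"]) ** 2)) / ss_total
            comps.append((ci_part + cd_part, marg, f[:, i], di,
                          ci_part, cd_part))
    comps.sort(key=lambda c: -c[0])
    comps = comps[:config.n_components]

    share = np.array([c[0] for c in comps])
    margs = [c[1] for c in comps]
    encoder = np.stack([c[2] for c in comps], axis=1)
    decoder = np.stack([c[3] for c in comps], axis=0)
    ci_share = np.array([c[4] for c in comps])
    cd_share = np.array([c[5] for c in comps])

    ci_idx = [i for i, m in enumerate(margs) if m == "CI"]
    if ci_idx:
        lead = ci_idx[int(np.argmax(share[ci_idx]))]
        cis = (decoder[lead] @ x).reshape(n_c, n_t)
    else:
        cis = np.zeros((n_c, n_t))
    return DPCAResult(
        decoder=decoder, encoder=encoder, marginalization=margs,
        share=share, ci_share=ci_share, cd_share=cd_share,
        cis_timecourses=cis,
        conditions=tuple(conditions) if conditions is not None
        else tuple(f"c{i}" for i in range(n_c)),
        time=time if time is not None else np.arange(n_t, dtype=float),
        reg=config.reg, meta={"ss_total": ss_total},
    )


def optimize_regularization(trial_tensors: list[list[np.ndarray]],
                            n_components: int = 8,
                            grid: np.ndarray | None = None,
                            n_reps: int = 10, seed: int = 0,
                            ) -> tuple[float, np.ndarray]:
    """Choose the ridge scale by held-out single-trial reconstruction.

    ``trial_tensors[c][k]`` is the (units x time) rate matrix of trial ``k``
    of condition ``c``.  For each repetition one trial per condition is held
    out; dPCA is fit on the average of the rest and scored by reconstruction
    error of the held-out tensor.  Returns ``(best reg, mean error per grid
    point)``.
    """
    if grid is None:
        grid = np.logspace(-8, -2, 7)
    rng = np.random.default_rng(seed)
    errors = np.zeros(grid.size)
    for _ in range(n_reps):
        test, train = [], []
        for trials in trial_tensors:
            if len(trials) < 2:
                raise ValueError("need >= 2 trials per condition")
            k = int(rng.integers(len(trials)))
            test.append(trials[k])
            rest = [t for i, t in enumerate(trials) if i != k]
            train.append(np.mean(rest, axis=0))
        x_train = np.stack(train, axis=1)     # (U, C, T)
        x_test = np.stack(test, axis=1)
        gm = x_train.mean(axis=(1, 2), keepdims=True)
        xt = (x_test - gm).reshape(x_test.shape[0], -1)
        for gi, reg in enumerate(grid):
            res = fit_dpca(x_train, DPCAConfig(n_components=n_components,
                                               reg=float(reg)))
            recon = res.encoder @ (res.decoder @
                                   (x_train - gm).reshape(x_train.shape[0], -1))
            errors[gi] += float(np.sum((xt - recon) ** 2)) / float(np.sum(xt ** 2))
    errors /= n_reps
    return float(grid[int(np.argmin(errors))]), errors


def encoder_orthogonality(axes: np.ndarray, alpha: float = 0.01,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise angles (degrees) and Kendall-tau non-orthogonality flags.

    ``axes`` is units x components.  A pair is flagged when the Kendall rank
    correlation between its electrode-weighting vectors has p < alpha.
    """
    k = axes.shape[1]
    angles = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            c = abs(float(axes[:, i] @ axes[:, j])) / (
                np.linalg.norm(axes[:, i]) * np.linalg.norm(axes[:, j]))
            angles[i, j] = angles[j, i] = np.degrees(np.arccos(min(c, 1.0)))
            tau = stats.kendalltau(axes[:, i], axes[:, j])
            pvals[i, j] = pvals[j, i] = float(tau.pvalue)
    flags = (pvals < alpha) & ~np.eye(k, dtype=bool)
    return angles, pvals, flags


def axis_orthogonality(result: DPCAResult, alpha: float = 0.01):
    if result.encoder.shape[1] < 2:
        raise ValueError("need >= 2 components")
    return encoder_orthogonality(result.encoder, alpha)


def subspace_angle(axis: np.ndarray, plane: np.ndarray) -> float:
    """Principal angle (degrees) between a unit axis and a 2-D orthonormal plane."""
    axis = np.asarray(axis, dtype=float).ravel()
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("zero axis")
    axis = axis / nrm
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2 or plane.shape[1] != 2:
        raise ValueError("plane must have 2 columns")
    if not np.allclose(plane.T @ plane, np.eye(2), atol=1e-8):
        raise ValueError("plane columns must be orthonormal")
    c = np.linalg.norm(plane.T @ axis)
    return float(np.degrees(np.arccos(min(c, 1.0))))
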