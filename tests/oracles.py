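"""Independent brute-force oracles used across the test suite.

These deliberately re-derive quantities by the most literal route available
(double sums, exhaustive sweeps, generic numerical optimizers) and never call
the implementation paths they are used to check.
"""

from __future__ import annotations

import numpy as np


def naive_cv_squared_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Literal O(N1*N2) double sum of the cross-validated squared distance."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    total = 0.0
    for i in range(n1):
        mu1 = np.delete(a, i, axis=0).mean(axis=0)
        for j in range(n2):
            mu2 = np.delete(b, j, axis=0).mean(axis=0)
            total += float((a[i] - b[j]) @ (mu1 - mu2))
    return total / (n1 * n2)


def skew_fit_by_optimizer(x: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Numerically minimize ||dx - x M^T||^2 over skew-symmetric M."""
    from scipy.optimize import minimize

    k = x.shape[1]
    iu = np.triu_indices(k, 1)

    def unpack(theta):
        m = np.zeros((k, k))
        m[iu] = theta
        return m - m.T

    def loss(theta):
        return float(np.sum((dx - x @ unpack(theta).T) ** 2))

    def grad(theta):
        r = dx - x @ unpack(theta).T
        dm = -2.0 * r.T @ x          # d loss / d M
        return dm[iu] - dm.T[iu]     # projection onto the antisymmetric basis

    res = minimize(loss, np.zeros(len(iu[0])), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    return unpack(res.x)


def tme_dual_by_optimizer(s_t: np.ndarray, s_n: np.ndarray,
                          s_c: np.ndarray) -> np.ndarray:
    """Brute-force minimization of the maximum-entropy dual; returns the
    joint eigenvalue tensor lambda."""
    from scipy.optimize import minimize

    t, n, c = s_t.size, s_n.size, s_c.size

    def dual(nu):
        denom = (nu[:t, None, None] + nu[t:t + n][None, :, None]
                 + nu[t + n:][None, None, :])
        if np.any(denom <= 0):
            return 1e12
        return (-np.sum(np.log(denom)) + nu[:t] @ s_t
                + nu[t:t + n] @ s_n + nu[t + n:] @ s_c)

    nu0 = np.concatenate([n * c / (3 * s_t), t * c / (3 * s_n),
                          t * n / (3 * s_c)])
    res = minimize(dual, nu0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 200_000, "maxfev": 200_000})
    nu = res.x
    denom = (nu[:t, None, None] + nu[t:t + n][None, :, None]
             + nu[t + n:][None, None, :])
    return 1.0 / denom
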