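"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's own solution paths: the LASSO oracle
is a smooth split-variable convex program solved by L-BFGS-B, the CCA
oracle is an alternating least-squares maximizer of corr(Xa, Yb), and the
mixed-model oracle evaluates the full n x n multivariate-normal density.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats


def lasso_oracle(X, y, w, lam):
    """Split beta = b+ - b- into nonnegative halves (smooth objective) and
    minimize with L-BFGS-B; returns (objective, intercept, beta)."""
    n, p = X.shape
    sw = w.sum()

    def f(z):
        b0, bp, bn = z[0], z[1:p + 1], z[p + 1:]
        r = y - b0 - X @ (bp - bn)
        return (w * r * r).sum() / (2 * sw) + lam * (bp.sum() + bn.sum())

    def grad(z):
        b0, bp, bn = z[0], z[1:p + 1], z[p + 1:]
        r = y - b0 - X @ (bp - bn)
        g_beta = -(X.T @ (w * r)) / sw
        g0 = -(w * r).sum() / sw
        return np.concatenate([[g0], g_beta + lam, -g_beta + lam])

    z0 = np.zeros(2 * p + 1)
    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = optimize.minimize(f, z0, jac=grad, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 5000, "ftol": 1e-15,
                                     "gtol": 1e-12})
    return res.fun, res.x[0], res.x[1:p + 1] - res.x[p + 1:]


def alternating_max_rho1(X, Y, n_iter=500, tol=1e-12):
    """Alternate least-squares regressions of each variate on the other set
    until the achieved correlation stabilizes; returns the maximum corr."""
    Xs = (X - X.mean()) / X.std(ddof=1)
    Ys = (Y - Y.mean()) / Y.std(ddof=1)
    Xv, Yv = Xs.to_numpy(), Ys.to_numpy()
    rng = np.random.default_rng(0)
    a = rng.normal(size=Xv.shape[1])
    rho_prev = 0.0
    for _ in range(n_iter):
        u = Xv @ a
        b, *_ = np.linalg.lstsq(Yv, u, rcond=None)
        v = Yv @ b
        a, *_ = np.linalg.lstsq(Xv, v, rcond=None)
        u = Xv @ a
        rho = abs(np.corrcoef(u, v)[0, 1])
        if abs(rho - rho_prev) < tol:
            break
        rho_prev = rho
    return rho


def mvn_loglik(y, X, subjects, beta, sigma_u2, sigma2):
    """Full-covariance multivariate-normal log likelihood of a
    random-intercept model, built brute-force as an n x n matrix."""
    n = len(y)
    Z = pd.get_dummies(subjects).to_numpy(dtype=float)
    V = sigma2 * np.eye(n) + sigma_u2 * (Z @ Z.T)
    resid = np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ beta
    return stats.multivariate_normal.logpdf(resid, mean=np.zeros(n), cov=V)
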