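"""Canonical correlation analysis between aging factors and network volumes.

Given standardized sets X (n x p; e.g. age, CyClo, sex) and Y (n x q; the
seven network volume fractions), CCA finds weight vectors a_k, b_k whose
variates U_k = X a_k and V_k = Y b_k maximize corr(U_k, V_k), successive
pairs being uncorrelated with earlier ones.  The solution comes from the
singular value decomposition of Rxx^{-1/2} Rxy Ryy^{-1/2}: singular values
are the canonical correlations rho_k (their squares the canonical roots,
i.e. shared variance), and the transformed singular vectors are the
standardized canonical weights.  Loadings (structure correlations) are the
correlations of each observed variable with its own set's variates.

Sequential significance of the dimensions uses Wilks'
Lambda_k = prod_{i>=k} (1 - rho_i^2) via Bartlett's chi-squared
approximation and Rao's F approximation; redundancy coefficients summarize
the average variance of one set explained by the other set's variates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class CCAError(ValueError):
    pass


@dataclass
class CCAResult:
    """Canonical weights, correlations, variates and loadings."""

    x_weights: pd.DataFrame      # p x s, standardized canonical weights a
    y_weights: pd.DataFrame      # q x s, weights b
    correlations: np.ndarray     # rho_1 >= ... >= rho_s
    u_scores: pd.DataFrame       # n x s variates of X
    v_scores: pd.DataFrame       # n x s variates of Y
    x_loadings: pd.DataFrame | None = None
    y_loadings: pd.DataFrame | None = None

    @property
    def n_functions(self) -> int:
        return len(self.correlations)

    @property
    def roots(self) -> np.ndarray:
        """Canonical roots rho_k^2 (shared variance per function)."""
        return self.correlations ** 2


@dataclass
class DimensionTests:
    """Sequential tests: row k tests dimensions k..s jointly."""

    table: pd.DataFrame          # columns: k, wilks, statistic, df(...), p


@dataclass
class RedundancyReport:
    per_dimension: pd.DataFrame  # columns: x_given_y, y_given_x
    total_x_given_y: float
    total_y_given_x: float


def max_functions(p: int, q: int) -> int:
    """Number of canonical functions: the size of the smaller set."""
    if p < 1 or q < 1:
        raise CCAError("set sizes must be >= 1")
    return min(p, q)


def shared_variance(rho: float) -> float:
    """Canonical root rho^2 of a canonical correlation."""
    if not (0.0 <= rho <= 1.0):
        raise CCAError("rho must lie in [0, 1]")
    return rho * rho


def bartlett_df(p: int, q: int, k: int) -> int:
    """Degrees of freedom (p - k + 1)(q - k + 1) of the k-th sequential test."""
    if not (1 <= k <= min(p, q)):
        raise CCAError(f"dimension k={k} out of range for p={p}, q={q}")
    return (p - k + 1) * (q - k + 1)


def _inv_sqrt(R: np.ndarray, name: str, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() <= floor:
        raise CCAError(f"{name} set is rank deficient (min eigenvalue "
                       f"{vals.min():.2e})")
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def _standardize(M: pd.DataFrame) -> pd.DataFrame:
    sd = M.std(axis=0, ddof=1)
    zero = sd[~(sd > 0)]
    if len(zero):
        raise CCAError(f"zero-variance column(s): {list(zero.index)}")
    return (M - M.mean(axis=0)) / sd


def fit_cca(X: pd.DataFrame, Y: pd.DataFrame) -> CCAResult:
    """Fit canonical correlations between two variable sets.

    Columns are standardized internally (so weights are standardized
    canonical weights); the sign of each function is fixed so that the
    largest-magnitude X-side loading is positive.
    """
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise CCAError(f"need n > p + q (got n={n}, p={p}, q={q})")
    Xs = _standardize(X)
    Ys = _standardize(Y)
    Rxx = np.corrcoef(Xs.to_numpy(), rowvar=False).reshape(p, p)
    Ryy = np.corrcoef(Ys.to_numpy(), rowvar=False).reshape(q, q)
    Rxy = (Xs.to_numpy().T @ Ys.to_numpy()) / (n - 1)
    Kx = _inv_sqrt(Rxx, "X")
    Ky = _inv_sqrt(Ryy, "Y")
    U, s, Vt = np.linalg.svd(Kx @ Rxy @ Ky)
    nf = max_functions(p, q)
    rho = np.clip(s[:nf], 0.0, 1.0)
    a = Kx @ U[:, :nf]
    b = Ky @ Vt[:nf].T

    u = Xs.to_numpy() @ a
    v = Ys.to_numpy() @ b
    # unit sample variance of every variate
    su = u.std(axis=0, ddof=1)
    sv = v.std(axis=0, ddof=1)
    a /= su
    b /= sv
    u /= su
    v /= sv
    # sign convention: largest-|loading| on the X side positive
    xl = (Xs.to_numpy().T @ u) / (n - 1)
    for k in range(nf):
        j = int(np.argmax(np.abs(xl[:, k])))
        if xl[j, k] < 0:
            a[:, k] *= -1
            u[:, k] *= -1
            b[:, k] *= -1
            v[:, k] *= -1
    funcs = [f"F{k + 1}" for k in range(nf)]
    result = CCAResult(
        x_weights=pd.DataFrame(a, index=X.columns, columns=funcs),
        y_weights=pd.DataFrame(b, index=Y.columns, columns=funcs),
        correlations=rho,
        u_scores=pd.DataFrame(u, index=X.index, columns=funcs),
        v_scores=pd.DataFrame(v, index=X.index, columns=funcs),
    )
    result.x_loadings, result.y_loadings = canonical_loadings(result, X, Y)
    return result


def canonical_loadings(result: CCAResult, X: pd.DataFrame, Y: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structure correlations of each observed variable with its own variates."""
    funcs = result.u_scores.columns
    xl = pd.DataFrame(
        {f: [stats.pearsonr(X[c], result.u_scores[f]).statistic for c in X.columns]
         for f in funcs}, index=X.columns)
    yl = pd.DataFrame(
        {f: [stats.pearsonr(Y[c], result.v_scores[f]).statistic for c in Y.columns]
         for f in funcs}, index=Y.columns)
    return xl, yl


def _wilks(rho: np.ndarray) -> np.ndarray:
    r2 = np.asarray(rho, dtype=float) ** 2
    s = len(r2)
    return np.array([np.prod(1.0 - r2[k:]) for k in range(s)])


def bartlett_sequential_test(rho: np.ndarray, n: int, p: int, q: int
                             ) -> DimensionTests:
    """Bartlett's chi-squared tests of the sequential dimension hypotheses.

    For starting dimension k: Lambda_k = prod_{i>=k} (1 - rho_i^2),
    chi2_k = -(n - 1 - (p + q + 1)/2) ln Lambda_k on (p-k+1)(q-k+1) df.
    """
    rho = np.asarray(rho, dtype=float)
    if (rho >= 1.0).any():
        warnings.warn("canonical correlation of 1: infinite statistic")
    lam = _wilks(rho)
    mult = n - 1 - (p + q + 1) / 2.0
    rows = []
    for k in range(1, len(rho) + 1):
        with np.errstate(divide="ignore"):
            chi2 = -mult * np.log(lam[k - 1])
        df = bartlett_df(p, q, k)
        rows.append({"k": k, "wilks": lam[k - 1], "chi2": float(chi2),
                     "df": df, "p": float(stats.chi2.sf(chi2, df))})
    return DimensionTests(table=pd.DataFrame(rows))


def rao_f_test(rho: np.ndarray, n: int, p: int, q: int) -> DimensionTests:
    """Rao's F approximation for the sequential dimension hypotheses."""
    rho = np.asarray(rho, dtype=float)
    lam = _wilks(rho)
    rows = []
    for k in range(1, len(rho) + 1):
        pk = p - k + 1
        qk = q - k + 1
        m = n - 1 - (pk + qk + 1) / 2.0
        denom = pk * pk + qk * qk - 5
        t = np.sqrt((pk * pk * qk * qk - 4.0) / denom) if denom > 0 else 1.0
        df1 = pk * qk
        df2 = m * t - pk * qk / 2.0 + 1.0
        if df2 <= 0:
            raise CCAError(f"denominator df {df2:.1f} <= 0 at k={k}; "
                           "larger n required")
        lam_t = lam[k - 1] ** (1.0 / t)
        F = (1.0 - lam_t) / lam_t * (df2 / df1)
        rows.append({"k": k, "wilks": lam[k - 1], "F": float(F),
                     "df1": float(df1), "df2": float(df2),
                     "p": float(stats.f.sf(F, df1, df2))})
    return DimensionTests(table=pd.DataFrame(rows))


def redundancy(result: CCAResult) -> RedundancyReport:
    """Per-dimension and total redundancy of each set given the other.

    Rd(Y|X)_k = mean_j loading(y_j, V_k)^2 * rho_k^2: the average fraction
    of Y's observed variance explained by the k-th X-side variate (and
    symmetrically for X given Y).  Totals sum over dimensions.
    """
    if result.x_loadings is None or result.y_loadings is None:
        raise CCAError("result lacks loadings")
    r2 = result.roots
    y_given_x = (result.y_loadings ** 2).mean(axis=0).to_numpy() * r2
    x_given_y = (result.x_loadings ** 2).mean(axis=0).to_numpy() * r2
    per = pd.DataFrame({"x_given_y": x_given_y, "y_given_x": y_given_x},
                       index=result.u_scores.columns)
    return RedundancyReport(per_dimension=per,
                            total_x_given_y=float(x_given_y.sum()),
                            total_y_given_x=float(y_given_x.sum()))
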