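"""Random-intercept linear mixed models and the four-model selection ladder.

The model is y = X beta + Z u + e with one random intercept per subject,
u ~ N(0, sigma_u^2 I), e ~ N(0, sigma^2 I), estimated by maximum (not
restricted) likelihood so that AIC/BIC and likelihood-ratio tests across
fixed-effect structures are valid.  Given the variance ratio
theta = sigma_u^2 / sigma^2, beta and sigma^2 have closed-form profiled
estimates, and the per-subject block structure of V = I + theta Z Z' makes
the profiled log-likelihood evaluable in time linear in the number of
observations; theta is then optimized by a coarse log-spaced grid followed
by bounded scalar minimization on [0, 1e6].

The ladder fits GMV ~ 1, ~ age, ~ age + sex, ~ age + sex + CyClo (all with
a subject random intercept) on one common row set and compares successive
models by AIC, BIC and chi-squared likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


class LMMError(ValueError):
    pass


@dataclass
class LMMFit:
    """Maximum-likelihood random-intercept fit."""

    beta: pd.Series
    beta_se: pd.Series
    sigma_u2: float
    sigma2: float
    loglik: float
    kparams: int                 # fixed coefficients + 2 variance parameters
    n_obs: int
    formula: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.kparams

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.kparams * np.log(self.n_obs)

    def wald_p(self) -> pd.Series:
        z = self.beta / self.beta_se
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.beta.index)


def _group_blocks(subjects: pd.Series) -> list[np.ndarray]:
    codes, _ = pd.factorize(subjects)
    order = np.argsort(codes, kind="stable")
    bounds = np.flatnonzero(np.diff(codes[order])) + 1
    return np.split(order, bounds)


def _profiled(theta: float, y: np.ndarray, X: np.ndarray,
              blocks: list[np.ndarray]) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profile beta and sigma^2 at fixed theta; returns (loglik, beta, sigma2, XtVX)."""
    p = X.shape[1]
    n = len(y)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    rss_terms = []
    logdet = 0.0
    # V_i^{-1} = I - theta/(1 + theta n_i) J for each subject block
    for idx in blocks:
        ni = len(idx)
        Xi, yi = X[idx], y[idx]
        shrink = theta / (1.0 + theta * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtVX += Xi.T @ Xi - shrink * np.outer(sx, sx)
        XtVy += Xi.T @ yi - shrink * sx * sy
        logdet += np.log1p(theta * ni)
        rss_terms.append((idx, shrink, sy, sx))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError as exc:
        raise LMMError("fixed-effect design is rank deficient") from exc
    quad = 0.0
    for idx, shrink, sy, sx in rss_terms:
        ri = y[idx] - X[idx] @ beta
        sr = ri.sum()
        quad += ri @ ri - shrink * sr * sr
    sigma2 = quad / n
    if not (sigma2 > 0) or not np.isfinite(sigma2):
        raise LMMError(f"non-finite profiled likelihood at theta={theta:g}")
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, XtVX


def fit_random_intercept(y: pd.Series, X: pd.DataFrame, subjects: pd.Series,
                         theta_max: float = 1e6, tol: float = 1e-9,
                         formula: str = "") -> LMMFit:
    """ML fit of a random-intercept model by profiled likelihood in theta."""
    if subjects.nunique() < 2:
        raise LMMError("need at least 2 subjects")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise LMMError("fixed-effect design is rank deficient")
    yv = y.to_numpy(dtype=float)
    blocks = _group_blocks(subjects)

    def neg_ll(theta: float) -> float:
        return -_profiled(theta, yv, Xv, blocks)[0]

    grid = np.concatenate([[0.0], np.logspace(-6, 6, 61)])
    vals = [neg_ll(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = min(grid[min(i + 1, len(grid) - 1)], theta_max)
    if hi <= lo:
        hi = lo + 1e-6
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    theta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    ll, beta, sigma2, XtVX = _profiled(theta, yv, Xv, blocks)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    return LMMFit(beta=pd.Series(beta, index=X.columns),
                  beta_se=pd.Series(se, index=X.columns),
                  sigma_u2=theta * sigma2, sigma2=sigma2,
                  loglik=float(ll), kparams=Xv.shape[1] + 2, n_obs=len(yv),
                  formula=formula)


def information_criteria(fit: LMMFit) -> tuple[float, float]:
    """(AIC, BIC) = (-2 loglik + 2 k, -2 loglik + k ln n)."""
    return fit.aic, fit.bic


def lrt_compare(reduced: LMMFit, full: LMMFit) -> tuple[float, int, float]:
    """Chi-squared likelihood-ratio test of nested ML fits."""
    if reduced.n_obs != full.n_obs:
        raise LMMError("models fit on different row sets")
    red_terms = set(reduced.beta.index)
    full_terms = set(full.beta.index)
    if not red_terms <= full_terms:
        raise LMMError("reduced model terms are not nested in the full model")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = len(full_terms) - len(red_terms)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
    return chi2, df, p


@dataclass
class ModelLadder:
    """The four nested random-intercept fits and their comparisons."""

    fits: list[LMMFit]
    lrt: list[tuple[float, int, float]]   # successive-model tests

    def table(self) -> pd.DataFrame:
        """AIC/BIC/loglik summary plus Wald significance stars per coefficient."""
        rows = []
        for fit in self.fits:
            stars = {t: _stars(p) for t, p in fit.wald_p().items()}
            rows.append({"model": fit.formula, "loglik": fit.loglik,
                         "AIC": fit.aic, "BIC": fit.bic,
                         "k": fit.kparams, **stars})
        return pd.DataFrame(rows)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


LADDER_TERMS = [[], ["age"], ["age", "sex"], ["age", "sex", "cyclo"]]


def build_model_ladder(data: pd.DataFrame, response: str = "gmv_frac"
                       ) -> ModelLadder:
    """Fit the four-model ladder on the common complete-case row set.

    ``data`` must carry columns response, age, sex, cyclo, subject_id.
    """
    need = [response, "age", "sex", "cyclo", "subject_id"]
    missing = [c for c in need if c not in data.columns]
    if missing:
        raise LMMError(f"missing columns: {missing}")
    cc = data[need].dropna()
    fits = []
    for terms in LADDER_TERMS:
        X = pd.DataFrame({"const": np.ones(len(cc))}, index=cc.index)
        for t in terms:
            X[t] = cc[t].astype(float)
        name = f"{response} ~ {' + '.join(['1'] + terms)} + (1 | subject)"
        fits.append(fit_random_intercept(cc[response], X, cc["subject_id"],
                                         formula=name))
    lrt = [lrt_compare(fits[i], fits[i + 1]) for i in range(len(fits) - 1)]
    return ModelLadder(fits=fits, lrt=lrt)
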