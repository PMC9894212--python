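"""The cytokine clock: pooled, cross-validated weighted LASSO of age on markers.

Per completed panel, calendar age is regressed on the centered/scaled
marker levels by an L1-penalized weighted least-squares fit (cyclic
coordinate descent with soft-thresholding, unpenalized intercept).  The
penalty is chosen by K-fold cross-validation with *subjects* (not visits)
randomized to folds, so repeated measures of one person never straddle the
train/test split.  Fitting one model per completed panel and pooling gives
per-marker mean coefficients, standard errors and selection frequencies,
and a per-visit predicted physiological age ("CyClo") as the median (or
mean) of the per-model predictions.  Predicted ages are finally propagated
to a subject's nearby visits (within +/- 3 years, shifted by the elapsed
time) to increase overlap with imaging visits.

The objective minimized at penalty lam is

    (1 / (2 * sum w)) * sum_i w_i (y_i - b0 - x_i . beta)^2 + lam * sum_j |beta_j|

with observation weights w normalized to mean one before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import ImputedEnsemble
from .preprocess import BalancingWeights

log = logging.getLogger(__name__)


class ClockError(ValueError):
    pass


@dataclass
class ClockModel:
    """A single fitted LASSO clock (one imputation)."""

    intercept: float
    coef: pd.Series                  # years per standardized log-unit
    lam: float
    centers: pd.Series
    scales: pd.Series
    cv_curve: pd.DataFrame | None = None     # columns: lam, mse, se
    selected_lambda_rule: str = "1se"

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Z = (X[self.coef.index] - self.centers) / self.scales
        return pd.Series(self.intercept + Z.to_numpy() @ self.coef.to_numpy(),
                         index=X.index, name="cyclo")


@dataclass
class PooledClock:
    """Ensemble summary: pooled coefficients, selection frequencies, CyClo."""

    mean_beta: pd.Series
    se_beta: pd.Series
    selection_frequency: pd.Series
    predictions: pd.DataFrame        # visits x M per-model predictions
    cyclo: pd.Series                 # pooled per-visit prediction (years)
    pool_statistic: str = "median"
    lambdas: list[float] = field(default_factory=list)
    rule: str = "1se"


def standardize_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center and scale columns to mean 0, sd 1 (divisor n-1).

    Returns the standardized matrix and the stored (center, scale)
    transform for prediction on new data.
    """
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    zero = scales[~(scales > 0)]
    if len(zero):
        raise ClockError(f"zero-variance column(s): {list(zero.index)}")
    return (X - centers) / scales, centers, scales


def lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero:
    max_j |sum_i w_i x_ij (y_i - weighted mean of y)| / sum_i w_i.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    ybar = (w * y).sum() / sw
    grad = X.T @ (w * (y - ybar))
    return float(np.max(np.abs(grad)) / sw)


def _cd_solve(G: np.ndarray, c: np.ndarray, sum_w: float, lam: float,
              beta: np.ndarray, tol: float, max_sweeps: int) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on the Gram form of the weighted LASSO."""
    p = len(c)
    thr = lam * sum_w
    diag = np.diag(G).copy()
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            r = c[j] - G[j] @ beta + diag[j] * beta[j]
            if r > thr:
                new = (r - thr) / diag[j]
            elif r < -thr:
                new = (r + thr) / diag[j]
            else:
                new = 0.0
            d = abs(new - beta[j])
            if d > delta:
                delta = d
            beta[j] = new
        if delta < tol:
            return beta, sweep + 1
    raise ClockError(f"coordinate descent did not converge at lam={lam:g}; "
                     f"last max change {delta:.3e}")


def _gram(X: np.ndarray, y: np.ndarray, w: np.ndarray
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted centering and Gram quantities for the intercept-profiled fit."""
    sw = w.sum()
    xm = (w[:, None] * X).sum(axis=0) / sw
    ym = (w * y).sum() / sw
    Xc = X - xm
    G = (Xc * w[:, None]).T @ Xc
    c = Xc.T @ (w * (y - ym))
    return G, c, xm, np.array([ym]), sw


def lasso_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float,
              tol: float = 1e-7, max_sweeps: int = 100_000,
              beta_init: np.ndarray | None = None
              ) -> tuple[float, np.ndarray]:
    """Weighted LASSO at one penalty; returns (intercept, coefficients).

    The intercept is unpenalized (profiled out exactly by weighted
    centering); convergence is declared when the largest coefficient change
    in a sweep falls below ``tol``.
    """
    if lam < 0:
        raise ClockError("lam must be nonnegative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    G, c, xm, ym, sw = _gram(X, y, w)
    beta = np.zeros(X.shape[1]) if beta_init is None else beta_init.copy()
    beta, _ = _cd_solve(G, c, sw, lam, beta, tol, max_sweeps)
    intercept = float(ym[0] - xm @ beta)
    return intercept, beta


def lasso_path(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               lambdas: np.ndarray, tol: float = 1e-7,
               max_sweeps: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits over a decreasing penalty grid.

    Returns (intercepts of length L, coefficient matrix p x L).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    G, c, xm, ym, sw = _gram(X, y, w)
    p = X.shape[1]
    B = np.zeros((p, len(lambdas)))
    b0 = np.zeros(len(lambdas))
    beta = np.zeros(p)
    for l, lam in enumerate(lambdas):
        beta, _ = _cd_solve(G, c, sw, lam, beta, tol, max_sweeps)
        B[:, l] = beta
        b0[l] = ym[0] - xm @ beta
    return b0, B


def lasso_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    intercept: float, beta: np.ndarray, lam: float) -> float:
    r = y - intercept - X @ beta
    return float((w * r * r).sum() / (2.0 * w.sum()) + lam * np.abs(beta).sum())


def kkt_max_violation(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      intercept: float, beta: np.ndarray, lam: float) -> float:
    """Largest Karush-Kuhn-Tucker residual of a candidate LASSO solution.

    At an exact optimum the (weighted, normalized) gradient of the smooth
    part satisfies |g_j| <= lam where beta_j = 0 and g_j = -lam sign(beta_j)
    elsewhere; the intercept gradient must vanish.
    """
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    r = y - intercept - X @ beta
    g = -(X.T @ (w * r)) / sw
    viol = np.where(beta == 0.0,
                    np.maximum(np.abs(g) - lam, 0.0),
                    np.abs(g + lam * np.sign(beta)))
    g0 = abs((w * r).sum() / sw)
    return float(max(viol.max(initial=0.0), g0))


def default_lambda_grid(lam_max: float, n_lambdas: int = 100,
                        min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio * lambda_max."""
    if lam_max <= 0:
        lam_max = 1e-3
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambdas)


def assign_folds(groups: pd.Series, n_folds: int,
                 rng: np.random.Generator) -> pd.Series:
    """Randomize subjects (not visits) to folds; every visit of a subject
    shares a fold."""
    subjects = pd.unique(groups)
    if n_folds > len(subjects):
        raise ClockError(f"K={n_folds} exceeds {len(subjects)} subjects")
    perm = rng.permutation(len(subjects))
    fold_of = {s: int(perm[i] % n_folds) for i, s in enumerate(subjects)}
    return groups.map(fold_of)


def grouped_cv_select_lambda(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                             groups: pd.Series, n_folds: int = 10,
                             rule: str = "1se",
                             rng: np.random.Generator | None = None,
                             lambdas: np.ndarray | None = None,
                             tol: float = 1e-7
                             ) -> tuple[float, pd.DataFrame]:
    """Subject-grouped K-fold CV over the penalty grid.

    Per penalty, the weighted mean squared error on held-out folds is
    averaged across folds with a standard error (sd across folds / sqrt K).
    Rule "min" picks the minimizer; rule "1se" picks the largest penalty
    whose CV error is within one standard error of the minimum.
    """
    if rule not in ("1se", "min"):
        raise ClockError(f"unknown rule {rule!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if lambdas is None:
        lambdas = default_lambda_grid(lambda_max(X, y, w))
    folds = assign_folds(groups, n_folds, rng).to_numpy()
    fold_mse = np.empty((n_folds, len(lambdas)))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        b0, B = lasso_path(X[train], y[train], w[train], lambdas, tol=tol)
        pred = X[test] @ B + b0[None, :]
        err = pred - y[test, None]
        fold_mse[f] = (w[test, None] * err * err).sum(axis=0) / w[test].sum()
    mse = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    curve = pd.DataFrame({"lam": lambdas, "mse": mse, "se": se})
    i_min = int(np.argmin(mse))
    if rule == "min":
        lam_star = float(lambdas[i_min])
    else:
        ok = np.nonzero(mse <= mse[i_min] + se[i_min])[0]
        lam_star = float(lambdas[ok.min()])   # grid decreasing: first = largest
    return lam_star, curve


def fit_clock_single(panel: pd.DataFrame, ages: pd.Series,
                     weights: BalancingWeights, groups: pd.Series,
                     n_folds: int = 10, rule: str = "1se",
                     rng: np.random.Generator | None = None) -> ClockModel:
    """Standardize, select the penalty by grouped CV, refit on all visits."""
    Z, centers, scales = standardize_columns(panel)
    Xz = Z.to_numpy()
    y = ages.loc[panel.index].to_numpy(dtype=float)
    w = weights.normalized().loc[panel.index].to_numpy()
    lam_star, curve = grouped_cv_select_lambda(
        Xz, y, w, groups.loc[panel.index], n_folds=n_folds, rule=rule, rng=rng)
    b0, beta = lasso_fit(Xz, y, w, lam_star)
    return ClockModel(intercept=b0,
                      coef=pd.Series(beta, index=panel.columns, name="beta"),
                      lam=lam_star, centers=centers, scales=scales,
                      cv_curve=curve, selected_lambda_rule=rule)


def fit_clock_ensemble(ensemble: ImputedEnsemble, ages: pd.Series,
                       weights: BalancingWeights, groups: pd.Series,
                       n_folds: int = 10, rule: str = "1se",
                       pool: str = "median", seed: int = 0) -> PooledClock:
    """One grouped-CV LASSO per completed panel, pooled over the ensemble.

    Pooled outputs: per-marker mean and standard error of the coefficient
    across the M models, the selection frequency (fraction of models with a
    nonzero coefficient), and the per-visit CyClo as the configured pooling
    statistic of the M predictions (median by default, mean available).
    """
    if pool not in ("median", "mean"):
        raise ClockError(f"unknown pooling statistic {pool!r}")
    streams = np.random.SeedSequence(seed).spawn(ensemble.m)
    betas, lams, preds = [], [], []
    markers = list(ensemble.panels[0].columns)
    for panel, ss in zip(ensemble.panels, streams):
        model = fit_clock_single(panel, ages, weights, groups,
                                 n_folds=n_folds, rule=rule,
                                 rng=np.random.default_rng(ss))
        betas.append(model.coef)
        lams.append(model.lam)
        preds.append(model.predict(panel))
    B = pd.concat(betas, axis=1)
    B.columns = range(ensemble.m)
    P = pd.concat(preds, axis=1)
    P.columns = range(ensemble.m)
    m = ensemble.m
    mean_beta = B.mean(axis=1)
    se_beta = (B.std(axis=1, ddof=1) / np.sqrt(m)) if m > 1 else B.std(axis=1).fillna(0.0) * 0.0
    cyclo = P.median(axis=1) if pool == "median" else P.mean(axis=1)
    return PooledClock(mean_beta=mean_beta, se_beta=se_beta,
                       selection_frequency=(B != 0.0).mean(axis=1),
                       predictions=P, cyclo=cyclo.rename("cyclo"),
                       pool_statistic=pool, lambdas=[float(l) for l in lams],
                       rule=rule)


def propagate_cyclo(measured: pd.Series, visits: pd.DataFrame,
                    max_gap: float = 3.0) -> pd.DataFrame:
    """Carry a subject's predicted age to nearby unmeasured visits.

    A visit lacking a measured CyClo borrows from the same subject's
    nearest-in-time measured visit within ``max_gap`` years (ties broken
    toward the earlier source) and registers the source value shifted by
    the elapsed time: a 2020 prediction c propagated back to a 2019 visit
    becomes c - 1.  Visits with no donor stay unassigned (absent from the
    output).

    Returns a table with columns cyclo, source ("measured"/"propagated"),
    gap (signed years, target minus source; 0 for measured entries).
    """
    if max_gap <= 0:
        raise ClockError("max_gap must be positive")
    rows = {}
    for vid in measured.index:
        rows[vid] = {"cyclo": float(measured[vid]), "source": "measured",
                     "gap": 0.0}
    t = visits["visit_time"]
    for subject, sub in visits.groupby("subject_id"):
        have = [v for v in sub.index if v in rows and rows[v]["source"] == "measured"]
        if not have:
            continue
        for vid in sub.index:
            if vid in rows:
                continue
            gaps = {src: t[vid] - t[src] for src in have}
            ok = {s: g for s, g in gaps.items() if abs(g) <= max_gap}
            if not ok:
                continue
            src = min(ok, key=lambda s: (abs(ok[s]), t[s]))
            rows[vid] = {"cyclo": rows[src]["cyclo"] + ok[src],
                         "source": "propagated", "gap": float(ok[src])}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "visit_id"
    return out.reindex([v for v in visits.index if v in rows])
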