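"""Multiple imputation by chained equations with weighted predictive mean matching.

Each incomplete marker is modeled conditionally on all other markers plus
sex, with per-visit age-bin balancing weights entering the conditional
regressions as observation weights.  Missing entries are filled by
predictive mean matching: the regression coefficients are perturbed by a
draw from their sampling distribution, predicted values are computed for
the missing rows, and each missing entry copies the observed value of one
of its k nearest predicted neighbors.  Imputed values are therefore always
members of the marker's observed support.  Running the chain M times with
independent substreams yields an ensemble of completed panels whose
observed entries are bit-identical to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CytokinePanel
from .preprocess import BalancingWeights

log = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSpec:
    """Parameters of the chained-equation ensemble.

    n_imputations is the ensemble size M (500 in the emulated study;
    desk-scale runs use less).  n_donors and n_sweeps default to the
    conventional chained-equations choices (5 donors, 5 sweeps).
    """

    n_imputations: int = 500
    n_sweeps: int = 5
    n_donors: int = 5
    include_sex: bool = True
    ridge: float = 1e-8          # fallback penalty for singular systems
    seed: int = 0

    def validate(self) -> None:
        if self.n_imputations < 1:
            raise ImputationError("n_imputations must be >= 1")
        if self.n_donors < 1:
            raise ImputationError("n_donors must be >= 1")
        if self.n_sweeps < 1:
            raise ImputationError("n_sweeps must be >= 1")


@dataclass
class ImputedEnsemble:
    """M completed panels plus provenance (seed, sweeps, donors)."""

    panels: list[pd.DataFrame]
    spec: ImputationSpec
    source_mask: pd.DataFrame = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.panels)


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares; returns (beta, covariance, sigma2).

    Falls back to a tiny ridge penalty when the normal equations are
    singular (logged), so chains never abort on degenerate predictors.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    p = X.shape[1]
    try:
        beta = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        log.warning("singular predictor system; ridge fallback %.1e", ridge)
        XtX = XtX + ridge * np.eye(p)
        beta = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)
    resid = yw - Xw @ beta
    dof = max(len(y) - p, 1)
    sigma2 = float(resid @ resid) / dof
    return beta, sigma2 * XtX_inv, sigma2


def weighted_pmm_impute_once(panel: CytokinePanel, spec: ImputationSpec,
                             weights: BalancingWeights,
                             sex: pd.Series | None,
                             rng: np.random.Generator) -> pd.DataFrame:
    """One chained-equations pass; returns a completed matrix.

    Missing entries are initialized by weighted draws from each marker's
    observed values, then each sweep revisits every incomplete marker in
    column order: weighted least-squares fit on the observed rows, a normal
    perturbation of the coefficients with the estimated covariance,
    point-estimate predictions for observed rows and perturbed predictions
    for missing rows, and donor matching among the k nearest predicted
    observed rows (ties and donor choice uniform at random).
    """
    spec.validate()
    values = panel.values.to_numpy(dtype=float).copy()
    mask_obs = ~np.isnan(values)
    n, p = values.shape
    if mask_obs.all():
        return panel.values.copy()
    w = weights.normalized().loc[panel.values.index].to_numpy()

    cols_incomplete = [j for j in range(p) if not mask_obs[:, j].all()]
    for j in cols_incomplete:
        obs = mask_obs[:, j]
        if obs.sum() < spec.n_donors:
            raise ImputationError(
                f"marker {panel.values.columns[j]!r} has fewer observed "
                f"entries than n_donors={spec.n_donors}")
        pool = values[obs, j]
        pw = w[obs] / w[obs].sum()
        values[~obs, j] = rng.choice(pool, size=(~obs).sum(), p=pw)

    sex_col = None
    if spec.include_sex and sex is not None:
        sex_col = sex.loc[panel.values.index].to_numpy(dtype=float)

    for _ in range(spec.n_sweeps):
        for j in cols_incomplete:
            obs = mask_obs[:, j]
            others = [k for k in range(p) if k != j]
            X = values[:, others]
            if sex_col is not None:
                X = np.column_stack([X, sex_col])
            X = np.column_stack([np.ones(n), X])
            beta, cov, _ = _weighted_lstsq(X[obs], values[obs, j], w[obs],
                                           spec.ridge)
            # symmetrize for the multivariate normal draw
            cov = (cov + cov.T) / 2.0
            try:
                L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
            except np.linalg.LinAlgError:
                L = np.zeros((len(beta), len(beta)))
            beta_star = beta + L @ rng.standard_normal(len(beta))
            yhat_obs = X[obs] @ beta
            yhat_mis = X[~obs] @ beta_star
            # k nearest observed predictions per missing row; donor uniform
            d = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
            k = min(spec.n_donors, d.shape[1])
            nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
            pick = rng.integers(k, size=len(yhat_mis))
            donor_idx = nearest[np.arange(len(yhat_mis)), pick]
            obs_values = values[obs, j]
            values[~obs, j] = obs_values[donor_idx]
    return pd.DataFrame(values, index=panel.values.index,
                        columns=panel.values.columns)


def generate_ensemble(panel: CytokinePanel, spec: ImputationSpec,
                      weights: BalancingWeights,
                      sex: pd.Series | None = None) -> ImputedEnsemble:
    """M independent chained runs from distinct substreams of the master seed."""
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_imputations)
    panels = []
    for m, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        completed = weighted_pmm_impute_once(panel, spec, weights, sex, rng)
        panels.append(completed)
    return ImputedEnsemble(panels=panels, spec=spec, source_mask=panel.mask)
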