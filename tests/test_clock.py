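"""Weighted LASSO clock: coordinate descent vs convex oracle, KKT optimality,
penalty grid and CV rules, pooling, and temporal propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cytoclock.clock import (ClockError, assign_folds, default_lambda_grid,
                             fit_clock_ensemble, grouped_cv_select_lambda,
                             kkt_max_violation, lambda_max, lasso_fit,
                             lasso_objective, lasso_path, propagate_cyclo,
                             standardize_columns)
from cytoclock.impute import ImputationSpec, ImputedEnsemble
from cytoclock.preprocess import BalancingWeights


from oracles import lasso_oracle


def _unit_weights(index):
    return BalancingWeights(w=pd.Series(1.0, index=index),
                            bin_edges=np.array([0.0, 1.0]),
                            bin_counts=np.array([len(index)]))


# ---------------------------------------------------------------- standardize

def test_standardize_columns_hand_example_and_round_trip():
    X = pd.DataFrame({"a": [0.0, 2.0], "b": [5.0, 9.0]})
    Z, centers, scales = standardize_columns(X)
    np.testing.assert_allclose(Z["a"], [-0.70710678, 0.70710678])
    np.testing.assert_allclose((X - centers) / scales, Z)
    shifted, *_ = standardize_columns(X + 100.0)
    pd.testing.assert_frame_equal(shifted, Z)
    with pytest.raises(ClockError, match="c"):
        standardize_columns(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))


# ----------------------------------------------------------------- lambda max

def test_lambda_max_orthogonal_and_identity_cases():
    rng = np.random.default_rng(0)
    n = 40
    y = rng.normal(size=n)
    X = np.ones((n, 1))          # constant column, centered corr 0
    X = X - X.mean()
    assert lambda_max(X, y, np.ones(n)) == pytest.approx(0.0, abs=1e-12)

    yc = y - y.mean()
    assert lambda_max(yc[:, None], y, np.ones(n)) == pytest.approx(
        yc @ yc / n)                       # weighted variance of y

    # at lam >= lambda_max the fit is all zeros with weighted-mean intercept
    Xr = rng.normal(size=(n, 4))
    w = rng.uniform(0.5, 2.0, n)
    lm = lambda_max(Xr, y, w)
    b0, beta = lasso_fit(Xr, y, w, lm * 1.000001)
    np.testing.assert_allclose(beta, 0.0, atol=1e-12)
    assert b0 == pytest.approx((w * y).sum() / w.sum())


# ------------------------------------------------------------------ lasso fit

def test_lasso_at_zero_penalty_equals_weighted_least_squares():
    rng = np.random.default_rng(1)
    n, p = 60, 4
    X = rng.normal(size=(n, p))
    y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=n)
    w = rng.uniform(0.5, 2.0, n)
    b0, beta = lasso_fit(X, y, w, 0.0)
    A = np.column_stack([np.ones(n), X]) * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
    np.testing.assert_allclose(np.r_[b0, beta], coef, atol=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_lasso_matches_convex_oracle_and_kkt(seed):
    """Coordinate descent objective within 1e-6 of the independent convex
    solver; KKT residual below 1e-6 (20 seeded toys, n <= 60, p <= 5)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 61))
    p = int(rng.integers(2, 6))
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta_true = rng.normal(size=p) * (rng.random(p) < 0.6)
    y = 2.0 + X @ beta_true + rng.normal(size=n)
    w = rng.uniform(0.5, 2.0, n)
    w = w / w.mean()
    lam = float(rng.uniform(0.02, 0.5) * lambda_max(X, y, w))
    b0, beta = lasso_fit(X, y, w, lam, tol=1e-10)
    obj = lasso_objective(X, y, w, b0, beta, lam)
    obj_oracle = lasso_oracle(X, y, w, lam)[0]
    assert obj <= obj_oracle + 1e-6
    assert abs(obj - obj_oracle) < 1e-6
    assert kkt_max_violation(X, y, w, b0, beta, lam) < 1e-6


def test_lasso_path_continuity():
    rng = np.random.default_rng(5)
    n, p = 80, 6
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    w = np.ones(n)
    grid = default_lambda_grid(lambda_max(X, y, w), n_lambdas=60)
    _, B = lasso_path(X, y, w, grid)
    steps = np.abs(np.diff(B, axis=1)).max(axis=0)
    assert steps.max() < 0.35      # no oscillation between adjacent grid points


# -------------------------------------------------------------------- CV

def test_grouped_folds_keep_subjects_together():
    rng = np.random.default_rng(2)
    groups = pd.Series(np.repeat([f"s{i}" for i in range(25)], 3))
    folds = assign_folds(groups, 5, rng)
    per_subject = folds.groupby(groups).nunique()
    assert (per_subject == 1).all()
    with pytest.raises(ClockError):
        assign_folds(pd.Series(["a", "b"]), 5, rng)


def test_one_visit_per_subject_reduces_to_plain_kfold():
    rng = np.random.default_rng(3)
    groups = pd.Series([f"s{i}" for i in range(30)])
    folds = assign_folds(groups, 5, rng)
    assert sorted(folds.value_counts()) == [6] * 5


def test_1se_rule_selects_at_least_min_rule_penalty():
    rng = np.random.default_rng(4)
    n_sub = 40
    groups = pd.Series(np.repeat([f"s{i}" for i in range(n_sub)], 2))
    n = len(groups)
    X = rng.normal(size=(n, 5))
    y = X @ [3.0, -2.0, 0.0, 0.0, 0.0] + rng.normal(size=n)
    w = np.ones(n)
    lam_1se, _ = grouped_cv_select_lambda(X, y, w, groups, n_folds=5,
                                          rule="1se",
                                          rng=np.random.default_rng(7))
    lam_min, _ = grouped_cv_select_lambda(X, y, w, groups, n_folds=5,
                                          rule="min",
                                          rng=np.random.default_rng(7))
    assert lam_1se >= lam_min


# -------------------------------------------------------------------- pooling

def test_single_model_pool_reduces_to_single_fit(recovery_cohort):
    from cytoclock.preprocess import compute_balancing_weights
    cfg, visits, panel, missing, _, _ = recovery_cohort
    weights = compute_balancing_weights(visits["age"])
    ens = ImputedEnsemble(panels=[panel.values.copy()],
                          spec=ImputationSpec(n_imputations=1),
                          source_mask=panel.mask)
    pooled = fit_clock_ensemble(ens, visits["age"], weights,
                                visits["subject_id"], seed=1)
    assert set(pooled.selection_frequency.unique()) <= {0.0, 1.0}
    pd.testing.assert_series_equal(pooled.cyclo,
                                   pooled.predictions[0].rename("cyclo"))


def test_pooled_prediction_within_per_model_extremes(pooled_clock_50):
    pooled, _ = pooled_clock_50
    lo = pooled.predictions.min(axis=1)
    hi = pooled.predictions.max(axis=1)
    assert ((pooled.cyclo >= lo - 1e-12) & (pooled.cyclo <= hi + 1e-12)).all()


def test_noise_light_cohort_support_recovery():
    """With tiny noise and no missingness the pooled support equals the true
    support and coefficient signs match the generative slopes."""
    import dataclasses
    from cytoclock.synthetic import SimConfig, generate_cohort
    from cytoclock.preprocess import compute_balancing_weights
    cfg = SimConfig(n_subjects=150, seed=13, marker_noise_sd=0.02,
                    latent_loadings={m: 0.0 for m in SimConfig().true_marker_names},
                    sex_effects={}, batch_magnitudes=0.0, n_batches=1)
    visits, panel, _, truth = generate_cohort(cfg)
    weights = compute_balancing_weights(visits["age"])
    ens = ImputedEnsemble(panels=[panel.values.copy()],
                          spec=ImputationSpec(n_imputations=1),
                          source_mask=panel.mask)
    pooled = fit_clock_ensemble(ens, visits["age"], weights,
                                visits["subject_id"], seed=2)
    support = set(pooled.mean_beta.index[pooled.mean_beta != 0])
    assert support == set(truth.support)
    for m in truth.support:
        assert np.sign(pooled.mean_beta[m]) == np.sign(truth.age_slopes[m])


# ---------------------------------------------------------------- propagation

def _toy_visits(times, subject="S0"):
    idx = [f"{subject}_v{i}" for i in range(len(times))]
    return pd.DataFrame({"subject_id": subject, "visit_time": times},
                        index=pd.Index(idx, name="visit_id"))


def test_propagation_shifts_by_elapsed_time():
    visits = _toy_visits([0.0, 1.0])         # 2019 and 2020
    measured = pd.Series({"S0_v1": 75.0})    # only the 2020 visit measured
    out = propagate_cyclo(measured, visits, max_gap=3.0)
    assert out.loc["S0_v0", "cyclo"] == pytest.approx(74.0)   # c - 1
    assert out.loc["S0_v0", "source"] == "propagated"
    assert out.loc["S0_v0", "gap"] == pytest.approx(-1.0)
    assert out.loc["S0_v1", "source"] == "measured"
    assert out.loc["S0_v1", "gap"] == 0.0


def test_no_donor_within_gap_stays_unassigned():
    visits = _toy_visits([0.0, 4.0])
    measured = pd.Series({"S0_v1": 80.0})
    out = propagate_cyclo(measured, visits, max_gap=3.0)
    assert "S0_v0" not in out.index


def test_tie_between_sources_prefers_nearest_then_earlier():
    # target at t=1: sources at t=0 (gap -1) and t=3 (gap +2) -> nearest wins
    visits = _toy_visits([0.0, 1.0, 3.0])
    measured = pd.Series({"S0_v0": 70.0, "S0_v2": 90.0})
    out = propagate_cyclo(measured, visits, max_gap=3.0)
    assert out.loc["S0_v1", "cyclo"] == pytest.approx(71.0)
    # exact tie: sources at t=0 and t=2, target t=1 -> earlier source
    visits2 = _toy_visits([0.0, 1.0, 2.0])
    measured2 = pd.Series({"S0_v0": 70.0, "S0_v2": 90.0})
    out2 = propagate_cyclo(measured2, visits2, max_gap=3.0)
    assert out2.loc["S0_v1", "cyclo"] == pytest.approx(71.0)


def test_propagated_gaps_bounded(pooled_clock_50, recovery_cohort):
    pooled, _ = pooled_clock_50
    _, visits, *_ = recovery_cohort
    out = propagate_cyclo(pooled.cyclo, visits, max_gap=3.0)
    prop = out[out["source"] == "propagated"]
    assert (prop["gap"].abs() <= 3.0).all()
    assert (out.loc[out["source"] == "measured", "gap"] == 0).all()
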