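"""Canonical correlation analysis: reductions to known statistics, brute-force
maximization oracle, invariance/orthogonality properties, sequential tests,
and redundancy coefficients."""

import numpy as np
import pandas as pd
import pytest

from cytoclock.cca import (CCAError, bartlett_df, bartlett_sequential_test,
                           canonical_loadings, fit_cca, max_functions,
                           rao_f_test, redundancy, shared_variance)


def _random_sets(seed, n=60, p=3, q=3, coupled=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if coupled:
        mix = rng.normal(size=(p, q))
        Y = X @ mix + rng.normal(size=(n, q)) * rng.uniform(0.5, 2.0)
    else:
        Y = rng.normal(size=(n, q))
    return (pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]),
            pd.DataFrame(Y, columns=[f"y{i}" for i in range(q)]))


from oracles import alternating_max_rho1


# --------------------------------------------------------------- reductions

def test_single_pair_reduces_to_pearson_r():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = 0.6 * x + rng.normal(size=50)
    res = fit_cca(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
    assert res.correlations[0] == pytest.approx(abs(np.corrcoef(x, y)[0, 1]),
                                                abs=1e-12)
    assert abs(res.x_loadings.iloc[0, 0]) == pytest.approx(1.0, abs=1e-12)


def test_single_response_reduces_to_multiple_correlation():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
    y = X @ [1.0, -0.5, 0.2] + rng.normal(size=80)
    res = fit_cca(X, pd.DataFrame({"y": y}))
    Xd = np.column_stack([np.ones(80), X.to_numpy()])
    beta, *_ = np.linalg.lstsq(Xd, y.to_numpy(), rcond=None)
    r2 = 1 - ((y - Xd @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert res.correlations[0] == pytest.approx(np.sqrt(r2), abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_rho1_matches_alternating_maximization_oracle(seed):
    """First canonical correlation within 1e-3 of the iterative brute-force
    maximizer on 20 seeded toys (p, q <= 3)."""
    rng = np.random.default_rng(seed)
    p = int(rng.integers(1, 4))
    q = int(rng.integers(1, 4))
    X, Y = _random_sets(seed, n=int(rng.integers(30, 51)), p=p, q=q)
    res = fit_cca(X, Y)
    assert res.correlations[0] == pytest.approx(
        alternating_max_rho1(X, Y), abs=1e-3)
    assert res.n_functions == min(p, q)


def test_orthogonality_and_unit_variance_invariants():
    X, Y = _random_sets(3, n=100, p=3, q=7)
    res = fit_cca(X, Y)
    for scores in (res.u_scores, res.v_scores):
        S = scores.to_numpy()
        np.testing.assert_allclose(S.std(axis=0, ddof=1), 1.0, atol=1e-8)
        C = np.corrcoef(S, rowvar=False)
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)
    # descending correlations
    assert (np.diff(res.correlations) <= 1e-12).all()


def test_affine_invariance_within_sets():
    X, Y = _random_sets(4, n=90, p=3, q=4)
    res = fit_cca(X, Y)
    rng = np.random.default_rng(9)
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    shift = rng.normal(size=3)
    X2 = pd.DataFrame(X.to_numpy() @ A + shift, columns=X.columns)
    res2 = fit_cca(X2, Y)
    np.testing.assert_allclose(res2.correlations, res.correlations, atol=1e-9)


def test_rank_deficient_set_rejected():
    X, Y = _random_sets(5, n=50, p=2, q=2)
    X["dup"] = X["x0"]
    with pytest.raises(CCAError, match="X"):
        fit_cca(X, Y)


def test_loadings_equal_weights_for_orthonormal_x():
    rng = np.random.default_rng(6)
    # exactly standardized orthogonal X: center the columns first, then QR
    # (Q's columns stay zero-mean), then scale to sample sd 1
    M = rng.normal(size=(60, 3))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    X = pd.DataFrame(Q * np.sqrt(59), columns=list("abc"))
    y = X["a"] + 0.1 * rng.normal(size=60)
    res = fit_cca(X, pd.DataFrame({"y": y}))
    np.testing.assert_allclose(res.x_loadings["F1"],
                               res.x_weights["F1"], atol=1e-8)
    assert (res.x_loadings.abs().to_numpy() <= 1 + 1e-12).all()


# --------------------------------------------------------- dimension tests

def test_bartlett_df_formula():
    assert bartlett_df(3, 7, 1) == 21
    assert bartlett_df(3, 7, 2) == 12
    assert bartlett_df(3, 7, 3) == 5
    assert bartlett_df(1, 1, 1) == 1
    with pytest.raises(CCAError):
        bartlett_df(3, 7, 4)


def test_bartlett_hand_multiplied_wilks():
    rho = np.array([0.59, 0.38, 0.1])
    out = bartlett_sequential_test(rho, n=500, p=3, q=7)
    lam1 = (1 - 0.3481) * (1 - 0.1444) * (1 - 0.01)
    assert out.table["wilks"].iloc[0] == pytest.approx(lam1, abs=1e-10)
    assert lam1 == pytest.approx(0.5522, abs=1e-4)
    mult = 500 - 1 - (3 + 7 + 1) / 2
    assert out.table["chi2"].iloc[0] == pytest.approx(-mult * np.log(lam1))
    assert list(out.table["df"]) == [21, 12, 5]
    # wilks nondecreasing in k
    assert (np.diff(out.table["wilks"]) >= 0).all()


def test_bartlett_all_zero_correlations():
    out = bartlett_sequential_test(np.zeros(3), n=200, p=3, q=7)
    assert (out.table["wilks"] == 1.0).all()
    assert (out.table["chi2"] == 0.0).all()
    assert (out.table["p"] == 1.0).all()


def test_dropping_near_zero_root_perturbs_wilks_weakly():
    rho = np.array([0.59, 0.38, 0.1])
    lam_full = np.prod(1 - rho ** 2)
    lam_drop = np.prod(1 - rho[:2] ** 2)
    assert abs(lam_full - lam_drop) / lam_drop < 0.011


def test_rao_f_trivial_and_exact_r2_reduction():
    out = rao_f_test(np.array([0.0]), n=100, p=1, q=1)
    assert out.table["F"].iloc[0] == 0.0
    assert out.table["p"].iloc[0] == 1.0

    # p_k = 1: Rao F reduces to the classical F test of a squared multiple
    # correlation: F = (R^2 / q) / ((1 - R^2) / (n - q - 1))
    rng = np.random.default_rng(7)
    n, q = 120, 4
    Y = pd.DataFrame(rng.normal(size=(n, q)),
                     columns=[f"y{i}" for i in range(q)])
    x = Y @ [1.0, 0.5, 0.0, -0.3] + rng.normal(size=n) * 2
    res = fit_cca(pd.DataFrame({"x": x}), Y)
    r2 = res.correlations[0] ** 2
    out = rao_f_test(res.correlations, n=n, p=1, q=q)
    f_classic = (r2 / q) / ((1 - r2) / (n - q - 1))
    assert out.table["F"].iloc[0] == pytest.approx(f_classic, rel=1e-10)


def test_bartlett_and_rao_agree_at_large_n():
    rho = np.array([0.4, 0.25, 0.1])
    bart = bartlett_sequential_test(rho, n=1000, p=3, q=7)
    rao = rao_f_test(rho, n=1000, p=3, q=7)
    np.testing.assert_allclose(bart.table["p"], rao.table["p"], atol=0.01)


# -------------------------------------------------------------- redundancy

def test_redundancy_identical_sets_total_one():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    res = fit_cca(X, X.copy().rename(columns=str.upper))
    rep = redundancy(res)
    assert rep.total_y_given_x == pytest.approx(1.0, abs=1e-8)
    assert rep.total_x_given_y == pytest.approx(1.0, abs=1e-8)


def test_redundancy_bounded_by_roots():
    X, Y = _random_sets(9, n=100, p=3, q=7)
    res = fit_cca(X, Y)
    rep = redundancy(res)
    roots = res.roots
    assert (rep.per_dimension["y_given_x"].to_numpy() <= roots + 1e-12).all()
    assert (rep.per_dimension["x_given_y"].to_numpy() <= roots + 1e-12).all()
    assert (rep.per_dimension >= -1e-15).all().all()


# ------------------------------------------------------------ small helpers

def test_shared_variance_and_max_functions():
    assert shared_variance(0.59) == pytest.approx(0.3481)
    assert round(shared_variance(0.59), 2) == 0.35
    assert shared_variance(0.0) == 0.0
    assert shared_variance(1.0) == 1.0
    with pytest.raises(CCAError):
        shared_variance(1.2)
    assert max_functions(3, 7) == 3
    assert max_functions(1, 5) == 1
    assert max_functions(4, 4) == 4


def test_recovery_age_function_loads_on_somatomotor():
    """On the default synthetic cohort the canonical function dominated by
    age on the X side has its largest Y-side loading on the somatomotor
    network (the structure built into the generator)."""
    from cytoclock.synthetic import SimConfig, generate_cohort
    from cytoclock.volumetrics import normalize_to_tiv
    from cytoclock.panel import NETWORKS
    cfg = SimConfig(n_subjects=400, seed=17)
    visits, _, volumes, truth = generate_cohort(cfg)
    nv = normalize_to_tiv(volumes)
    X = pd.DataFrame({"age": visits["age"], "cyclo": truth.physio_age,
                      "sex": visits["sex"]})
    Y = nv[[f"{k}_frac" for k in NETWORKS]]
    res = fit_cca(X, Y)
    age_fn = res.x_loadings.loc["age"].abs().idxmax()
    top_net = res.y_loadings[age_fn].abs().idxmax()
    assert top_net == "somatomotor_frac"
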