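"""Lagged SAR likelihood, predictor construction and model averaging."""

import numpy as np
import pandas as pd
import pytest

from finesgs import (ConnectionNetwork, EnvironmentTable, SpatialFrame,
                     build_env_predictors, build_network, model_select_average,
                     sar_fit)
from finesgs.sar import PREDICTOR_NAMES


def make_net(n, seed=0):
    rng = np.random.default_rng(seed)
    frame = SpatialFrame([f"i{k}" for k in range(n)],
                         rng.uniform(0, 20, n), rng.uniform(0, 20, n))
    return build_network(frame, style="row")


def sar_sim(net, rho, beta, seed, sigma=1.0):
    """Draw G = (I - rho W)^(-1) (X beta + eps) from the generating model."""
    rng = np.random.default_rng(seed)
    n = net.n
    X = rng.standard_normal((n, len(beta)))
    eps = rng.standard_normal(n) * sigma
    G = np.linalg.solve(np.eye(n) - rho * net.weights, X @ beta + eps)
    return G, X


def test_zero_weights_reduce_to_ols():
    rng = np.random.default_rng(1)
    n = 40
    X = rng.standard_normal((n, 2))
    G = 1.0 + X @ [0.5, -0.3] + rng.standard_normal(n) * 0.1
    net = ConnectionNetwork(weights=np.zeros((n, n)), style="row",
                            ids=[f"i{k}" for k in range(n)])
    fit = sar_fit(G, X, net)
    X1 = np.column_stack([np.ones(n), X])
    beta_ols = np.linalg.lstsq(X1, G, rcond=None)[0]
    assert fit.rho == 0.0
    assert np.allclose(fit.beta, beta_ols, atol=1e-10)


def test_profile_optimum_beats_grid_scan():
    net = make_net(60, seed=2)
    G, X = sar_sim(net, rho=0.6, beta=np.array([0.5]), seed=3)
    fit = sar_fit(G, X, net)
    lam = np.sort(np.linalg.eigvals(net.weights).real)
    lo = max(1 / lam[0], -5) + 1e-6
    hi = min(1 / lam[-1], 5) - 1e-6
    X1 = np.column_stack([np.ones(net.n), X])
    H = np.linalg.inv(X1.T @ X1) @ X1.T

    def loglik(rho):
        y = G - rho * net.weights @ G
        resid = y - X1 @ (H @ y)
        s2 = resid @ resid / net.n
        return (-0.5 * net.n * (np.log(2 * np.pi * s2) + 1)
                + np.sum(np.log(np.maximum(1 - rho * lam, 1e-300))))

    grid_best = max(loglik(r) for r in np.linspace(lo, hi, 101))
    assert fit.loglik >= grid_best - 1e-9


def test_aic_counts_rho_and_sigma():
    net = make_net(50, seed=4)
    G, X = sar_sim(net, rho=0.5, beta=np.array([0.4]), seed=5)
    fit = sar_fit(G, X, net)
    k = 2 + 2  # intercept + slope + rho + sigma^2
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-10)


def env_table(df_dict):
    return EnvironmentTable(pd.DataFrame(df_dict))


def test_collinear_anions_explain_everything():
    rng = np.random.default_rng(6)
    n = 20
    nt = rng.standard_normal(n)
    env = env_table({
        "individual_id": [f"i{k}" for k in range(n)],
        "dsf": rng.uniform(0, 1, n), "na": rng.standard_normal(n),
        "k": rng.standard_normal(n), "mg": rng.standard_normal(n),
        "n_total": nt, "p_total": 2.0 * nt + 1.0,
        "field_capacity": rng.uniform(0.1, 0.5, n),
    })
    preds = build_env_predictors(env)
    assert preds.variance_explained["anions"] == pytest.approx(1.0, abs=1e-10)


def test_cation_pca_matches_eigendecomposition():
    rng = np.random.default_rng(7)
    n = 5
    cats = rng.standard_normal((n, 3))
    env = env_table({
        "individual_id": [f"i{k}" for k in range(n)],
        "dsf": rng.uniform(0, 1, n), "na": cats[:, 0], "k": cats[:, 1],
        "mg": cats[:, 2], "n_total": rng.standard_normal(n),
        "p_total": rng.standard_normal(n),
        "field_capacity": rng.uniform(0.1, 0.5, n),
    })
    preds = build_env_predictors(env)
    Z = (cats - cats.mean(axis=0)) / cats.std(axis=0, ddof=1)
    vals, vecs = np.linalg.eigh(np.corrcoef(Z, rowvar=False))
    order = np.argsort(vals)[::-1]
    for pc_name, k in (("cations1", 0), ("cations2", 1)):
        score = Z @ vecs[:, order[k]]
        score = (score - score.mean()) / score.std(ddof=1)
        got = preds.data[pc_name].to_numpy()
        assert (np.allclose(got, score, atol=1e-10)
                or np.allclose(got, -score, atol=1e-10))


def test_sign_anchoring_is_deterministic():
    rng = np.random.default_rng(8)
    n = 30
    base = {
        "individual_id": [f"i{k}" for k in range(n)],
        "dsf": rng.uniform(0, 1, n), "na": rng.standard_normal(n),
        "k": rng.standard_normal(n), "mg": rng.standard_normal(n),
        "n_total": rng.standard_normal(n), "p_total": rng.standard_normal(n),
        "field_capacity": rng.uniform(0.1, 0.5, n),
    }
    p1 = build_env_predictors(env_table(base))
    p2 = build_env_predictors(env_table(base))
    pd.testing.assert_frame_equal(p1.data, p2.data)
    for comp in ("PC1", "PC2"):
        load = p1.loadings["cations"][comp]
        assert load.iloc[np.argmax(np.abs(load.to_numpy()))] > 0


def test_constant_variable_error_names_it():
    n = 10
    env = env_table({
        "individual_id": [f"i{k}" for k in range(n)],
        "dsf": [0.5] * n, "na": np.arange(n, dtype=float),
        "k": np.arange(n, dtype=float) ** 2, "mg": np.arange(n, dtype=float),
        "n_total": np.arange(n, dtype=float),
        "p_total": np.arange(n, dtype=float) + 1,
        "field_capacity": np.linspace(0.1, 0.4, n),
    })
    with pytest.raises(ValueError, match="dsf"):
        build_env_predictors(env)


def full_preds(n, seed=9):
    rng = np.random.default_rng(seed)
    env = env_table({
        "individual_id": [f"i{k}" for k in range(n)],
        "dsf": rng.uniform(0, 1, n), "na": rng.standard_normal(n),
        "k": rng.standard_normal(n), "mg": rng.standard_normal(n),
        "n_total": rng.standard_normal(n), "p_total": rng.standard_normal(n),
        "field_capacity": rng.uniform(0.1, 0.5, n),
    })
    return build_env_predictors(env)


def test_rho_importance_is_one_and_aic_order_invariant():
    net = make_net(50, seed=10)
    preds = full_preds(50)
    X = preds.matrix()
    G, _ = sar_sim(net, rho=0.7, beta=np.zeros(1), seed=11)
    ma = model_select_average(G, preds, net, moran_perm=0)
    assert set(ma.table["predictor"]) == set(PREDICTOR_NAMES)
    assert np.all((ma.table["w_plus"] >= 0) & (ma.table["w_plus"] <= 1))
    # rho is structural: present in every model
    for m in ma.all_models:
        assert "rho" in m
    aics = sorted(m["aic"] for m in ma.all_models)
    # reversing predictor column order leaves the AIC multiset unchanged
    preds_rev = full_preds(50)
    preds_rev.data = preds_rev.data[list(PREDICTOR_NAMES)[::-1]]
    import finesgs.sar as sarmod
    orig = sarmod.PREDICTOR_NAMES
    try:
        sarmod.PREDICTOR_NAMES = tuple(list(orig)[::-1])
        ma2 = model_select_average(G, preds_rev, net, moran_perm=0)
    finally:
        sarmod.PREDICTOR_NAMES = orig
    aics2 = sorted(m["aic"] for m in ma2.all_models)
    assert np.allclose(aics, aics2, atol=1e-8)


def test_true_predictor_gets_high_importance():
    net = make_net(100, seed=12)
    preds = full_preds(100, seed=13)
    rng = np.random.default_rng(14)
    eps = rng.standard_normal(100) * 0.3
    signal = preds.data["dsf"].to_numpy()
    G = np.linalg.solve(np.eye(100) - 0.6 * net.weights, 1.0 * signal + eps)
    ma = model_select_average(G, preds, net, moran_perm=0)
    row = ma.table.set_index("predictor")
    assert row.loc["dsf", "w_plus"] > 0.9
    assert row.loc["dsf", "estimate"] > 0.5


def test_residual_moran_smaller_than_raw(sim_small):
    net = make_net(80, seed=15)
    G, X = sar_sim(net, rho=0.9, beta=np.array([0.3]), seed=16)
    from finesgs import moran_i
    raw_I, _ = moran_i(G, net)
    fit = sar_fit(G, X, net, moran_perm=0)
    res_I, _ = moran_i(fit.residuals, net)
    assert abs(res_I) < abs(raw_I)


def test_full_averaging_shrinks_relative_to_conditional():
    net = make_net(60, seed=17)
    preds = full_preds(60, seed=18)
    G, _ = sar_sim(net, rho=0.5, beta=np.zeros(1), seed=19)
    full = model_select_average(G, preds, net, variant="full", moran_perm=0)
    cond = model_select_average(G, preds, net, variant="conditional",
                                moran_perm=0)
    f = full.table.set_index("predictor")["estimate"].abs()
    c = cond.table.set_index("predictor")["estimate"].abs()
    # zero substitution can only shrink coefficients that appear in a strict
    # subset of the selected models
    partial = full.table.set_index("predictor")["w_plus"] < 1.0
    assert (f[partial] <= c[partial] + 1e-12).all()
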