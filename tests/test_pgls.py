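"""GLS engine: whitened fit, λ-ML, AICc, weights, CIs, multi-tree runs."""

import numpy as np
import pytest

from fadesat import (
    aicc,
    apply_lambda,
    compare_models,
    confidence_intervals,
    effect_size,
    fit_lambda_ml,
    gls_fit,
    multi_tree_pgls,
    read_newick,
)
from fadesat.pgls import FitError, _profile_lnl
from fadesat.simulate import SimulationConfig, simulate_tree
from conftest import random_tree


def _sim_xy(rng, n, beta=(1.0, 2.0)):
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.asarray(beta) + rng.normal(size=n)
    return y, X


# ---------------------------------------------------------------- gls_fit

def test_gls_identity_v_equals_ols(rng):
    y, X = _sim_xy(rng, 30)
    fit = gls_fit(y, X, np.eye(30))
    b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.beta, b_ols, atol=1e-8)
    # and the SEs match the textbook OLS formula
    resid = y - X @ b_ols
    s2 = resid @ resid / (30 - 2)
    se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    np.testing.assert_allclose(fit.se, se_ols, atol=1e-8)


@pytest.mark.parametrize("seed", range(8))
def test_gls_matches_explicit_inverse_oracle(seed):
    """Cholesky-whitened GLS equals the explicit-inverse normal equations."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 9)
    tree = random_tree(seed + 50, int(n))
    _, V = tree.vcv()
    y, X = _sim_xy(rng, int(n))
    fit = gls_fit(y, X, V)
    Vinv = np.linalg.inv(V)
    b_direct = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    np.testing.assert_allclose(fit.beta, b_direct, atol=1e-8)
    r = y - X @ b_direct
    np.testing.assert_allclose(fit.sigma2_hat, r @ Vinv @ r / n, atol=1e-8)
    # log-likelihood against the dense MVN formula
    lnl_direct = (
        -0.5 * n * np.log(2 * np.pi * fit.sigma2_hat)
        - 0.5 * np.linalg.slogdet(V)[1]
        - 0.5 * n
    )
    assert fit.lnl == pytest.approx(lnl_direct, abs=1e-8)


def test_gls_noiseless_recovery(rng):
    tree = random_tree(3, 10)
    _, V = tree.vcv()
    X = np.column_stack([np.ones(10), rng.normal(size=10)])
    beta = np.array([0.5, -1.5])
    y = X @ beta + 1e-9 * rng.normal(size=10)
    fit = gls_fit(y, X, V)
    np.testing.assert_allclose(fit.beta, beta, atol=1e-6)


def test_gls_saturated_model_flagged(rng):
    """n = p: residuals are exactly zero and the fit is refused as degenerate."""
    tree = random_tree(3, 3)
    _, V = tree.vcv()
    X = np.column_stack([np.ones(3), rng.normal(size=3), rng.normal(size=3)])
    y = rng.normal(size=3)
    with pytest.raises(FitError, match="degenerate|zero"):
        gls_fit(y, X, V)


def test_gls_rank_deficient_names_columns(rng):
    y, X = _sim_xy(rng, 20)
    X = np.column_stack([X, X[:, 1]])
    with pytest.raises(FitError, match="collinear"):
        gls_fit(y, X, np.eye(20), coef_names=["intercept", "x", "x_copy"])


def test_gls_non_pd_v(rng):
    y, X = _sim_xy(rng, 3)
    V = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(FitError, match="positive definite"):
        gls_fit(y, X, V)


# ---------------------------------------------------------------- aicc

def test_aicc_hand_value():
    assert aicc(-10.0, 3, 10) == pytest.approx(30.0)


def test_aicc_limits_and_errors():
    lnl, k = -100.0, 4
    aic = -2 * lnl + 2 * k
    assert abs(aicc(lnl, k, 10**6) - aic) < 1e-3
    assert aicc(lnl, k, 100) == aicc(lnl, k, 100)
    with pytest.raises(FitError):
        aicc(lnl, k, k + 1)


# ---------------------------------------------------------------- λ-ML

def test_lambda_grid_oracle():
    """Brent's λ̂ is never beaten by a 0.01-step grid search beyond tolerance."""
    for seed in range(4):
        cfg = SimulationConfig(seed=seed, n_tips=40, true_lambda=0.6)
        tree = simulate_tree(cfg)
        _, V = tree.vcv()
        rng = np.random.default_rng(seed)
        y, X = _sim_xy(rng, 40)
        fit = fit_lambda_ml(y, X, V)
        grid_best = max(_profile_lnl(l, y, X, V) for l in np.linspace(0, 1, 101))
        assert fit.lnl >= grid_best - 1e-6


def test_lambda_profile_continuous():
    tree = random_tree(7, 30)
    _, V = tree.vcv()
    rng = np.random.default_rng(7)
    y, X = _sim_xy(rng, 30)
    lams = np.linspace(0, 1, 200)
    vals = np.array([_profile_lnl(l, y, X, V) for l in lams])
    assert np.all(np.isfinite(vals))
    assert np.max(np.abs(np.diff(vals))) < 1.0  # no jumps on a fine grid


def test_lambda_ml_from_tree_requires_taxa(rng):
    tree = random_tree(1, 10)
    y, X = _sim_xy(rng, 10)
    with pytest.raises(FitError, match="taxa"):
        fit_lambda_ml(y, X, tree)


# ------------------------------------------------------- model comparison

def test_akaike_weights_and_evidence_ratios():
    """ΔAICc of 2.0 ⇒ evidence ratio e ≈ 2.7; 1.2 ⇒ e^0.6 ≈ 1.8."""
    rng = np.random.default_rng(0)
    y, X = _sim_xy(rng, 25)
    base = gls_fit(y, X, np.eye(25))
    import dataclasses

    def shifted(delta):
        lnl = base.lnl - delta / 2.0
        return dataclasses.replace(base, lnl=lnl, aicc=aicc(lnl, base.k, base.n))

    comp = compare_models({"best": base, "other": shifted(2.0)})
    assert comp.table["weight"].sum() == pytest.approx(1.0, abs=1e-10)
    assert comp.table["delta_aicc"].min() == 0.0
    assert comp.evidence_ratio("best", "other") == pytest.approx(np.e, rel=1e-9)
    assert round(comp.evidence_ratio("best", "other"), 1) == 2.7

    comp2 = compare_models({"best": base, "other": shifted(1.2)})
    assert comp2.evidence_ratio("best", "other") == pytest.approx(np.exp(0.6), rel=1e-9)
    assert round(comp2.evidence_ratio("best", "other"), 1) == 1.8


def test_single_model_weight_one(rng):
    y, X = _sim_xy(rng, 20)
    comp = compare_models({"only": gls_fit(y, X, np.eye(20))})
    assert comp.table.loc[0, "weight"] == pytest.approx(1.0)


def test_compare_models_mismatched_n(rng):
    y1, X1 = _sim_xy(rng, 20)
    y2, X2 = _sim_xy(rng, 25)
    with pytest.raises(FitError, match="sample sizes"):
        compare_models({"a": gls_fit(y1, X1, np.eye(20)),
                        "b": gls_fit(y2, X2, np.eye(25))})


def test_delta_aicc_invariant_to_lnl_shift(rng):
    """Adding a constant to every lnL leaves ΔAICc and weights unchanged."""
    import dataclasses
    y, X = _sim_xy(rng, 30)
    f1 = gls_fit(y, X, np.eye(30))
    f2 = gls_fit(y, X[:, :1], np.eye(30), coef_names=["intercept"])
    comp = compare_models({"full": f1, "null": f2})
    shift = 7.5
    shifted = {
        k: dataclasses.replace(f, lnl=f.lnl + shift, aicc=f.aicc - 2 * shift)
        for k, f in {"full": f1, "null": f2}.items()
    }
    comp_s = compare_models(shifted)
    np.testing.assert_allclose(comp.table["delta_aicc"], comp_s.table["delta_aicc"])
    np.testing.assert_allclose(comp.table["weight"], comp_s.table["weight"])


# ------------------------------------------------------------ CIs, effect size

def test_confidence_intervals_zero_exclusion(rng):
    """Significance is 'CI excludes 0': (0.02,0.11)-style CIs are significant,
    (−0.02,0.05)-style are not."""
    n = 200
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 80, n)
    X = np.column_stack([np.ones(n), x])
    y_strong = 1.0 + 0.06 * x + rng.normal(0, 1.0, n)
    fit = gls_fit(y_strong, X, np.eye(n), coef_names=["intercept", "latitude"])
    ci = confidence_intervals(fit, 0.95)
    row = ci[ci["coef"] == "latitude"].iloc[0]
    assert row["ci_low"] > 0 and bool(row["significant"])
    y_null = 1.0 + 0.0 * x + rng.normal(0, 2.0, n)
    fit0 = gls_fit(y_null, X, np.eye(n), coef_names=["intercept", "latitude"])
    ci0 = confidence_intervals(fit0, 0.95)
    row0 = ci0[ci0["coef"] == "latitude"].iloc[0]
    assert row0["ci_low"] < 0 < row0["ci_high"] and not bool(row0["significant"])


def test_effect_size_bounds(rng):
    n = 40
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = 2.0 + 3.0 * x + rng.normal(0, 0.1, n)
    full = gls_fit(y, X, np.eye(n))
    null = gls_fit(y, X[:, :1], np.eye(n), coef_names=["intercept"])
    r = effect_size(full, null)
    assert 0.9 < r <= 1.0
    assert effect_size(null, null) == 0.0
    # r = 0.57 corresponds to ~33% variance explained (to printed rounding)
    assert 0.57**2 == pytest.approx(0.33, abs=0.01)


# --------------------------------------------------------- multi-tree PGLS

def _poly_tree_and_data(seed=11, n=24):
    cfg = SimulationConfig(seed=seed, n_tips=n, polytomy_fraction=0.4)
    tree = simulate_tree(cfg)
    rng = np.random.default_rng(seed)
    taxa = tree.tip_labels
    y, X = _sim_xy(rng, n)
    return tree, taxa, y, X


def test_multi_tree_deterministic():
    tree, taxa, y, X = _poly_tree_and_data()
    assert tree.has_polytomies()
    r1 = multi_tree_pgls(y, X, tree, taxa, n_iter=8, seed=4)
    r2 = multi_tree_pgls(y, X, tree, taxa, n_iter=8, seed=4)
    assert r1.per_iteration.equals(r2.per_iteration)
    assert len(r1.per_iteration) == 8


def test_multi_tree_binary_shortcut(rng):
    tree = random_tree(2, 16)
    taxa = tree.tip_labels
    y, X = _sim_xy(rng, 16)
    res = multi_tree_pgls(y, X, tree, taxa, n_iter=5, seed=0)
    single = fit_lambda_ml(y, X, tree, taxa=taxa)
    assert res.per_iteration["aicc"].nunique() == 1
    np.testing.assert_allclose(res.mean_fit.beta, single.beta)
    assert res.mean_fit.aicc == pytest.approx(single.aicc)


def test_multi_tree_single_iteration():
    tree, taxa, y, X = _poly_tree_and_data()
    res = multi_tree_pgls(y, X, tree, taxa, n_iter=1, seed=9)
    np.testing.assert_allclose(res.mean_fit.beta, res.median_fit.beta)
    assert len(res.per_iteration) == 1


# ---------------------------------------------- parameter-recovery property

def test_beta_recovery_under_generative_model():
    """Mean β̂ over replicates is within 2 Monte-Carlo SEs of the truth."""
    from scipy import linalg as sla

    n, reps = 100, 60
    cfg = SimulationConfig(seed=21, n_tips=n, true_lambda=0.5)
    tree = simulate_tree(cfg)
    taxa = tree.tip_labels
    _, V = tree.vcv(order=taxa)
    Vl = apply_lambda(V, 0.5)
    L = sla.cholesky(0.3 * Vl, lower=True)
    rng = np.random.default_rng(77)
    X = np.column_stack([np.ones(n), rng.uniform(0, 80, n)])
    beta = np.array([1.0, 0.05])
    ests = []
    for _ in range(reps):
        y = X @ beta + L @ rng.standard_normal(n)
        ests.append(fit_lambda_ml(y, X, V).beta)
    ests = np.array(ests)
    mc_se = ests.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(ests.mean(axis=0) - beta) <= 2 * mc_se + 1e-12)


# --------------------------------------- independent-contrasts equivalence

def _pic_through_origin_slope(tree, values_x, values_y, taxa):
    """Felsenstein's independent contrasts, regression through the origin.

    Independent oracle for the λ=1 PGLS slope: standardised contrasts of y
    on contrasts of x with no intercept.
    """
    x = dict(zip(taxa, values_x))
    y = dict(zip(taxa, values_y))
    cx, cy = [], []
    state: dict[int, tuple[float, float, float]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = (
                x[node.taxon.label],
                y[node.taxon.label],
                node.edge.length or 0.0,
            )
            continue
        kids = node.child_nodes()
        assert len(kids) == 2
        (x1, y1, v1), (x2, y2, v2) = state[id(kids[0])], state[id(kids[1])]
        s = np.sqrt(v1 + v2)
        cx.append((x1 - x2) / s)
        cy.append((y1 - y2) / s)
        xm = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        ym = (y1 / v1 + y2 / v2) / (1 / v1 + 1 / v2)
        v = (node.edge.length or 0.0) + v1 * v2 / (v1 + v2)
        state[id(node)] = (xm, ym, v)
    cx, cy = np.asarray(cx), np.asarray(cy)
    return float(cx @ cy / (cx @ cx))


def test_pgls_lambda1_matches_independent_contrasts():
    cfg = SimulationConfig(seed=31, n_tips=40)
    tree = simulate_tree(cfg)
    taxa = tree.tip_labels
    rng = np.random.default_rng(31)
    xv = rng.normal(size=40)
    yv = 0.7 * xv + rng.normal(size=40)
    _, V = tree.vcv(order=taxa)
    fit = gls_fit(yv, np.column_stack([np.ones(40), xv]), V,
                  coef_names=["intercept", "x"])
    pic = _pic_through_origin_slope(tree, xv, yv, taxa)
    assert fit.beta[1] == pytest.approx(pic, abs=1e-6)
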