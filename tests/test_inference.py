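"""Mixed-model estimation and q-value FDR behaviour.

The REML fitter is checked three ways: against an independent dense-matrix
grid oracle over the variance ratio, against ordinary least squares in the
tau2 = 0 / unit-weight limit, and against statsmodels MixedLM on an
unweighted instance.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from plasmaome.inference import (COEF_NAMES, fit_all, fit_feature_model,
                                 qvalues)
from plasmaome.synthetic import SimConfig, make_design, simulate_features


def dense_reml_criterion(lam, y, X, w, mouse):
    """Independent dense implementation of the profiled REML criterion."""
    mice, idx = np.unique(mouse, return_inverse=True)
    Z = np.zeros((len(y), len(mice)))
    Z[np.arange(len(y)), idx] = 1.0
    V0 = np.diag(w) + lam * Z @ Z.T
    Vi = np.linalg.inv(V0)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = X.shape
    s2 = max(float(r @ Vi @ r) / (n - p), 1e-12)
    _, ld = np.linalg.slogdet(V0)
    _, ld2 = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(s2) + ld + ld2)


def random_instance(rng, max_obs=40):
    n_mice = int(rng.integers(4, 10))
    reps = int(rng.integers(2, 5))
    rows = []
    for m in range(n_mice):
        b = rng.normal(0, 0.6)
        for k in range(reps):
            rows.append(dict(
                y=rng.normal(b + 0.5 * (m % 2), 0.7),
                a=float(m % 2), d=float(m % 3 == 0),
                t2=float(k % 3 == 1), t3=float(k % 3 == 2),
                mouse=f"m{m}", w=float(np.exp(rng.uniform(-1.5, 1.5)))))
    return pd.DataFrame(rows)[:max_obs]


def design_columns(obs):
    X = np.column_stack([np.ones(len(obs)), obs["a"], obs["d"], obs["t2"],
                         obs["t3"]])
    keep = [0]
    for j in range(1, 5):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    return X[:, keep]


def test_reml_beats_grid_oracle():
    """Fitted variance components reach the dense-grid REML maximum."""
    rng = np.random.default_rng(77)
    grid = np.concatenate([[0.0], np.exp(np.linspace(-8, 8, 401))])
    for _ in range(8):
        obs = random_instance(rng)
        fit = fit_feature_model(obs)
        y, w = obs["y"].to_numpy(), obs["w"].to_numpy()
        mouse = obs["mouse"].to_numpy()
        X = design_columns(obs)
        ll_fit = dense_reml_criterion(fit.tau2 / fit.sigma2, y, X, w, mouse)
        ll_grid = max(dense_reml_criterion(l, y, X, w, mouse) for l in grid)
        assert ll_fit >= ll_grid - 1e-4


def test_one_observation_per_mouse_reduces_to_ols():
    """tau2 and sigma2 confounded -> tau2=0 convention, fixed effects = OLS."""
    rng = np.random.default_rng(5)
    rows = [dict(y=rng.normal(), a=float(m % 2), d=float(m % 4 == 0),
                 t2=float(m % 3 == 1), t3=float(m % 3 == 2), mouse=f"m{m}")
            for m in range(12)]
    obs = pd.DataFrame(rows)
    fit = fit_feature_model(obs)
    assert fit.tau2 == 0.0
    X = design_columns(obs)
    beta_ols = np.linalg.lstsq(X, obs["y"].to_numpy(), rcond=None)[0]
    got = [fit.coef[c] for c in COEF_NAMES if not np.isnan(fit.coef[c])]
    assert np.allclose(got, beta_ols, atol=1e-8)


def test_fixed_zero_lambda_equals_ols():
    rng = np.random.default_rng(6)
    obs = random_instance(rng)
    obs["w"] = 1.0
    fit = fit_feature_model(obs, lambda_fixed=0.0)
    X = design_columns(obs)
    beta_ols = np.linalg.lstsq(X, obs["y"].to_numpy(), rcond=None)[0]
    got = [fit.coef[c] for c in COEF_NAMES if not np.isnan(fit.coef[c])]
    assert np.allclose(got, beta_ols, atol=1e-8)


def test_matches_statsmodels_mixedlm_unweighted():
    rng = np.random.default_rng(3)
    rows = []
    for m in range(12):
        b = rng.normal(0, 0.5)
        for k in range(3):
            rows.append(dict(y=rng.normal(b + 0.8 * (m >= 6), 0.6),
                             a=float(m >= 6), d=0.0,
                             t2=float(k == 1), t3=float(k == 2),
                             mouse=f"m{m:02d}"))
    obs = pd.DataFrame(rows)
    fit = fit_feature_model(obs)
    md = smf.mixedlm("y ~ a + t2 + t3", obs, groups=obs["mouse"]).fit(reml=True)
    assert fit.coef["beta_age"] == pytest.approx(md.params["a"], abs=1e-6)
    assert fit.se["beta_age"] == pytest.approx(md.bse["a"], rel=1e-4)
    assert fit.tau2 == pytest.approx(float(md.cov_re.iloc[0, 0]), abs=1e-4)
    assert fit.sigma2 == pytest.approx(md.scale, abs=1e-4)


def test_constant_response_handled():
    obs = pd.DataFrame([dict(y=3.0, a=float(m % 2), d=0.0, t2=float(k == 1),
                             t3=float(k == 2), mouse=f"m{m}")
                        for m in range(4) for k in range(3)])
    fit = fit_feature_model(obs)
    assert fit.sigma2 >= 1e-12
    assert not fit.converged or "floored" in fit.note or fit.sigma2 == 1e-12
    assert fit.coef["beta_age"] == pytest.approx(0.0, abs=1e-8)


def test_aliased_coefficient_reported_not_dropped():
    # diet column identical to age column -> diet is non-estimable
    rng = np.random.default_rng(8)
    obs = pd.DataFrame([dict(y=rng.normal(), a=float(m % 2), d=float(m % 2),
                             t2=float(k == 1), t3=float(k == 2), mouse=f"m{m}")
                        for m in range(6) for k in range(3)])
    fit = fit_feature_model(obs)
    assert "beta_diet" in fit.aliased
    assert np.isnan(fit.coef["beta_diet"])
    assert not np.isnan(fit.coef["beta_age"])


def test_weight_rescaling_leaves_fixed_effects_and_p(rng):
    obs = random_instance(rng)
    fit1 = fit_feature_model(obs)
    obs2 = obs.copy()
    obs2["w"] = obs2["w"] * 7.3
    fit2 = fit_feature_model(obs2)
    for c in COEF_NAMES:
        if not np.isnan(fit1.coef[c]):
            assert fit2.coef[c] == pytest.approx(fit1.coef[c], rel=1e-6)
            assert fit2.p[c] == pytest.approx(fit1.p[c], rel=1e-4)
    assert fit2.sigma2 == pytest.approx(fit1.sigma2 / 7.3, rel=1e-5)


def test_fit_all_independence_and_determinism(design_no_plex):
    cfg = SimConfig(seed=30, n_lipids=16, planted_sets=())
    values, _ = simulate_features(design_no_plex, 6, cfg)
    dup = values.copy()
    dup["feature_id"] = dup["feature_id"] + "_copy"
    both = pd.concat([values, dup], ignore_index=True)
    fits = fit_all(both, design_no_plex)
    for fid in values["feature_id"].unique():
        a = fits.loc[fid].drop([c for c in fits.columns if c.startswith("q_")])
        b = fits.loc[fid + "_copy"].drop(
            [c for c in fits.columns if c.startswith("q_")])
        pd.testing.assert_series_equal(
            a, b, check_names=False)
    # permuting feature order does not change per-feature results
    shuffled = both.sample(frac=1.0, random_state=0)
    fits2 = fit_all(shuffled, design_no_plex)
    pd.testing.assert_frame_equal(fits, fits2)


def test_fit_all_recovers_truth(design_no_plex):
    cfg = SimConfig(seed=31)
    values, truth = simulate_features(design_no_plex, 150, cfg)
    fits = fit_all(values, design_no_plex)
    true_beta = truth.set_index("feature_id").loc[fits.index, "beta_diet"]
    r = np.corrcoef(fits["beta_diet"], true_beta)[0, 1]
    assert r > 0.9


def test_fit_all_skips_sparse_features(design_no_plex):
    cfg = SimConfig(seed=32, planted_sets=())
    values, _ = simulate_features(design_no_plex, 3, cfg)
    sparse = values.groupby("feature_id").head(3)
    sparse = sparse[sparse["feature_id"] == sparse["feature_id"].iloc[0]]
    full = values[values["feature_id"] != sparse["feature_id"].iloc[0]]
    from plasmaome.core_io import ProcessingReport
    report = ProcessingReport()
    fits = fit_all(pd.concat([full, sparse]), design_no_plex, report=report)
    assert len(fits) == 2
    assert any(e["message"].startswith("too few") for e in report.entries)


# ---------------------------------------------------------------------------
# q-values


def test_qvalues_all_ones():
    assert np.allclose(qvalues(np.ones(50)), 1.0)


def test_qvalues_pi0_one_equals_bh():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    from statsmodels.stats.multitest import multipletests
    bh = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(qvalues(p, pi0=1.0), bh)


def test_qvalues_uniform_pi0_near_one():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=10_000)
    q = qvalues(p)
    # BH q at the largest p equals pi0; under the null pi0-hat in [0.9, 1]
    pi0_hat = q.max() / p.max()
    assert 0.9 <= pi0_hat <= 1.0 + 1e-9


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(4)
    p = np.concatenate([rng.uniform(size=500), rng.uniform(0, 1e-3, size=100)])
    q = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert ((q >= 0) & (q <= 1)).all()


def test_qvalues_empty_and_invalid():
    assert qvalues([]).size == 0
    with pytest.raises(ValueError):
        qvalues([0.5, 1.5])
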