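"""Screening, VIF, mixed/Poisson fits, stepwise AIC and pseudo-R2."""

import numpy as np
import pandas as pd
import pytest

from greenmig.stats_pipeline import (
    fit_activity_model,
    fit_richness_model,
    log_activity,
    pearson_screen,
    pseudo_r2,
    standardize_predictors,
    stepwise_aic,
    vif_filter,
)


def grouped_gaussian(rng, n_groups=9, per_group=20, beta=(0.5,), tau=0.3, sigma=0.5):
    """Simulated mixed-model data with known standardized coefficients."""
    n = n_groups * per_group
    X = pd.DataFrame({f"x{i + 1}": rng.normal(size=n) for i in range(len(beta))})
    groups = np.repeat([f"g{i}" for i in range(n_groups)], per_group)
    b = dict(zip(np.unique(groups), rng.normal(0, tau, n_groups)))
    y = np.array([b[g] for g in groups]) + rng.normal(0, sigma, n)
    if beta:
        y = y + X.to_numpy() @ np.array(beta)
    return y, X, groups


# --- screening -------------------------------------------------------------


def test_identical_columns_flagged():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
    rep = pearson_screen(X)
    assert rep.flagged == [("a", "b", pytest.approx(1.0))]


def test_negated_column_flagged():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [-1.0, -2, -3, -4]})
    assert pearson_screen(X).flagged[0][2] == pytest.approx(-1.0)


def test_independent_columns_not_flagged(rng):
    X = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
    rep = pearson_screen(X)
    assert abs(rep.corr.loc["a", "b"]) < 0.05
    assert rep.flagged == []


def test_zero_variance_column_reported_undefined():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
    rep = pearson_screen(X)
    assert ("a", "b") in rep.undefined
    assert np.isnan(rep.corr.loc["a", "b"])


# --- VIF -------------------------------------------------------------------


def test_orthogonal_predictors_all_kept(rng):
    # orthogonalize against the constant too, so each auxiliary
    # regression (which includes an intercept) has R^2 exactly 0
    raw = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
    q, _ = np.linalg.qr(raw)
    X = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
    kept, trace = vif_filter(X)
    assert kept == ["a", "b", "c"]
    assert all(v == pytest.approx(1.0, abs=1e-8) for v in trace[-1].values())


def test_duplicated_column_dropped(rng):
    x = rng.normal(size=40)
    X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=40)})
    with pytest.warns(UserWarning, match="collinearity"):
        kept, _ = vif_filter(X)
    assert kept == ["b", "c"]  # alphabetical tie-break drops 'a'


def test_two_predictor_vif_closed_form(rng):
    """For two predictors, VIF = 1 / (1 - r^2) exactly."""
    n = 2000
    x = rng.normal(size=n)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
    X = pd.DataFrame({"a": x, "b": y})
    r = np.corrcoef(x, y)[0, 1]
    _, trace = vif_filter(X)
    expected = 1.0 / (1.0 - r**2)  # ~5.26 at r = .9
    assert trace[0]["a"] == pytest.approx(expected, rel=1e-6)
    assert trace[0]["b"] == pytest.approx(expected, rel=1e-6)
    assert "<dropped>" in trace[0]


def test_vif_invariant_to_row_and_column_order(rng):
    X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("dcba"))
    X["a"] = X["b"] * 0.95 + rng.normal(0, 0.2, 60)
    kept1, _ = vif_filter(X)
    kept2, _ = vif_filter(X[list("abcd")].sample(frac=1, random_state=1))
    assert kept1 == kept2


# --- transforms ------------------------------------------------------------


def test_standardize_moments(rng):
    X = pd.DataFrame({"a": rng.uniform(10, 50, 100), "b": rng.normal(5, 2, 100)})
    Z = standardize_predictors(X)
    assert np.allclose(Z.mean(), 0, atol=1e-8)
    assert np.allclose(Z.std(ddof=0), 1, atol=1e-8)


def test_standardize_names_constant_column():
    X = pd.DataFrame({"a": [1.0, 2, 3], "flat": [7.0, 7, 7]})
    with pytest.raises(ValueError, match="flat"):
        standardize_predictors(X)


def test_log_activity_offset():
    assert log_activity([0.0])[0] == 0.0
    assert log_activity([np.e - 1])[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        log_activity([-1.0])


def test_standardization_preserves_t_statistics(rng):
    """Affine predictor rescaling leaves slope t-values unchanged."""
    import statsmodels.api as sm

    x = rng.uniform(100, 200, 80)
    y = 0.03 * x + rng.normal(0, 1, 80)
    raw = sm.OLS(y, sm.add_constant(x)).fit()
    z = standardize_predictors(pd.DataFrame({"x": x}))["x"].to_numpy()
    std = sm.OLS(y, sm.add_constant(z)).fit()
    assert raw.tvalues[1] == pytest.approx(std.tvalues[1], rel=1e-10)


# --- mixed model -----------------------------------------------------------


def test_intercept_only_recovers_grand_mean(rng):
    y, X, groups = grouped_gaussian(rng, beta=(), tau=0.0, sigma=0.4)
    fit = fit_activity_model(y, None, groups)
    assert fit.params["Intercept"] == pytest.approx(np.mean(y), abs=0.02)


def test_equal_group_means_give_zero_variance(rng):
    y, X, groups = grouped_gaussian(rng, beta=(), tau=0.0, sigma=0.3)
    fit = fit_activity_model(y, None, groups)
    assert fit.random_intercept_variance == pytest.approx(0.0, abs=0.02)


def test_mixed_model_parameter_recovery(rng):
    """beta-hat within 3 SE of truth in nearly all seeded replicates."""
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        y, X, groups = grouped_gaussian(r, beta=(0.4, -0.25), tau=0.3, sigma=0.5)
        fit = fit_activity_model(y, X, groups)
        ok = abs(fit.params["x1"] - 0.4) < 3 * fit.bse["x1"]
        ok &= abs(fit.params["x2"] + 0.25) < 3 * fit.bse["x2"]
        hits += ok
    assert hits >= 19


def test_mixed_model_needs_two_groups(rng):
    y = rng.normal(size=10)
    with pytest.raises(ValueError, match="groups"):
        fit_activity_model(y, None, np.repeat("a", 10))


# --- Poisson / quasi-Poisson ----------------------------------------------


def test_equidispersed_poisson_not_corrected(rng):
    x = rng.normal(size=5000)
    y = rng.poisson(np.exp(1.0 + 0.3 * x))
    fit = fit_richness_model(y, pd.DataFrame({"x": x}))
    assert fit.family == "poisson"
    assert fit.dispersion == pytest.approx(1.0, abs=0.1)


def test_overdispersed_counts_trigger_quasipoisson(rng):
    x = rng.normal(size=2000)
    mu = np.exp(1.0 + 0.3 * x)
    # negative binomial with variance ~3x the mean
    y = rng.negative_binomial(n=mu / 2.0, p=1 / 3.0)
    fit = fit_richness_model(y, pd.DataFrame({"x": x}))
    assert fit.dispersion > 1.5
    assert fit.family == "quasipoisson"


def test_quasipoisson_se_identity(rng):
    """SE_quasi / SE_poisson = sqrt(phi) term-wise, by construction."""
    x = rng.normal(size=500)
    y = rng.negative_binomial(n=2, p=0.3, size=500)
    X = pd.DataFrame({"x": x})
    quasi = fit_richness_model(y, X)
    plain = fit_richness_model(y, X, overdispersion_threshold=np.inf)
    assert plain.family == "poisson" and quasi.family == "quasipoisson"
    ratio = quasi.bse / plain.bse
    assert np.allclose(ratio, np.sqrt(quasi.dispersion), rtol=1e-10)


def test_non_integer_response_rejected(rng):
    with pytest.raises(ValueError, match="integer"):
        fit_richness_model(np.array([1.5, 2.0, 3.0]), None)


# --- stepwise + pseudo-R2 --------------------------------------------------


def test_stepwise_matches_direct_aic_comparison(rng):
    y, X, groups = grouped_gaussian(rng, beta=(0.6,), tau=0.2, sigma=0.5)
    fitter = lambda terms: fit_activity_model(y, X, groups, terms)  # noqa: E731
    selected = stepwise_aic(["x1"], fitter)
    direct = min([fitter([]), fitter(["x1"])], key=lambda f: f.aic)
    assert selected.terms == direct.terms
    assert selected.aic == pytest.approx(direct.aic)
    assert selected.selection_path  # path is logged


def test_stepwise_retains_strong_predictor(rng):
    hits = 0
    for seed in range(20):
        r = np.random.default_rng((7, seed))
        y, X, groups = grouped_gaussian(r, beta=(0.5, 0, 0, 0, 0), tau=0.3, sigma=0.5)
        fit = stepwise_aic(
            list(X.columns), lambda terms: fit_activity_model(y, X, groups, terms)
        )
        hits += "x1" in fit.terms
    assert hits >= 19


def test_stepwise_all_noise_mostly_selects_intercept_only(rng):
    lean = 0
    for seed in range(10):
        r = np.random.default_rng((11, seed))
        x = pd.DataFrame({f"x{i}": r.normal(size=300) for i in range(1, 4)})
        y = r.poisson(3.0, size=300)
        fit = stepwise_aic(
            list(x.columns), lambda terms: fit_richness_model(y, x, terms)
        )
        lean += len(fit.terms) == 0
    assert lean >= 6


def test_pseudo_r2_limits(rng):
    # intercept-only GLM: zero by definition
    y = rng.poisson(3.0, size=200)
    assert fit_richness_model(y, None).pseudo_r2 == pytest.approx(0.0, abs=1e-10)
    # near-noise-free linear signal: mixed-model marginal R2 -> 1
    # (an exactly deterministic response makes the likelihood unbounded)
    X = pd.DataFrame({"x": rng.normal(size=180)})
    groups = np.repeat([f"g{i}" for i in range(9)], 20)
    y = X["x"].to_numpy() + rng.normal(0, 0.01, 180)
    fit = fit_activity_model(y, X, groups)
    assert fit.pseudo_r2 > 0.99


def test_pseudo_r2_increases_with_true_predictor(rng):
    y, X, groups = grouped_gaussian(rng, beta=(0.5,), tau=0.2, sigma=0.5)
    null = fit_activity_model(y, None, groups)
    full = fit_activity_model(y, X, groups)
    assert pseudo_r2(full) > pseudo_r2(null)
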