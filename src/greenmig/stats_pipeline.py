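"""Collinearity screening, model fitting and stepwise AIC selection.

The modelling workflow applied to the per-site tables:

1. Pearson screen: report all pairwise correlations among candidate
   predictors and flag |r| > 0.5.
2. VIF filter: iteratively drop the predictor with the largest variance
   inflation factor while any VIF exceeds 2.
3. Transform: activity -> ln(activity + 1) (the offset admits silent
   sites); continuous predictors z-scored to mean 0, sd 1.
4. Activity models: linear mixed model (Gaussian GLMM) with a random
   intercept per green-space type; ML likelihoods for AIC comparison
   during selection, final coefficients from a REML refit.
5. Richness models: Poisson GLM with log link; if the Pearson
   dispersion exceeds 1.5 the standard errors are inflated by sqrt(phi)
   (quasi-Poisson correction).
6. Bidirectional stepwise AIC from the full post-VIF model.

Pseudo-R2 is deviance-based for GLMs (1 - D/D_null) and, for mixed
models, the marginal variance-partition form: var(fixed-effect
predictions) / (that + random-intercept variance + residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationReport",
    "FitResult",
    "pearson_screen",
    "vif_filter",
    "standardize_predictors",
    "log_activity",
    "fit_activity_model",
    "fit_richness_model",
    "stepwise_aic",
    "pseudo_r2",
]

PEARSON_THRESHOLD = 0.5
VIF_THRESHOLD = 2.0
OVERDISPERSION_THRESHOLD = 1.5


# ---------------------------------------------------------------------------
# screening and transformation


@dataclass(frozen=True)
class CorrelationReport:
    corr: pd.DataFrame  # full pairwise Pearson r matrix (nan where undefined)
    flagged: list[tuple[str, str, float]]  # pairs with |r| > threshold
    undefined: list[tuple[str, str]]  # pairs involving a zero-variance column
    threshold: float


def pearson_screen(X: pd.DataFrame, threshold: float = PEARSON_THRESHOLD) -> CorrelationReport:
    """All pairwise Pearson correlations; flag pairs with |r| > threshold."""
    cols = list(X.columns)
    if len(X) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    flagged, undefined = [], []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            xa, xb = X[a].to_numpy(float), X[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                undefined.append((a, b))
                continue
            r = float(sps.pearsonr(xa, xb)[0])
            corr.loc[a, b] = corr.loc[b, a] = r
            if abs(r) > threshold:
                flagged.append((a, b, r))
    return CorrelationReport(corr=corr, flagged=flagged, undefined=undefined, threshold=threshold)


def _vif(X: pd.DataFrame, col: str) -> float:
    # VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.
    others = [c for c in X.columns if c != col]
    if not others:
        return 1.0
    res = sm.OLS(X[col].to_numpy(float), sm.add_constant(X[others].to_numpy(float))).fit()
    r2 = min(res.rsquared, 1.0)
    return float(np.inf) if r2 >= 1.0 else float(1.0 / (1.0 - r2))


def vif_filter(
    X: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> tuple[list[str], list[dict[str, float]]]:
    """Iteratively drop the largest-VIF predictor while any VIF > threshold.

    Ties are broken alphabetically (the first name in sorted order is
    dropped), making the result invariant to row and column order.
    Returns the retained column names and the VIF trace (one dict of
    VIFs per iteration, the dropped column marked under ``"<dropped>"``).
    """
    if len(X) <= len(X.columns):
        raise ValueError("need more rows than candidate predictors for VIF")
    kept = sorted(X.columns)
    trace: list[dict[str, float]] = []
    while len(kept) > 1:
        vifs = {c: _vif(X[kept], c) for c in kept}
        worst = max(vifs.values())
        record = dict(vifs)
        if worst <= threshold:
            trace.append(record)
            break
        drop = sorted(c for c, v in vifs.items() if v == worst)[0]
        if np.isinf(worst):
            warnings.warn(f"perfect collinearity: dropping {drop!r}")
        record["<dropped>"] = drop  # type: ignore[assignment]
        trace.append(record)
        kept.remove(drop)
    return kept, trace


def standardize_predictors(X: pd.DataFrame, skip: tuple[str, ...] = ()) -> pd.DataFrame:
    """Z-score each column (mean 0, sd 1); columns in ``skip`` pass through."""
    out = X.copy()
    for c in X.columns:
        if c in skip:
            continue
        col = X[c].to_numpy(float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant predictor column {c!r} cannot be standardized")
        out[c] = (col - col.mean()) / sd
    return out


def log_activity(activity: np.ndarray | pd.Series) -> np.ndarray:
    """ln(activity + 1); the unit offset keeps zero-activity sites defined."""
    a = np.asarray(activity, dtype=float)
    if (a < 0).any():
        raise ValueError("activity must be non-negative")
    return np.log1p(a)


# ---------------------------------------------------------------------------
# model fits


@dataclass(frozen=True)
class FitResult:
    """Coefficients and fit summaries for one model.

    ``terms`` excludes the intercept; ``params`` etc. are indexed by
    term name including "Intercept".  ``aic`` is on the ML likelihood
    for mixed models so it is comparable across candidates within one
    stepwise run.
    """

    family: str  # gaussian-mixed | poisson | quasipoisson
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    dispersion: float | None = None
    random_intercept_variance: float | None = None
    residual_variance: float | None = None
    deviance: float | None = None
    null_deviance: float | None = None
    fixed_pred_variance: float | None = None
    selection_path: tuple[str, ...] = field(default=())

    @property
    def pseudo_r2(self) -> float:
        return pseudo_r2(self)


def pseudo_r2(fit: FitResult) -> float:
    """Goodness-of-fit analogue in [0, 1].

    GLMs: 1 - residual deviance / null deviance.  Mixed models: the
    marginal variance-partition form var(Xb) / (var(Xb) + tau^2 + sigma^2).
    """
    if fit.family in ("poisson", "quasipoisson"):
        if fit.null_deviance is None or fit.deviance is None:
            raise ValueError("fit lacks a stored null model")
        if fit.null_deviance == 0:
            return 0.0
        return float(1.0 - fit.deviance / fit.null_deviance)
    if fit.fixed_pred_variance is None:
        raise ValueError("fit lacks stored variance components")
    denom = (
        fit.fixed_pred_variance
        + (fit.random_intercept_variance or 0.0)
        + (fit.residual_variance or 0.0)
    )
    return 0.0 if denom == 0 else float(fit.fixed_pred_variance / denom)


def _design(X: pd.DataFrame | None, terms: list[str], n: int) -> np.ndarray:
    if X is None or not terms:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), X[terms].to_numpy(float)])


def _fit_mixed(model, reml: bool):
    # near-collinear candidates can make one optimizer's curvature
    # matrix singular, and L-BFGS occasionally reports convergence at a
    # degenerate point (infinite llf); fall back through slower methods
    # and accept only a finite-likelihood fit
    last: Exception | None = None
    for method in ("bfgs", "cg", "powell"):
        try:
            res = model.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
            continue
        if np.isfinite(res.llf):
            return res
    raise RuntimeError(f"mixed model failed to converge: {last}")


def fit_activity_model(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame | None,
    groups: np.ndarray | pd.Series,
    terms: list[str] | None = None,
) -> FitResult:
    """Gaussian linear mixed model with a random intercept per group.

    ``y`` is the (log-transformed) activity; ``groups`` the green-space
    type of each site.  AIC comes from the ML fit (-2 llf + 2 k with
    k = fixed effects + random-intercept variance + residual variance);
    reported coefficients and variances come from a REML refit.  A
    boundary fit (zero group variance) converges with a warning.
    """
    y = np.asarray(y, dtype=float)
    terms = list(X.columns) if terms is None and X is not None else list(terms or [])
    exog = _design(X, terms, len(y))
    names = ["Intercept"] + terms
    if len(np.unique(np.asarray(groups))) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if len(y) <= exog.shape[1]:
        raise ValueError("need more observations than fixed-effect parameters")
    model = sm.MixedLM(y, exog, groups=np.asarray(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_ml = _fit_mixed(model, reml=False)
        res = _fit_mixed(model, reml=True)
        k = exog.shape[1] + 2  # fixed effects + tau^2 + sigma^2
        aic = float(-2.0 * res_ml.llf + 2.0 * k)
        fe = pd.Series(np.asarray(res.fe_params), index=names)
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
    tvals = fe / bse
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(tvals)), index=names)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    fixed_pred = exog @ np.asarray(res.fe_params)
    return FitResult(
        family="gaussian-mixed",
        terms=tuple(terms),
        params=fe,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        aic=aic,
        random_intercept_variance=tau2,
        residual_variance=sigma2,
        fixed_pred_variance=float(np.var(fixed_pred)),
    )


def fit_richness_model(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame | None,
    terms: list[str] | None = None,
    overdispersion_threshold: float = OVERDISPERSION_THRESHOLD,
) -> FitResult:
    """Poisson GLM (log link) with quasi-Poisson SE correction.

    The dispersion phi = Pearson chi^2 / df_resid is always estimated;
    when phi exceeds the threshold, standard errors are rescaled by
    sqrt(phi), t- and p-values recomputed, and the family reported as
    quasipoisson.  AIC is that of the underlying Poisson likelihood.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("richness response must be non-negative integer counts")
    terms = list(X.columns) if terms is None and X is not None else list(terms or [])
    exog = _design(X, terms, len(y))
    names = ["Intercept"] + terms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
    phi = float(res.pearson_chi2 / res.df_resid)
    params = pd.Series(np.asarray(res.params), index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    family = "poisson"
    if phi > overdispersion_threshold:
        bse = bse * np.sqrt(phi)
        family = "quasipoisson"
    tvals = params / bse
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(tvals)), index=names)
    return FitResult(
        family=family,
        terms=tuple(terms),
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        aic=float(res.aic),
        dispersion=phi,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
    )


def stepwise_aic(candidates: list[str], fitter, start: str = "full") -> FitResult:
    """Bidirectional stepwise AIC over single-term moves.

    ``fitter(terms)`` fits one candidate model and returns a FitResult;
    selection starts from the full candidate set (or empty with
    ``start="null"``), tries dropping each included and adding each
    excluded term, takes the move with the lowest AIC, and stops when no
    move improves it.  Non-converging candidate fits are skipped with a
    warning.  The winning model's FitResult carries the selection path.
    """
    included = sorted(candidates) if start == "full" else []
    path: list[str] = []

    def try_fit(terms: list[str]) -> FitResult | None:
        try:
            return fitter(sorted(terms))
        except Exception as exc:  # noqa: BLE001 - any fit failure skips the move
            warnings.warn(f"candidate fit {terms} failed ({exc}); move skipped")
            return None

    current = try_fit(included)
    if current is None:
        raise RuntimeError("initial stepwise model failed to fit")
    path.append(f"start[{','.join(included) or 'intercept'}] AIC={current.aic:.3f}")
    while True:
        moves: list[tuple[float, str, FitResult]] = []
        for term in sorted(included):
            f = try_fit([t for t in included if t != term])
            if f is not None:
                moves.append((f.aic, f"-{term}", f))
        for term in sorted(set(candidates) - set(included)):
            f = try_fit(included + [term])
            if f is not None:
                moves.append((f.aic, f"+{term}", f))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, move, best_fit = moves[0]
        if best_aic >= current.aic:
            break
        current = best_fit
        included = list(current.terms)
        path.append(f"{move} AIC={best_aic:.3f}")
    return FitResult(**{**current.__dict__, "selection_path": tuple(path)})
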