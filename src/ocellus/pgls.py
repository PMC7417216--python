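"""Phylogenetic generalized least squares and isometry testing.

The regression model is y = b0 + b1 x + e with e ~ N(0, sigma2 * V),
where V is the Brownian-motion covariance implied by the phylogeny
(:func:`ocellus.treekit.bm_covariance`).  Estimates are the GLS
solution beta = (X' V^-1 X)^-1 X' V^-1 y; sigma2 is the residual
quadratic form divided by n - 2, and confidence intervals use the t
distribution with n - 2 degrees of freedom.

All analyses run on raw mm / mm^2 scales.  Isometry of matched eye and
eyespot features is a slope of 1 through the origin on these scales, so
the isometry test is a two-sided t-test of the slope against 1 together
with a t-test of the intercept against 0.  Two fitted models are judged
to share a slope (or intercept) when their 95% confidence intervals
overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy import stats

from .datamodel import Dataset
from .treekit import Phylogeny, TraitCovariance, add_replicate_tips, bm_covariance

__all__ = [
    "RankError",
    "PGLSFit",
    "IsometryTest",
    "ModelComparison",
    "fit_pgls",
    "test_isometry",
    "compare_models",
    "estimate_white_noise_ridge",
    "fit_feature_regressions",
    "fit_body_size_allometry",
    "FEATURE_PAIRS",
]


class RankError(np.linalg.LinAlgError):
    """The design matrix is rank-deficient (e.g., a constant predictor)."""


@dataclass(frozen=True)
class PGLSFit:
    """A fitted two-parameter GLS regression."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    df_resid: int
    sigma2: float
    n: int
    p_slope_vs_0: float
    p_intercept_vs_0: float
    p_slope_vs_1: float


@dataclass(frozen=True)
class IsometryTest:
    """Two-sided t-tests of slope = 1 and intercept = 0 at level alpha."""

    p_slope_eq_1: float
    p_intercept_eq_0: float
    slope_differs_from_1: bool
    intercept_differs_from_0: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class ModelComparison:
    """CI-overlap comparison of two fits on the same scales."""

    fit_a: PGLSFit
    fit_b: PGLSFit
    slopes_differ: bool
    intercepts_differ: bool


def _as_matrix(cov: TraitCovariance | np.ndarray) -> np.ndarray:
    return cov.matrix if isinstance(cov, TraitCovariance) else np.asarray(cov, float)


def fit_pgls(
    x: np.ndarray, y: np.ndarray, cov: TraitCovariance | np.ndarray
) -> PGLSFit:
    """Fit y = b0 + b1 x by GLS with error covariance ``cov``.

    With an identity covariance this reduces exactly to ordinary least
    squares.  ``cov`` must be positive-definite (use a ridge when the
    tree carries replicate tips).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    V = _as_matrix(cov)
    n = x.size
    if y.size != n or V.shape != (n, n):
        raise ValueError(
            f"shape mismatch: x has {n} entries, y has {y.size}, cov is {V.shape}"
        )
    if n < 3:
        raise ValueError("need at least 3 observations for a 2-parameter GLS fit")
    if np.ptp(x) == 0:
        raise RankError("predictor is constant; slope is unidentifiable")

    X = np.column_stack([np.ones(n), x])
    try:
        cho = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance is not positive-definite: {exc}"
        ) from exc
    Vi_X = scipy.linalg.cho_solve(cho, X)
    Vi_y = scipy.linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    try:
        beta = np.linalg.solve(XtViX, XtViy)
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"normal equations are singular: {exc}") from exc

    resid = y - X @ beta
    df = n - 2
    sigma2 = float(resid @ scipy.linalg.cho_solve(cho, resid)) / df
    sigma2 = max(sigma2, 0.0)
    cov_beta = sigma2 * XtViX_inv
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    tcrit = float(stats.t.ppf(0.975, df))

    def _p(t: float) -> float:
        return float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else float("nan")

    intercept, slope = float(beta[0]), float(beta[1])
    se_int, se_slope = float(se[0]), float(se[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_int = intercept / se_int if se_int > 0 else np.inf * np.sign(intercept)
        t_slope = slope / se_slope if se_slope > 0 else np.inf * np.sign(slope)
        t_iso = (slope - 1.0) / se_slope if se_slope > 0 else np.inf * np.sign(slope - 1.0)
    return PGLSFit(
        slope=slope,
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_int,
        ci95_slope=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        ci95_intercept=(intercept - tcrit * se_int, intercept + tcrit * se_int),
        df_resid=df,
        sigma2=sigma2,
        n=n,
        p_slope_vs_0=_p(t_slope) if se_slope > 0 else (1.0 if slope == 0 else 0.0),
        p_intercept_vs_0=_p(t_int) if se_int > 0 else (1.0 if intercept == 0 else 0.0),
        p_slope_vs_1=_p(t_iso) if se_slope > 0 else (1.0 if slope == 1.0 else 0.0),
    )


def test_isometry(fit: PGLSFit, alpha: float = 0.05) -> IsometryTest:
    """Test slope = 1 (isometry) and intercept = 0 for a fitted model."""
    return IsometryTest(
        p_slope_eq_1=fit.p_slope_vs_1,
        p_intercept_eq_0=fit.p_intercept_vs_0,
        slope_differs_from_1=fit.p_slope_vs_1 < alpha,
        intercept_differs_from_0=fit.p_intercept_vs_0 < alpha,
        alpha=alpha,
    )


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def compare_models(fit_a: PGLSFit, fit_b: PGLSFit) -> ModelComparison:
    """Compare two fits by 95% CI disjointness of slope and intercept."""
    return ModelComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        slopes_differ=_disjoint(fit_a.ci95_slope, fit_b.ci95_slope),
        intercepts_differ=_disjoint(fit_a.ci95_intercept, fit_b.ci95_intercept),
    )


def estimate_white_noise_ridge(
    x: np.ndarray,
    y: np.ndarray,
    cov: TraitCovariance | np.ndarray,
    bounds: tuple[float, float] = (1e-8, 1e4),
) -> float:
    """ML estimate of the white-noise variance fraction ("ridge").

    The error covariance is modelled as sigma2 * (C + eps * dbar * I),
    where C is the Brownian structure, dbar the mean tip depth and eps
    the specimen-level (measurement / individual) variance expressed as
    a fraction of dbar.  eps is profiled out by maximum likelihood on a
    log scale; beta and sigma2 have closed forms given eps.  With
    replicate tips C is singular on its own, so eps also plays the
    regularization role, but at a data-driven magnitude.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    C = _as_matrix(cov)
    n = x.size
    if y.size != n or C.shape != (n, n):
        raise ValueError("shape mismatch between x, y and cov")
    dbar = float(np.trace(C)) / n
    lam, U = np.linalg.eigh(C)
    lam = np.maximum(lam, 0.0)
    X = np.column_stack([np.ones(n), x])
    return _ml_eps(U.T @ X, U.T @ y, lam, dbar, bounds)


def _ml_eps(
    Xr: np.ndarray,
    yr: np.ndarray,
    lam: np.ndarray,
    dbar: float,
    bounds: tuple[float, float] = (1e-8, 1e4),
) -> float:
    """Profile ML for the white-noise fraction in rotated coordinates."""
    n = yr.size

    def negloglik(log_eps: float) -> float:
        w = lam + math.exp(log_eps) * dbar
        Xw = Xr / w[:, None]
        try:
            beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
        except np.linalg.LinAlgError:
            return math.inf
        r = yr - Xr @ beta
        q = float(np.sum(r * r / w))
        if q <= 0:
            return math.inf
        return 0.5 * (n * math.log(q / n) + float(np.sum(np.log(w))))

    res = scipy.optimize.minimize_scalar(
        negloglik,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(math.exp(res.x))


def _gls_rotated(
    Xr: np.ndarray, yr: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """GLS in the eigenbasis of the covariance (weights = eigenvalues)."""
    n, p = Xr.shape
    Xw = Xr / w[:, None]
    A = Xr.T @ Xw
    try:
        beta = np.linalg.solve(A, Xw.T @ yr)
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"normal equations are singular: {exc}") from exc
    r = yr - Xr @ beta
    df = n - p
    sigma2 = max(float(np.sum(r * r / w)) / df, 0.0)
    return beta, sigma2 * A_inv, sigma2, df


def _fit_from_estimates(
    beta: np.ndarray, cov_beta: np.ndarray, sigma2: float, n: int
) -> PGLSFit:
    df = n - 2
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    tcrit = float(stats.t.ppf(0.975, df))
    intercept, slope = float(beta[0]), float(beta[1])
    se_int, se_slope = float(se[0]), float(se[1])

    def _p(est: float, null: float, s: float) -> float:
        if s <= 0:
            return 1.0 if est == null else 0.0
        return float(2 * stats.t.sf(abs((est - null) / s), df))

    return PGLSFit(
        slope=slope,
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_int,
        ci95_slope=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        ci95_intercept=(intercept - tcrit * se_int, intercept + tcrit * se_int),
        df_resid=df,
        sigma2=sigma2,
        n=n,
        p_slope_vs_0=_p(slope, 0.0, se_slope),
        p_intercept_vs_0=_p(intercept, 0.0, se_int),
        p_slope_vs_1=_p(slope, 1.0, se_slope),
    )


#: model name -> (predictor column, response column).  The eye feature is
#: always the explanatory variable; the eyespot feature the response.
FEATURE_PAIRS: dict[str, tuple[str, str]] = {
    "eye_area": ("eye_area_mm2", "eyespot_area_mm2"),
    "pupil_area": ("pupil_area_mm2", "eyespot_pupil_area_mm2"),
    "eye_diameter": ("eye_diameter_mm", "eyespot_diameter_mm"),
    "pupil_diameter": ("pupil_diameter_mm", "eyespot_pupil_diameter_mm"),
}


def specimen_tip_labels(ds: Dataset) -> tuple[list[str], dict[str, int]]:
    """Tip label per morphometric record, and per-species specimen counts.

    Specimens are ordered by (species, specimen id); the first specimen
    of a species keeps the bare species label, later ones get
    ``species#k`` labels matching :func:`add_replicate_tips`.
    """
    ordered = sorted(
        ds.morphometrics, key=lambda m: (m.specimen.species_id, m.specimen.specimen_id)
    )
    counts: dict[str, int] = {}
    labels: list[str] = []
    for m in ordered:
        sp = m.specimen.species_id
        counts[sp] = counts.get(sp, 0) + 1
        labels.append(sp if counts[sp] == 1 else f"{sp}#{counts[sp]}")
    return labels, counts


def fit_feature_regressions(
    ds: Dataset,
    tree: Phylogeny,
    ridge: float | str = "ml",
    models: list[str] | None = None,
    variance_power: float = 1.0,
) -> tuple[dict[str, PGLSFit], pd.DataFrame]:
    """Run the matched eye-vs-eyespot PGLS regressions over a dataset.

    Replicate tips are added per species according to the number of
    measured specimens, the Brownian covariance is built, and each
    feature pair is fitted with the eye measurement as predictor.

    ``ridge`` sets the white-noise (specimen-level) variance fraction on
    the covariance diagonal: a number fixes it, ``"ml"`` (default)
    estimates it per model by maximum likelihood — with replicate tips
    at zero distance, specimen-level noise otherwise degrades the GLS
    error estimate however small the fixed ridge is.

    Measurement scatter on positive size data is multiplicative, so the
    residual standard deviation is modelled as proportional to the
    fitted level raised to ``variance_power`` (1 by default; 0 recovers
    a homoscedastic fit).  The weighting is estimated from a first-pass
    unweighted fit.

    Returns the fits keyed by model name and a tidy coefficient table
    (one row per term).
    """
    if not ds.morphometrics:
        raise ValueError("dataset has no morphometric records")
    if isinstance(ridge, str) and ridge != "ml":
        raise ValueError(f"ridge must be a number or 'ml', got {ridge!r}")
    models = list(FEATURE_PAIRS) if models is None else models
    ordered = sorted(
        ds.morphometrics, key=lambda m: (m.specimen.species_id, m.specimen.specimen_id)
    )
    labels, counts = specimen_tip_labels(ds)
    tree_species = set(tree.tip_labels)
    missing = sorted(set(counts) - tree_species)
    if missing:
        raise KeyError(f"species in data but absent from tree: {missing}")
    rep_tree = add_replicate_tips(tree, counts)
    # Brownian structure over the specimens' tips, in specimen order;
    # the eigenbasis is shared by all four models.
    raw = bm_covariance(rep_tree, ridge=0.0, allow_singular=True).reorder(labels)
    n = len(labels)
    dbar = float(np.trace(raw.matrix)) / n
    lam, U = np.linalg.eigh(raw.matrix)
    lam = np.maximum(lam, 0.0)

    fits: dict[str, PGLSFit] = {}
    rows = []
    for name in models:
        xcol, ycol = FEATURE_PAIRS[name]
        x = np.array([getattr(m, xcol) for m in ordered])
        y = np.array([getattr(m, ycol) for m in ordered])
        if np.ptp(x) == 0:
            raise RankError(f"{name}: predictor is constant")
        X = np.column_stack([np.ones(n), x])
        if variance_power != 0.0:
            b0 = np.linalg.lstsq(X, y, rcond=None)[0]
            fitted = X @ b0
            floor = 1e-6 * float(np.max(np.abs(fitted))) or 1.0
            scale = np.maximum(fitted, floor) ** variance_power
            scale = scale / np.exp(np.mean(np.log(scale)))
        else:
            scale = np.ones(n)
        Xs = X / scale[:, None]
        ys = y / scale
        Xr = U.T @ Xs
        yr = U.T @ ys
        eps = (
            _ml_eps(Xr, yr, lam, dbar) if ridge == "ml" else max(float(ridge), 1e-12)
        )
        beta, cov_beta, sigma2, _ = _gls_rotated(Xr, yr, lam + eps * dbar)
        fit = _fit_from_estimates(beta, cov_beta, sigma2, n)
        fits[name] = fit
        rows.append(
            {
                "model": name,
                "term": "intercept",
                "estimate": fit.intercept,
                "se": fit.se_intercept,
                "ci_low": fit.ci95_intercept[0],
                "ci_high": fit.ci95_intercept[1],
                "p_vs_0": fit.p_intercept_vs_0,
                "p_vs_1": float("nan"),
            }
        )
        rows.append(
            {
                "model": name,
                "term": "slope",
                "estimate": fit.slope,
                "se": fit.se_slope,
                "ci_low": fit.ci95_slope[0],
                "ci_high": fit.ci95_slope[1],
                "p_vs_0": fit.p_slope_vs_0,
                "p_vs_1": fit.p_slope_vs_1,
            }
        )
    return fits, pd.DataFrame(rows)


def fit_body_size_allometry(
    ds: Dataset,
    tree: Phylogeny,
    response: str,
    ridge: float | str = "ml",
) -> PGLSFit:
    """PGLS of a measured feature against standard length.

    Negative allometry shows up as a diameter slope below the isometric
    expectation; the fit is the same GLS machinery with SL as predictor.
    """
    ordered = sorted(
        ds.morphometrics, key=lambda m: (m.specimen.species_id, m.specimen.specimen_id)
    )
    if not ordered:
        raise ValueError("dataset has no morphometric records")
    labels, counts = specimen_tip_labels(ds)
    rep_tree = add_replicate_tips(tree, counts)
    x = np.array([m.specimen.standard_length_mm for m in ordered])
    y = np.array([getattr(m, response) for m in ordered])
    if ridge == "ml":
        raw = bm_covariance(rep_tree, ridge=0.0, allow_singular=True).reorder(labels)
        eps = estimate_white_noise_ridge(x, y, raw)
        dbar = float(np.trace(raw.matrix)) / len(labels)
        cov = TraitCovariance(raw.labels, raw.matrix + eps * dbar * np.eye(len(labels)))
    else:
        cov = bm_covariance(rep_tree, ridge=float(ridge)).reorder(labels)
    return fit_pgls(x, y, cov)
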