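"""Size-window analysis: species bootstrap, gamma/binomial GLMs, 50-50 point.

Eyespots are gained and lost during ontogeny, and the size at which this
happens varies between individuals of a species.  To compare the size
distributions of eyespot-bearing and eyespot-lacking fish without
letting well-photographed species dominate, the data are resampled to
one specimen per species (within each presence state by default) and the
analysis is repeated over many such resamples:

* a gamma GLM (log link) of standard length on the presence indicator
  asks whether fish with eyespots are smaller;
* a binomial (logistic) GLM of presence on standard length gives the
  probability of carrying an eyespot at a given size; its 50-50 point,
  -intercept/slope on the logit scale, is the size at which presence
  and absence are equally likely (an ED50 analogue).

Both GLMs are fitted by iteratively reweighted least squares written
out explicitly; per-iteration p-values, coefficients and 50-50 points
are recorded and summarized.  Everything is reproducible from a single
root seed via counter-derived substreams.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Dataset

__all__ = [
    "FitError",
    "SeparationError",
    "BootstrapConfig",
    "GammaFit",
    "BinomialFit",
    "IterationResult",
    "BootstrapSummary",
    "resample_one_per_species",
    "fit_gamma_glm",
    "fit_binomial_glm",
    "fifty_fifty_point",
    "run_bootstrap",
]

logger = logging.getLogger(__name__)

#: IRLS stops when the relative deviance change drops below this.
IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100
#: Coefficient norm beyond which a logistic fit is declared separated.
SEPARATION_NORM = 1e6
#: Slopes smaller than this in absolute value give an undefined 50-50 point.
FLAT_SLOPE_TOL = 1e-12


class FitError(RuntimeError):
    """A GLM could not be fitted (degenerate grouping or data)."""


class SeparationError(FitError):
    """Complete separation: logistic coefficients diverge."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the species-level bootstrap."""

    n_iterations: int = 250
    seed: int = 0
    alpha: float = 0.05
    group_by: Literal["species_state", "species_only"] = "species_state"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.group_by not in ("species_state", "species_only"):
            raise ValueError(f"unknown group_by {self.group_by!r}")


@dataclass(frozen=True)
class GammaFit:
    """Gamma GLM of size on a group indicator (log link)."""

    intercept: float
    group_coef: float
    se_intercept: float
    se_group: float
    dispersion: float
    p_value: float
    df_resid: int
    n_irls_iterations: int


@dataclass(frozen=True)
class BinomialFit:
    """Logistic GLM of presence on size."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_value: float
    n: int
    n_irls_iterations: int


@dataclass(frozen=True)
class IterationResult:
    iteration: int
    gamma_p: float = math.nan
    binom_p: float = math.nan
    binom_intercept: float = math.nan
    binom_slope: float = math.nan
    fifty_fifty_mm: float = math.nan
    error: str | None = None


@dataclass
class BootstrapSummary:
    """All iteration results plus their aggregates."""

    iterations: list[IterationResult]
    config: BootstrapConfig
    mean_p: float = math.nan
    median_p: float = math.nan
    mean_binom_p: float = math.nan
    median_binom_p: float = math.nan
    mean_5050_mm: float = math.nan
    median_5050_mm: float = math.nan
    min_5050_mm: float = math.nan
    max_5050_mm: float = math.nan
    n_failures: int = 0

    def __post_init__(self):
        ok = [it for it in self.iterations if it.error is None]
        self.n_failures = len(self.iterations) - len(ok)
        if ok:
            gamma_p = np.array([it.gamma_p for it in ok])
            binom_p = np.array([it.binom_p for it in ok])
            self.mean_p = float(np.mean(gamma_p))
            self.median_p = float(np.median(gamma_p))
            self.mean_binom_p = float(np.mean(binom_p))
            self.median_binom_p = float(np.median(binom_p))
            ff = np.array([it.fifty_fifty_mm for it in ok])
            ff = ff[np.isfinite(ff)]
            if ff.size:
                self.mean_5050_mm = float(np.mean(ff))
                self.median_5050_mm = float(np.median(ff))
                self.min_5050_mm = float(np.min(ff))
                self.max_5050_mm = float(np.max(ff))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [it.iteration for it in self.iterations],
                "gamma_p": [it.gamma_p for it in self.iterations],
                "binom_p": [it.binom_p for it in self.iterations],
                "binom_intercept": [it.binom_intercept for it in self.iterations],
                "binom_slope": [it.binom_slope for it in self.iterations],
                "fifty_fifty_mm": [it.fifty_fifty_mm for it in self.iterations],
                "error": [it.error for it in self.iterations],
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_iterations": len(self.iterations),
                    "n_failures": self.n_failures,
                    "mean_gamma_p": self.mean_p,
                    "median_gamma_p": self.median_p,
                    "mean_binom_p": self.mean_binom_p,
                    "median_binom_p": self.median_binom_p,
                    "mean_5050_mm": self.mean_5050_mm,
                    "median_5050_mm": self.median_5050_mm,
                    "min_5050_mm": self.min_5050_mm,
                    "max_5050_mm": self.max_5050_mm,
                }
            ]
        )


def resample_one_per_species(
    ds: Dataset,
    rng: np.random.Generator,
    group_by: Literal["species_state", "species_only"] = "species_state",
) -> Dataset:
    """Draw one specimen uniformly at random per group.

    With ``group_by='species_state'`` (default) the groups are
    (species, presence-state) pairs, so a species observed both with and
    without eyespots contributes one size to each distribution; with
    ``'species_only'`` each species contributes a single specimen
    regardless of state.
    """
    if not ds.records:
        raise ValueError("cannot resample an empty dataset")
    groups: dict[tuple, list] = {}
    for rec in ds.records:
        key = (
            (rec.species_id, rec.eyespot_present)
            if group_by == "species_state"
            else (rec.species_id,)
        )
        groups.setdefault(key, []).append(rec)
    chosen = []
    for key in sorted(groups):
        members = groups[key]
        chosen.append(members[int(rng.integers(len(members)))])
    return Dataset(records=chosen)


def fit_gamma_glm(size_mm: np.ndarray, group: np.ndarray) -> GammaFit:
    """Gamma GLM of positive sizes on a binary group indicator, log link.

    For the log link the GLM working weights are identically 1, so each
    IRLS step is an unweighted least-squares solve of the working
    response.  The dispersion is the Pearson moment estimator and the
    group effect is tested with a Wald t-test on ``df = n - 2``.
    """
    y = np.asarray(size_mm, dtype=float).ravel()
    g = np.asarray(group, dtype=float).ravel()
    if y.size != g.size:
        raise ValueError("size and group vectors differ in length")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("sizes must be positive and finite for a gamma GLM")
    if not (np.any(g == 0) and np.any(g == 1)):
        raise FitError("both groups must be nonempty")
    n = y.size
    X = np.column_stack([np.ones(n), g])

    beta, _, _, _ = np.linalg.lstsq(X, np.log(y), rcond=None)
    dev = math.inf
    n_iter = 0
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
        mu = np.exp(X @ beta)
        new_dev = 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))
        if abs(new_dev - dev) <= IRLS_TOL * (abs(new_dev) + IRLS_TOL):
            dev = new_dev
            break
        dev = new_dev
    df = n - 2
    mu = np.exp(X @ beta)
    dispersion = float(np.sum(((y - mu) / mu) ** 2)) / df
    cov = dispersion * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t_stat = beta[1] / se[1]
    p = float(2 * stats.t.sf(abs(t_stat), df))
    return GammaFit(
        intercept=float(beta[0]),
        group_coef=float(beta[1]),
        se_intercept=float(se[0]),
        se_group=float(se[1]),
        dispersion=dispersion,
        p_value=p,
        df_resid=df,
        n_irls_iterations=n_iter,
    )


def fit_binomial_glm(present: np.ndarray, size_mm: np.ndarray) -> BinomialFit:
    """Logistic regression of a binary outcome on size, by IRLS.

    Convergence is a relative deviance change below 1e-10 within 100
    iterations.  Complete separation (perfectly predicted outcomes,
    diverging coefficients) raises :class:`SeparationError`.
    """
    y = np.asarray(present, dtype=float).ravel()
    x = np.asarray(size_mm, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("outcome and size vectors differ in length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise FitError("only one outcome class present; cannot fit a logistic")
    n = y.size
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    dev = math.inf
    n_iter = 0
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        z = eta + (y - p) / np.maximum(w, 1e-300)
        sw = np.sqrt(w)
        beta_new, _, _, _ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        beta = beta_new
        eta = np.clip(X @ beta, -500, 500)
        with np.errstate(over="ignore"):
            new_dev = 2.0 * float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.where(y == 1, np.maximum(-eta, 0), np.maximum(eta, 0))))
        if np.linalg.norm(beta) > SEPARATION_NORM:
            raise SeparationError("logistic coefficients diverged (separation)")
        if abs(new_dev - dev) <= IRLS_TOL * (abs(new_dev) + IRLS_TOL):
            dev = new_dev
            break
        dev = new_dev
    eta = X @ beta
    p_hat = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    # Complete separation: the fit classifies every outcome perfectly and
    # the deviance is essentially zero (the true MLE is at infinity).
    perfectly_classified = bool(np.all((eta > 0) == (y == 1.0)))
    if perfectly_classified and dev < 1e-6 * n:
        raise SeparationError(
            "outcomes perfectly separated by size; coefficient estimates diverge"
        )
    w = p_hat * (1.0 - p_hat)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    z_stat = beta[1] / se[1]
    p_value = float(2 * stats.norm.sf(abs(z_stat)))
    return BinomialFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        p_value=p_value,
        n=n,
        n_irls_iterations=n_iter,
    )


def fifty_fifty_point(intercept: float, slope: float) -> float | None:
    """Size at which presence probability is 0.5: -intercept/slope.

    Returns None (with a warning) for an effectively flat logistic.
    """
    if abs(slope) < FLAT_SLOPE_TOL:
        warnings.warn(
            "logistic slope is (numerically) zero; the 50-50 point is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    return -intercept / slope


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # Counter-derived substream: results do not depend on iteration order.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def run_bootstrap(ds: Dataset, cfg: BootstrapConfig) -> BootstrapSummary:
    """Run the full resample-and-refit bootstrap.

    Each iteration resamples one specimen per (species, state) group,
    fits the gamma size model and the logistic presence model on the
    pooled resample, and records p-values, coefficients and the 50-50
    point.  Per-iteration fit failures are recorded, not fatal.
    """
    states = {r.eyespot_present for r in ds.records}
    if states != {True, False}:
        raise FitError("dataset must contain both presence states")
    results: list[IterationResult] = []
    for i in range(cfg.n_iterations):
        rng = _iteration_rng(cfg.seed, i)
        sample = resample_one_per_species(ds, rng, group_by=cfg.group_by)
        sizes = np.array([r.standard_length_mm for r in sample.records])
        state = np.array([float(r.eyespot_present) for r in sample.records])
        try:
            gamma = fit_gamma_glm(sizes, state)
            binom = fit_binomial_glm(state, sizes)
        except FitError as exc:
            results.append(IterationResult(iteration=i, error=str(exc)))
            continue
        ff = fifty_fifty_point(binom.intercept, binom.slope)
        results.append(
            IterationResult(
                iteration=i,
                gamma_p=gamma.p_value,
                binom_p=binom.p_value,
                binom_intercept=binom.intercept,
                binom_slope=binom.slope,
                fifty_fifty_mm=math.nan if ff is None else ff,
            )
        )
    summary = BootstrapSummary(iterations=results, config=cfg)
    if summary.n_failures:
        logger.warning("%d of %d bootstrap iterations failed", summary.n_failures, cfg.n_iterations)
    return summary
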